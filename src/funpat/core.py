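"""Domain types and file I/O for time-series expression analysis.

The central containers are :class:`ExpressionSeries` (a gene x sample matrix of
counts or normalized expression), :class:`SampleDesign` (which sample belongs to
which condition / time point / replicate), :class:`GeneSetCatalog` (gene -> set
annotations, e.g. GO terms) and :class:`AnnotationDAG` (child -> parent edges
among set IDs encoding term specificity).

All tabular files are plain TSV, UTF-8, with ``#`` comment lines ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SampleDesign",
    "ExpressionSeries",
    "GeneSetCatalog",
    "AnnotationDAG",
    "read_expression",
    "read_annotations",
    "propagate_annotations",
]

_READ_TSV_KW = dict(sep="\t", comment="#", dtype=str)


class SampleDesign:
    """Maps samples to (condition, time, replicate) on a shared time grid.

    Parameters
    ----------
    table : pandas.DataFrame
        Indexed by sample ID with columns ``condition`` (two labels, e.g.
        treatment / control), ``time`` (real valued, shared ordered grid) and
        ``replicate`` (1..R within each condition).

    Both conditions must observe the same ordered grid of at least three time
    points.  Replicate availability is checked where it matters (the noise
    model), not here, so single-replicate series can still be represented.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"condition", "time", "replicate"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"design is missing columns: {sorted(missing)}")
        table = table.copy()
        table["time"] = table["time"].astype(float)
        table["replicate"] = table["replicate"].astype(int)
        table["condition"] = table["condition"].astype(str)
        if table.index.duplicated().any():
            raise ValueError("duplicate sample IDs in design")
        conds = sorted(table["condition"].unique())
        if len(conds) != 2:
            raise ValueError(f"expected exactly 2 conditions, got {conds}")
        grids = {c: np.sort(table.loc[table.condition == c, "time"].unique()) for c in conds}
        if not np.array_equal(grids[conds[0]], grids[conds[1]]):
            raise ValueError("conditions do not share the same time grid")
        self.times = grids[conds[0]]
        if len(self.times) < 3:
            raise ValueError("need at least 3 time points")
        self.table = table
        self.conditions = conds

    @property
    def n_timepoints(self) -> int:
        return len(self.times)

    @property
    def samples(self) -> pd.Index:
        return self.table.index

    def samples_at(self, condition: str, time: float) -> list[str]:
        t = self.table
        return list(t.index[(t.condition == condition) & (t.time == time)])

    def n_replicates(self, condition: str, time: float) -> int:
        return len(self.samples_at(condition, time))

    def has_replicated_cell(self) -> bool:
        """True if at least one (condition, time) cell has >= 2 replicates."""
        return any(
            self.n_replicates(c, t) >= 2 for c in self.conditions for t in self.times
        )

    def subset_replicate(self, replicate: int) -> "SampleDesign":
        """Design restricted to one replicate index in both conditions."""
        sub = self.table[self.table.replicate == replicate]
        if sub.empty:
            raise ValueError(f"no samples with replicate index {replicate}")
        return SampleDesign(sub)


class ExpressionSeries:
    """A gene x sample expression matrix with a scale flag.

    ``scale`` is one of ``raw`` (integer counts), ``normalized`` (non-negative
    reals on the count scale) or ``log2``.
    """

    SCALES = ("raw", "normalized", "log2")

    def __init__(self, values: pd.DataFrame, scale: str = "raw"):
        if scale not in self.SCALES:
            raise ValueError(f"unknown scale {scale!r}")
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene IDs: {list(dups[:5])}")
        arr = values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("non-numeric cells in expression table")
        if scale != "log2" and (arr < 0).any():
            raise ValueError("negative count in expression table")
        if scale == "raw" and not np.allclose(arr, np.round(arr)):
            raise ValueError("raw counts must be integers")
        self.values = values
        self.scale = scale

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def subset_samples(self, samples) -> "ExpressionSeries":
        return ExpressionSeries(self.values[list(samples)], scale=self.scale)


@dataclass
class GeneSetCatalog:
    """Gene-set annotations: set ID -> member genes, plus readable names."""

    members: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for sid, genes in self.members.items():
            if len(genes) == 0:
                raise ValueError(f"empty gene set {sid!r}")
            self.members[sid] = frozenset(str(g) for g in genes)

    @property
    def set_ids(self) -> list[str]:
        return list(self.members)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.members

    def __len__(self) -> int:
        return len(self.members)

    def name(self, set_id: str) -> str:
        return self.names.get(set_id, set_id)


class AnnotationDAG:
    """Acyclic child -> parent graph over gene-set IDs.

    Depth of a set is its longest path to a root (a node with no parent);
    deeper sets encode more specific annotations.
    """

    def __init__(self, edges: list[tuple[str, str]]):
        g = nx.DiGraph()
        g.add_edges_from((str(c), str(p)) for c, p in edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("cycle in annotation DAG")
        self.graph = g
        self.roots = [n for n in g.nodes if g.out_degree(n) == 0]
        # longest path to a root, computed once in reverse topological order
        depth: dict[str, int] = {}
        for node in reversed(list(nx.topological_sort(g))):
            parents = list(g.successors(node))
            depth[node] = 0 if not parents else 1 + max(depth[p] for p in parents)
        self._depth = depth

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def depth(self, set_id: str) -> int:
        return self._depth[set_id]

    def ancestors(self, set_id: str) -> set[str]:
        """All sets reachable through parent links (excluding the set itself)."""
        return set(nx.descendants(self.graph, set_id))


def read_expression(table_path, design_path) -> tuple[ExpressionSeries, SampleDesign]:
    """Read an expression TSV (first column gene IDs, header = sample IDs)
    together with its sample design TSV (sample, condition, time, replicate).

    The expression scale is taken to be raw counts when every cell is a
    non-negative integer, otherwise normalized.
    """
    table = pd.read_csv(table_path, index_col=0, **_READ_TSV_KW)
    try:
        table = table.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cells in expression table: {exc}") from None
    design_tab = pd.read_csv(design_path, index_col=0, **_READ_TSV_KW)
    design = SampleDesign(design_tab)
    unknown = design.samples.difference(table.columns)
    if len(unknown):
        raise ValueError(f"unknown sample in design: {list(unknown)}")
    extra = table.columns.difference(design.samples)
    if len(extra):
        raise ValueError(f"samples missing from design: {list(extra)}")
    table = table[list(design.samples)]
    arr = table.to_numpy()
    if (arr < 0).any():
        raise ValueError("negative count in expression table")
    scale = "raw" if np.allclose(arr, np.round(arr)) else "normalized"
    return ExpressionSeries(table, scale=scale), design


def propagate_annotations(catalog: GeneSetCatalog, dag: AnnotationDAG) -> GeneSetCatalog:
    """Annotate every gene to all ancestors of its sets (idempotent)."""
    members: dict[str, set[str]] = {s: set(g) for s, g in catalog.members.items()}
    for sid in list(catalog.members):
        if sid not in dag.graph:
            continue
        for anc in dag.ancestors(sid):
            members.setdefault(anc, set()).update(catalog.members[sid])
    members = {s: g for s, g in members.items() if g}
    return GeneSetCatalog({s: frozenset(g) for s, g in members.items()}, dict(catalog.names))


def read_annotations(anno_path, dag_path=None) -> tuple[GeneSetCatalog, AnnotationDAG | None]:
    """Read a two-column gene<TAB>set annotation TSV and an optional
    child<TAB>parent DAG edge list; with a DAG, annotations are propagated to
    all ancestor sets."""
    anno = pd.read_csv(anno_path, header=None, names=["gene", "set"], **_READ_TSV_KW)
    members: dict[str, set[str]] = {}
    for gene, sid in zip(anno["gene"], anno["set"]):
        members.setdefault(sid, set()).add(gene)
    catalog = GeneSetCatalog({s: frozenset(g) for s, g in members.items()})
    if dag_path is None:
        return catalog, None
    edges_tab = pd.read_csv(dag_path, header=None, names=["child", "parent"], **_READ_TSV_KW)
    dag = AnnotationDAG(list(zip(edges_tab["child"], edges_tab["parent"])))
    catalog = propagate_annotations(catalog, dag)
    for node in dag.nodes:
        if node not in catalog:
            raise ValueError(f"DAG set {node!r} has no annotation and no annotated descendants")
    return catalog, dag
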