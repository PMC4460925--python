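"""Full analysis pipeline: selection, per-gene-set pattern clustering over the
annotation DAG, ancestor gene removal, DE list assembly and Main Patterns.

The public surface is statsmodels-style: build a :class:`FunPat` model from an
expression matrix, a sample design, gene-set annotations and (optionally) the
annotation DAG, call :meth:`FunPat.fit`, and read estimates off the returned
:class:`FunPatResults`.

The traversal visits gene sets from most specific (greatest longest-path
depth to the DAG root) to most general; when a significant pattern is found
in a set, its member genes are removed from the pools of all ancestor sets so
that each gene attaches to its most informative annotation.  A gene is called
differentially expressed if it is a seed or belongs to a significant pattern
(pattern-rescued).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bounded_area import BoundedArea, BoundedAreaResults
from .clustering import PatternModel, extract_clusters
from .core import (AnnotationDAG, ExpressionSeries, GeneSetCatalog, SampleDesign,
                   read_annotations, read_expression)
from .normalize import log2_expression, log_ratio_profiles, tmm_normalize

__all__ = ["FunPat", "FunPatResults", "MainPattern", "order_gene_sets",
           "main_patterns", "run", "write_reports"]


def order_gene_sets(catalog: GeneSetCatalog, dag: AnnotationDAG | None = None) -> list[str]:
    """Gene sets ordered most-specific first.

    With a DAG: decreasing longest-path depth to the root, ties broken
    lexicographically by set ID.  Without one: catalog order.
    """
    ids = catalog.set_ids
    if dag is None:
        return ids
    depth = {s: (dag.depth(s) if s in dag.graph else 0) for s in ids}
    return sorted(ids, key=lambda s: (-depth[s], s))


@dataclass
class MainPattern:
    """A cluster of highly correlated gene-set-level patterns."""

    pattern: np.ndarray
    member_patterns: list[str]
    member_sets: list[str]
    main_id: str


def main_patterns(patterns: list[PatternModel], *, base_sd: float = 0.25,
                  alpha: float = 0.05, max_iter: int = 100,
                  tol: float = 1e-6) -> list[MainPattern]:
    """Second-level clustering of the per-set patterns.

    Every input pattern is treated as a seed (they are already vetted by the
    per-set significance rules); the same pattern-extraction machinery groups
    them, and each output cluster becomes one Main Pattern.  Each pattern's
    merge scale combines its own estimation sd with ``base_sd``, which
    absorbs the anchor pattern's uncertainty and the (membership-selection)
    bias that makes two estimates of one shape disagree slightly more than
    independent noise predicts.  The best-determined unassigned pattern
    anchors each new Main Pattern, and a unique pattern keeps a Main Pattern
    of its own.
    """
    if not patterns:
        return []
    ids = [p.pattern_id for p in patterns]
    prof = pd.DataFrame([p.pattern for p in patterns], index=ids)
    sds = pd.Series({p.pattern_id: float(np.hypot(p.pattern_sd, base_sd))
                     for p in patterns})
    clusters = extract_clusters(prof, ids, noise_sd=sds, areas=1.0 / sds,
                                alpha=alpha, slope_alpha=alpha / 3.0, min_members=1,
                                max_iter=max_iter, tol=tol)
    by_id = {p.pattern_id: p for p in patterns}
    out = []
    for i, c in enumerate(clusters):
        mem = c.genes
        out.append(MainPattern(pattern=c.pattern, member_patterns=mem,
                               member_sets=[by_id[m].set_id for m in mem],
                               main_id=f"MP{i + 1}"))
    return out


class FunPat:
    """Integrated selection / clustering / functional-assignment model.

    Parameters
    ----------
    expr : ExpressionSeries
        Raw counts (TMM normalization is applied) or already-normalized
        expression.
    design : SampleDesign
    catalog : GeneSetCatalog
        Gene-set annotations; with ``dag`` they should be ancestor-propagated
        (readers do this automatically).
    dag : AnnotationDAG, optional
        Child -> parent specificity structure; enables depth-ordered
        traversal and ancestor gene removal.
    fdr_threshold, soft_threshold : float
        Seed (BH-adjusted) and candidate (nominal) p-value thresholds.
    alpha : float
        Level of the per-gene goodness-of-fit and runs tests in clustering.
    max_set_size : int
        Sets with more member genes are not clustered (their seeds still
        enter the DE list); guards near-root terms.
    n_null : int
        Monte-Carlo null sample size for the area statistic.
    data_poor : "auto" | bool
        Adjacent-time pseudo-replicate noise estimation when no replicated
        cell exists.
    """

    def __init__(self, expr: ExpressionSeries, design: SampleDesign,
                 catalog: GeneSetCatalog, dag: AnnotationDAG | None = None, *,
                 fdr_threshold: float = 0.05, soft_threshold: float = 0.05,
                 alpha: float = 0.05, max_set_size: int = 3000,
                 slope_alpha: float = 0.01, min_members: int = 3,
                 runs_scope: str = "gene",
                 pseudocount: float = 1.0, n_null: int = 10_000,
                 null_mode: str = "parametric", data_poor: bool | str = "auto",
                 max_iter: int = 100, tol: float = 1e-6,
                 cluster_leaves_only: bool = True,
                 main_pattern_sd: float = 0.25, treatment: str | None = None):
        self.expr = expr
        self.design = design
        self.catalog = catalog
        self.dag = dag
        self.fdr_threshold = fdr_threshold
        self.soft_threshold = soft_threshold
        self.alpha = alpha
        self.slope_alpha = slope_alpha
        self.min_members = min_members
        self.runs_scope = runs_scope
        self.max_set_size = max_set_size
        self.pseudocount = pseudocount
        self.n_null = n_null
        self.null_mode = null_mode
        self.data_poor = data_poor
        self.max_iter = max_iter
        self.tol = tol
        self.cluster_leaves_only = cluster_leaves_only
        self.main_pattern_sd = main_pattern_sd
        self.treatment = treatment

    @classmethod
    def from_files(cls, counts_path, design_path, anno_path, dag_path=None, **kw) -> "FunPat":
        expr, design = read_expression(counts_path, design_path)
        catalog, dag = read_annotations(anno_path, dag_path)
        return cls(expr, design, catalog, dag, **kw)

    # -- internal -----------------------------------------------------------

    def _normalized(self) -> ExpressionSeries:
        if self.expr.scale == "raw":
            normalized, _ = tmm_normalize(self.expr)
            return normalized
        return self.expr

    def _profile_noise_sd(self, ba: BoundedAreaResults,
                          normalized: ExpressionSeries) -> pd.Series:
        """Per-gene sd of one log-ratio profile point, from the replicate
        noise model at the gene's mean log2 expression."""
        mean_log2 = log2_expression(normalized, self.pseudocount).values.mean(axis=1)
        design = self.design
        inv_r = np.mean([
            1.0 / design.n_replicates(c, t)
            for c in design.conditions for t in design.times])
        return pd.Series(ba.noise_model.sd(mean_log2) * np.sqrt(2.0 * inv_r),
                         index=normalized.genes)

    # -- fitting ------------------------------------------------------------

    def fit(self, seed: int | None = 0,
            scores: pd.DataFrame | None = None) -> "FunPatResults":
        """Run the pipeline.

        ``scores`` may supply precomputed per-gene results (columns pvalue,
        padj, is_seed, is_candidate and optionally area), replacing the
        built-in Bounded-Area selection.
        """
        if len(self.catalog) == 0:
            raise ValueError("empty gene-set catalog")
        normalized = self._normalized()
        ba = BoundedArea(normalized, self.design, pseudocount=self.pseudocount,
                         n_null=self.n_null, fdr_threshold=self.fdr_threshold,
                         soft_threshold=self.soft_threshold,
                         null_mode=self.null_mode, data_poor=self.data_poor,
                         treatment=self.treatment).fit(seed)
        if scores is None:
            scores = ba.scores
        else:
            scores = scores.reindex(normalized.genes)
        seeds = set(scores.index[scores.is_seed])
        candidates = set(scores.index[scores.is_candidate])
        profiles = log_ratio_profiles(normalized, self.design, self.pseudocount,
                                      treatment=self.treatment)
        noise_sd = self._profile_noise_sd(ba, normalized)
        areas = scores["area"] if "area" in scores else pd.Series(0.0, index=scores.index)

        removed: dict[str, set[str]] = {s: set() for s in self.catalog.set_ids}
        patterns: list[PatternModel] = []
        order = order_gene_sets(self.catalog, self.dag)
        leaves = (None if self.dag is None or not self.cluster_leaves_only
                  else {n for n in self.dag.graph if self.dag.graph.in_degree(n) == 0})
        for sid in order:
            members = self.catalog.members[sid]
            if len(members) > self.max_set_size:
                continue
            if leaves is not None and sid in self.dag.graph and sid not in leaves:
                continue  # patterns are searched in the most specific terms
            pool = [g for g in profiles.index
                    if g in members and g in candidates and g not in removed[sid]]
            pool_seeds = [g for g in pool if g in seeds]
            if not pool_seeds:
                continue
            clusters = extract_clusters(profiles.loc[pool], pool_seeds,
                                        noise_sd=noise_sd.loc[pool], areas=areas,
                                        alpha=self.alpha, slope_alpha=self.slope_alpha,
                                        min_members=self.min_members,
                                        runs_scope=self.runs_scope,
                                        max_iter=self.max_iter, tol=self.tol)
            for ci, cl in enumerate(clusters):
                cl.set_id = sid
                cl.pattern_id = f"{sid}#{ci + 1}"
                patterns.append(cl)
                if self.dag is not None and sid in self.dag.graph:
                    for anc in self.dag.ancestors(sid):
                        if anc in removed:
                            removed[anc].update(cl.genes)

        mains = main_patterns(patterns, base_sd=self.main_pattern_sd,
                              alpha=self.alpha, max_iter=self.max_iter, tol=self.tol)

        rows = []
        assigned: set[str] = set()
        for cl in patterns:
            for g in cl.genes:
                rows.append((g, "seed" if g in seeds else "pattern-rescued",
                             cl.set_id, cl.pattern_id))
                assigned.add(g)
        for g in sorted(seeds - assigned):
            rows.append((g, "seed", "", ""))
        de_genes = pd.DataFrame(rows, columns=["gene", "provenance", "set_id", "pattern_id"])
        return FunPatResults(self, ba, scores, patterns, mains, de_genes,
                             profiles=profiles, noise_sd=noise_sd)


class FunPatResults:
    """Fitted pipeline results: per-gene scores, significant per-set
    patterns, Main Patterns and the final DE gene list with provenance."""

    def __init__(self, model: FunPat, selection: BoundedAreaResults,
                 scores: pd.DataFrame, patterns: list[PatternModel],
                 mains: list[MainPattern], de_genes: pd.DataFrame, *,
                 profiles: pd.DataFrame, noise_sd: pd.Series):
        self.model = model
        self.selection = selection
        self.scores = scores
        self.patterns = patterns
        self.main_patterns = mains
        self.de_table = de_genes
        self.profiles = profiles
        self.noise_sd = noise_sd

    @property
    def seeds(self) -> list[str]:
        return list(self.scores.index[self.scores.is_seed])

    @property
    def de_genes(self) -> list[str]:
        return list(dict.fromkeys(self.de_table["gene"]))

    @property
    def rescued(self) -> list[str]:
        t = self.de_table
        return list(dict.fromkeys(t.gene[t.provenance == "pattern-rescued"]))

    def main_partition(self) -> dict[str, set[str]]:
        """Main-Pattern ID -> member genes (union over the member per-set
        patterns); the partition of selected genes at the resolution the
        pipeline reports its output clusters.  Falls back to the per-set
        partition when no Main Patterns exist."""
        if not self.main_patterns:
            return self.cluster_partition()
        by_pid = {p.pattern_id: p for p in self.patterns}
        part: dict[str, set[str]] = {}
        seen: set[str] = set()
        for mp in self.main_patterns:
            mem: set[str] = set()
            for pid in mp.member_patterns:
                mem |= {g for g in by_pid[pid].genes if g not in seen}
            if mem:
                part[mp.main_id] = mem
                seen |= mem
        return part

    def cluster_partition(self) -> dict[str, set[str]]:
        """Pattern ID -> member genes (first assignment wins for the rare
        gene clustered in two sets of a flat catalog)."""
        part: dict[str, set[str]] = {}
        seen: set[str] = set()
        for cl in self.patterns:
            mem = {g for g in cl.genes if g not in seen}
            if mem:
                part[cl.pattern_id] = mem
                seen |= mem
        return part

    def summary(self) -> str:
        n_sets = len({p.set_id for p in self.patterns})
        lines = [
            "FunPat time-series analysis",
            "===========================",
            f"genes                  {len(self.scores)}",
            f"seeds (FDR <= {self.model.fdr_threshold:g})    {len(self.seeds)}",
            f"candidates (p <= {self.model.soft_threshold:g})  {int(self.scores.is_candidate.sum())}",
            f"significant patterns   {len(self.patterns)} in {n_sets} gene sets",
            f"main patterns          {len(self.main_patterns)}",
            f"DE genes               {len(self.de_genes)} "
            f"({len(self.rescued)} pattern-rescued)",
            f"null family            {self.selection.null.family}",
        ]
        return "\n".join(lines)

    def write_reports(self, out_dir, plots: bool = False) -> None:
        write_reports(self, out_dir, plots=plots)


def run(expr, design, catalog, dag=None, seed: int | None = 0,
        scores: pd.DataFrame | None = None, **config) -> FunPatResults:
    """Functional one-call entry point; see :class:`FunPat`."""
    return FunPat(expr, design, catalog, dag, **config).fit(seed, scores=scores)


def write_reports(result: FunPatResults, out_dir, plots: bool = False) -> None:
    """Write genes.tsv, gene_sets.tsv, main_patterns.tsv, scores.tsv and
    patterns.json (numeric profiles); optional per-pattern PDF plots."""
    os.makedirs(out_dir, exist_ok=True)
    j = lambda name: os.path.join(out_dir, name)
    result.de_table.to_csv(j("genes.tsv"), sep="\t", index=False)

    rows = [(p.set_id, result.model.catalog.name(p.set_id), p.pattern_id,
             len(p), int(p.members.index.isin(result.seeds).sum()))
            for p in result.patterns]
    pd.DataFrame(rows, columns=["set_id", "set_name", "pattern_id", "n_genes",
                                "n_seeds"]).to_csv(j("gene_sets.tsv"), sep="\t", index=False)

    mrows = [(mp.main_id, pid, sid) for mp in result.main_patterns
             for pid, sid in zip(mp.member_patterns, mp.member_sets)]
    pd.DataFrame(mrows, columns=["main_pattern_id", "pattern_id", "set_id"]
                 ).to_csv(j("main_patterns.tsv"), sep="\t", index=False)

    out = result.scores.copy()
    out.index.name = "gene"
    out.to_csv(j("scores.tsv"), sep="\t")

    payload = {
        "times": [float(t) for t in result.model.design.times],
        "patterns": {p.pattern_id: [float(v) for v in p.pattern] for p in result.patterns},
        "main_patterns": {mp.main_id: [float(v) for v in mp.pattern]
                          for mp in result.main_patterns},
    }
    with open(j("patterns.json"), "w") as fh:
        json.dump(payload, fh, indent=1)

    if plots and result.patterns:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        times = result.model.design.times
        with plt.rc_context({"figure.max_open_warning": 0}):
            for p in result.patterns:
                fig, ax = plt.subplots(figsize=(4, 3))
                for g in p.genes:
                    ax.plot(times, result.profiles.loc[g], color="0.7", lw=0.6)
                ax.plot(times, p.pattern * np.abs(result.profiles.loc[p.genes]).to_numpy().max(),
                        color="crimson", lw=2)
                ax.set_xlabel("time")
                ax.set_ylabel("log2 fold change")
                ax.set_title(p.pattern_id)
                fig.tight_layout()
                fig.savefig(j(f"pattern_{p.pattern_id.replace('#', '_')}.pdf"))
                plt.close(fig)
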