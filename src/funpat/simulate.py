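"""Synthetic time-series RNA-seq benchmark generator.

Datasets mimic a two-condition (treatment vs control) time course: S temporal
log fold-change patterns drive a small block of differentially expressed
genes, every other gene is flat in expectation, read counts are drawn from a
Negative Binomial at a random per-sample sequencing depth, and the counts are
TMM-normalized.  A synthetic gene-set catalog with a three-level DAG (leaf
sets -> mid-level sets -> root) ties each pattern's genes to one specific
leaf term, with non-DE genes mixed in.

Ground truth (DE flags and pattern labels) is retained so selection and
clustering can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import AnnotationDAG, ExpressionSeries, GeneSetCatalog, SampleDesign, propagate_annotations
from .normalize import tmm_normalize

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "pattern_library",
    "make_patterns",
    "simulate_profiles",
    "sample_counts",
    "attach_annotations",
    "generate",
    "write_dataset",
]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults: 10000 genes over 13 time points, 6 patterns x 20 DE genes,
    3 replicates per (condition, time), NB dispersion 0.1, depths uniform in
    [1e6, 1e7], baseline log expression q ~ N(1.5, sd 1.8) (natural log),
    response gain k ~ U[0.5, 2].
    """

    n_genes: int = 10_000
    n_timepoints: int = 13
    n_patterns: int = 6
    de_per_pattern: int = 20
    n_replicates: int = 3
    dispersion: float = 0.1
    depth_range: tuple[float, float] = (1e6, 1e7)
    q_mean: float = 1.5
    q_scale: float = 1.8
    q_scale_is_variance: bool = False
    k_range: tuple[float, float] = (0.5, 2.0)
    anno_extra_range: tuple[int, int] = (9, 925)
    n_decoy_sets: int = 50
    decoy_size_range: tuple[int, int] = (10, 200)
    n_mid_sets: int = 10
    seed: int | None = None

    def __post_init__(self):
        if self.n_patterns * self.de_per_pattern > self.n_genes:
            raise ValueError("more DE genes than genes")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.depth_range[0] <= 0:
            raise ValueError("depth range must be positive")

    @property
    def n_de(self) -> int:
        return self.n_patterns * self.de_per_pattern

    @property
    def q_sd(self) -> float:
        return float(np.sqrt(self.q_scale)) if self.q_scale_is_variance else self.q_scale


@dataclass
class SimulatedDataset:
    """Counts, normalization, ground truth and annotations for one dataset."""

    counts: ExpressionSeries
    normalized: ExpressionSeries
    factors: pd.Series
    design: SampleDesign
    truth: pd.DataFrame  # index gene; columns is_de (bool), pattern (int, -1 if not DE)
    catalog: GeneSetCatalog
    dag: AnnotationDAG
    depths: pd.Series
    patterns: np.ndarray
    config: SimulationConfig

    @property
    def de_genes(self) -> list[str]:
        return list(self.truth.index[self.truth.is_de])

    def truth_partition(self) -> dict[int, set[str]]:
        t = self.truth[self.truth.is_de]
        return {int(j): set(t.index[t.pattern == j]) for j in sorted(t.pattern.unique())}


# ---------------------------------------------------------------------------
# temporal patterns

def pattern_library(u: np.ndarray) -> dict[str, np.ndarray]:
    """Built-in temporal shapes on the unit interval (raw, unnormalized)."""
    sig = lambda mid, sc: 1.0 / (1.0 + np.exp(-(u - mid) / sc))
    shapes = {
        "early_transient_up": (u / 0.15) * np.exp(1 - u / 0.15),
        "late_sustained_up": sig(0.78, 0.05) - sig(0.78, 0.05)[0],
        "early_transient_down": -(u / 0.30) * np.exp(1 - u / 0.30),
        "late_sustained_down": -(sig(0.60, 0.10) - sig(0.60, 0.10)[0]),
        "slow_ramp_up": 1.0 - np.exp(-4.0 * u),
        "peak_mid": np.sin(np.pi * u),
        "peak_late": np.where(u >= 0.3, np.sin(np.pi * np.clip((u - 0.3) / 0.7, 0, 1)), 0.0),
        "slow_ramp_down": -(1.0 - np.exp(-4.0 * u)),
    }
    return shapes


def make_patterns(n_timepoints: int, n_patterns: int, seed: int | None = None,
                  custom: np.ndarray | None = None) -> np.ndarray:
    """Return an (S, M) array of temporal patterns scaled to max |value| 1.

    ``custom`` shapes, when given, are passed through after normalization;
    otherwise the first S shapes of the built-in library are used.
    """
    if custom is not None:
        pats = np.atleast_2d(np.asarray(custom, float))
        if pats.shape != (n_patterns, n_timepoints):
            raise ValueError("custom shapes have wrong dimensions")
    else:
        u = np.linspace(0.0, 1.0, n_timepoints)
        lib = list(pattern_library(u).values())
        if n_patterns > len(lib):
            raise ValueError(f"only {len(lib)} built-in shapes; supply custom shapes")
        pats = np.array(lib[:n_patterns])
    scale = np.abs(pats).max(axis=1, keepdims=True)
    if (scale == 0).any():
        raise ValueError("constant pattern shape")
    return pats / scale


# ---------------------------------------------------------------------------
# expression profiles and counts

def simulate_profiles(config: SimulationConfig, patterns: np.ndarray,
                      rng: np.random.Generator):
    """Per-condition expected expression levels theta (natural-log model).

    Treatment, DE gene f of pattern j:  log theta_f(t) = k_f * P_j(t) + q_f.
    Control and non-DE genes:           log theta_f(t) = q_f.

    Returns (theta_treatment, theta_control) as (N, M) arrays plus the truth
    table with per-gene DE flags, pattern labels, k and q.
    """
    n, m = config.n_genes, config.n_timepoints
    genes = [f"g{i:05d}" for i in range(n)]
    q = rng.normal(config.q_mean, config.q_sd, size=n)
    k = np.zeros(n)
    pattern_of = np.full(n, -1)
    de_idx = rng.choice(n, size=config.n_de, replace=False)
    for j in range(config.n_patterns):
        block = de_idx[j * config.de_per_pattern:(j + 1) * config.de_per_pattern]
        pattern_of[block] = j
        k[block] = rng.uniform(*config.k_range, size=len(block))
    log_ctl = np.tile(q[:, None], (1, m))
    log_trt = log_ctl.copy()
    is_de = pattern_of >= 0
    log_trt[is_de] += k[is_de, None] * patterns[pattern_of[is_de]]
    truth = pd.DataFrame({"is_de": is_de, "pattern": pattern_of, "k": k, "q": q},
                         index=pd.Index(genes, name="gene"))
    return np.exp(log_trt), np.exp(log_ctl), truth


def sample_counts(theta: np.ndarray, depth: float, dispersion: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw one sample's counts: NB with mean depth * theta / sum(theta) and
    variance mean + dispersion * mean^2 (Poisson when dispersion = 0)."""
    theta = np.asarray(theta, float)
    total = theta.sum()
    if total <= 0:
        raise ValueError("zero total expression")
    mean = depth * theta / total
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _sample_name(cond: str, t_index: int, rep: int) -> str:
    return f"{cond}_t{t_index:02d}_r{rep}"


def simulate_counts(config: SimulationConfig, theta_trt: np.ndarray,
                    theta_ctl: np.ndarray, rng: np.random.Generator,
                    genes: pd.Index):
    """All samples of a dataset: both conditions, every time point and
    replicate, each at its own uniformly drawn sequencing depth."""
    times = np.arange(config.n_timepoints, dtype=float)
    cols, data, rows = [], [], []
    theta_of = {"treatment": theta_trt, "control": theta_ctl}
    depths = {}
    for cond in ("control", "treatment"):
        for ti in range(config.n_timepoints):
            for rep in range(1, config.n_replicates + 1):
                name = _sample_name(cond, ti, rep)
                depth = rng.uniform(*config.depth_range)
                depths[name] = depth
                cols.append(name)
                data.append(sample_counts(theta_of[cond][:, ti], depth,
                                          config.dispersion, rng))
                rows.append((name, cond, times[ti], rep))
    counts = pd.DataFrame(np.array(data).T, index=genes, columns=cols)
    design = SampleDesign(pd.DataFrame(
        [(c, t, r) for _, c, t, r in rows],
        index=pd.Index(cols, name="sample"),
        columns=["condition", "time", "replicate"]))
    return ExpressionSeries(counts, scale="raw"), design, pd.Series(depths, name="depth")


# ---------------------------------------------------------------------------
# synthetic annotations

def attach_annotations(truth: pd.DataFrame, config: SimulationConfig,
                       rng: np.random.Generator) -> tuple[GeneSetCatalog, AnnotationDAG]:
    """Synthetic gene-set catalog: one specific leaf term per DE pattern (its
    20 DE genes plus a uniform 9..925 non-DE genes), decoy leaf terms holding
    only non-DE genes, and a seeded random leaf -> mid -> root DAG.
    Annotations are propagated upward."""
    genes = truth.index.to_numpy()
    non_de = genes[~truth.is_de.to_numpy()]
    members: dict[str, frozenset] = {}
    lo, hi = config.anno_extra_range
    for j in sorted(truth.pattern[truth.is_de].unique()):
        de_members = genes[truth.pattern.to_numpy() == j]
        n_extra = min(int(rng.integers(lo, hi + 1)), len(non_de))
        extra = rng.choice(non_de, size=n_extra, replace=False)
        members[f"GS_T{j + 1}"] = frozenset(de_members) | frozenset(extra)
    in_truth_sets = set().union(*members.values()) if members else set()
    decoy_pool = np.array([g for g in non_de if g not in in_truth_sets])
    dlo, dhi = config.decoy_size_range
    for d in range(config.n_decoy_sets):
        size = int(rng.integers(dlo, dhi + 1))
        size = min(size, len(decoy_pool))
        if size == 0:
            break
        members[f"GS_D{d + 1:02d}"] = frozenset(rng.choice(decoy_pool, size=size, replace=False))
    leaves = sorted(members)
    mids = [f"GS_M{i + 1:02d}" for i in range(min(config.n_mid_sets, len(leaves)))]
    edges = []
    perm = rng.permutation(len(leaves))
    for pos, leaf_i in enumerate(perm):
        # first pass guarantees every mid-level set has at least one child
        mid = mids[pos] if pos < len(mids) else mids[int(rng.integers(len(mids)))]
        edges.append((leaves[leaf_i], mid))
    edges += [(m, "GS_ROOT") for m in mids]
    dag = AnnotationDAG(edges)
    catalog = propagate_annotations(GeneSetCatalog(members), dag)
    return catalog, dag


# ---------------------------------------------------------------------------
# top level

def generate(config: SimulationConfig | None = None, seed: int | None = None) -> SimulatedDataset:
    """Simulate one full dataset: patterns -> profiles -> NB counts -> TMM
    normalization -> synthetic annotations, with truth retained.

    ``seed`` overrides ``config.seed``; the same seed reproduces the dataset
    exactly.
    """
    config = config or SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    patterns = make_patterns(config.n_timepoints, config.n_patterns)
    theta_trt, theta_ctl, truth = simulate_profiles(config, patterns, rng)
    counts, design, depths = simulate_counts(config, theta_trt, theta_ctl, rng,
                                             truth.index)
    normalized, factors = tmm_normalize(counts)
    catalog, dag = attach_annotations(truth, config, rng)
    return SimulatedDataset(counts=counts, normalized=normalized, factors=factors,
                            design=design, truth=truth, catalog=catalog, dag=dag,
                            depths=depths, patterns=patterns, config=config)


def write_dataset(dataset: SimulatedDataset, out_dir) -> None:
    """Write counts.tsv, normalized.tsv, design.tsv, anno.tsv, dag.tsv and
    truth.tsv under ``out_dir``."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    j = os.path.join
    dataset.counts.values.rename_axis("gene").to_csv(j(out_dir, "counts.tsv"), sep="\t")
    dataset.normalized.values.rename_axis("gene").to_csv(j(out_dir, "normalized.tsv"), sep="\t")
    dataset.design.table.rename_axis("sample").to_csv(j(out_dir, "design.tsv"), sep="\t")
    with open(j(out_dir, "anno.tsv"), "w") as fh:
        for sid in sorted(dataset.catalog.set_ids):
            if dataset.dag is not None and dataset.dag.graph.in_degree(sid) > 0:
                continue  # only leaf annotations; readers re-propagate
            for g in sorted(dataset.catalog.members[sid]):
                fh.write(f"{g}\t{sid}\n")
    with open(j(out_dir, "dag.tsv"), "w") as fh:
        for c, p in sorted(dataset.dag.graph.edges):
            fh.write(f"{c}\t{p}\n")
    dataset.truth.to_csv(j(out_dir, "truth.tsv"), sep="\t")
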