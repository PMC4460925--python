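"""Metric suite and benchmark harness for the simulation study.

Selection is scored by precision / recall against the simulated DE genes;
clustering by maximum-intersection matching (C-precision / C-recall) and
normalized mutual information; replicate stability by the three-way list
intersection divided by the smallest list size.  :func:`run_benchmark`
repeats simulate -> analyse -> score over many datasets and aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bounded_area import BoundedArea
from .pipeline import FunPat, FunPatResults
from .simulate import SimulatedDataset, SimulationConfig, generate

__all__ = [
    "precision_recall",
    "match_and_score_clusters",
    "nmi",
    "reproducibility",
    "BenchmarkReport",
    "run_benchmark",
    "comparator_clusters",
]


def precision_recall(selected, truth_de, n_truth: int) -> tuple[float, float]:
    """Precision = TP / |selected| (1.0 for an empty selection: no false
    positives), recall = TP / n_truth."""
    if n_truth == 0:
        raise ValueError("n_truth must be positive")
    selected = set(selected)
    tp = len(selected & set(truth_de))
    precision = 1.0 if not selected else tp / len(selected)
    return precision, tp / n_truth


def match_and_score_clusters(found: dict[object, set], truth: dict[object, set],
                             truth_size_per_cluster: int | None = None) -> pd.DataFrame:
    """Match each found cluster to the truth cluster of maximum intersection
    (ties -> lowest truth key) and score it.

    C-precision = TP / |found cluster|; C-recall = TP / truth cluster size
    (or ``truth_size_per_cluster`` when given, e.g. the simulated 20).
    """
    truth_keys = sorted(truth)
    rows = []
    for fid in found:
        fset = set(found[fid])
        if not fset:
            continue
        inter = [(len(fset & set(truth[t])), t) for t in truth_keys]
        tp, best = max(inter, key=lambda it: (it[0], -truth_keys.index(it[1])))
        denom = truth_size_per_cluster or len(truth[best])
        rows.append((fid, best, tp, tp / len(fset), tp / denom))
    return pd.DataFrame(rows, columns=["found", "matched_truth", "tp",
                                       "c_precision", "c_recall"]).set_index("found")


def nmi(labels_a, labels_b, average: str = "arithmetic") -> float:
    """Normalized mutual information between two labelings of the same
    items, from the contingency table; MI is normalized by the arithmetic
    (default) or geometric mean of the two entropies.  Degenerate
    single-class labelings give 0."""
    a = pd.Series(list(labels_a))
    b = pd.Series(list(labels_b))
    if len(a) != len(b):
        raise ValueError("labelings must cover the same items")
    n = len(a)
    if n == 0:
        return 0.0
    table = pd.crosstab(a, b).to_numpy(float)
    pij = table / n
    pi = pij.sum(axis=1, keepdims=True)
    pj = pij.sum(axis=0, keepdims=True)
    nz = pij > 0
    mi = float((pij[nz] * np.log(pij[nz] / (pi @ pj)[nz])).sum())
    ha = float(-(pi[pi > 0] * np.log(pi[pi > 0])).sum())
    hb = float(-(pj[pj > 0] * np.log(pj[pj > 0])).sum())
    if average == "arithmetic":
        denom = 0.5 * (ha + hb)
    elif average == "geometric":
        denom = np.sqrt(ha * hb)
    else:
        raise ValueError("average must be 'arithmetic' or 'geometric'")
    if denom == 0:
        return 0.0
    return float(np.clip(mi / denom, 0.0, 1.0))


def reproducibility(lists) -> float:
    """|intersection of the lists| / min list size; 0 if any list is empty."""
    sets = [set(l) for l in lists]
    if len(sets) < 2:
        raise ValueError("need at least 2 lists")
    if any(not s for s in sets):
        return 0.0
    inter = set.intersection(*sets)
    return len(inter) / min(len(s) for s in sets)


# ---------------------------------------------------------------------------
# comparator clusterings (harness baselines only)

def comparator_clusters(profiles: pd.DataFrame, n_clusters: int,
                        method: str, seed: int | None = 0) -> dict[str, set]:
    """Hierarchical (Euclidean, average linkage) or k-means (10 restarts)
    baseline clustering of gene profiles."""
    from sklearn.cluster import AgglomerativeClustering, KMeans

    x = profiles.to_numpy(float)
    k = max(1, min(n_clusters, len(profiles)))
    if method == "hierarchical":
        labels = AgglomerativeClustering(n_clusters=k, linkage="average").fit_predict(x)
    elif method == "kmeans":
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(x)
    else:
        raise ValueError(f"unknown method {method!r}")
    out: dict[str, set] = {}
    for g, lab in zip(profiles.index, labels):
        out.setdefault(f"{method}{lab}", set()).add(g)
    return out


# ---------------------------------------------------------------------------
# benchmark harness

_KNOWN_METHODS = ("funpat", "bounded_area_only", "hierarchical", "kmeans")


@dataclass
class BenchmarkReport:
    """Per-dataset metrics plus across-dataset means."""

    per_dataset: pd.DataFrame
    config: SimulationConfig

    def means(self) -> pd.Series:
        return self.per_dataset.mean(numeric_only=True)

    def summary(self) -> str:
        m = self.means()
        lines = ["Simulation benchmark", "====================",
                 f"datasets: {len(self.per_dataset)}"]
        lines += [f"{k:28s} {v:8.4f}" for k, v in m.items()]
        return "\n".join(lines)

    def to_files(self, out_dir) -> None:
        import json, os

        os.makedirs(out_dir, exist_ok=True)
        self.per_dataset.to_csv(os.path.join(out_dir, "report.tsv"), sep="\t")
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump({k: float(v) for k, v in self.means().items()}, fh, indent=1)


def _clustering_scores(result: FunPatResults, dataset: SimulatedDataset,
                       found: dict | None = None) -> tuple[float, float, float, int]:
    """C-precision / C-recall / NMI of a found partition vs the simulated
    one.  NMI labels live on the selected (DE-list) genes: truth label =
    simulated pattern (or "nonDE"), found label = cluster (or "none")."""
    truth_part = dataset.truth_partition()
    if found is None:
        found = result.main_partition()
    if not found:
        return np.nan, np.nan, 0.0, 0
    per_cluster = match_and_score_clusters(found, truth_part,
                                           dataset.config.de_per_pattern)
    member_of = {g: cid for cid, genes in found.items() for g in genes}
    truth_of = {g: int(j) for j, genes in truth_part.items() for g in genes}
    universe = sorted(set(result.de_genes) | set(member_of))
    la = [truth_of.get(g, "nonDE") for g in universe]
    lb = [member_of.get(g, "none") for g in universe]
    return (float(per_cluster.c_precision.mean()),
            float(per_cluster.c_recall.mean()),
            nmi(la, lb), len(found))


def _single_replicate_runs(dataset: SimulatedDataset, seed: int,
                           funpat_kw: dict) -> dict[str, float]:
    """Apply the pipeline (and seeds-only selection) independently to each
    replicate, in data-poor mode, and score stability."""
    from .normalize import tmm_normalize

    de_lists, seed_counts, seed_recalls = [], [], []
    truth_de = set(dataset.de_genes)
    reps = sorted(dataset.design.table.replicate.unique())
    for i, rep in enumerate(reps):
        design_r = dataset.design.subset_replicate(rep)
        counts_r = dataset.counts.subset_samples(design_r.samples)
        norm_r, _ = tmm_normalize(counts_r)
        res = FunPat(norm_r, design_r, dataset.catalog, dataset.dag,
                     data_poor=True, **funpat_kw).fit(seed + i)
        de_lists.append(res.de_genes)
        seed_counts.append(len(res.seeds))
        seed_recalls.append(len(set(res.seeds) & truth_de) / len(truth_de))
    return {
        "reproducibility": reproducibility(de_lists),
        "sr_ba_n_selected": float(np.mean(seed_counts)),
        "sr_ba_recall": float(np.mean(seed_recalls)),
    }


def run_benchmark(n_datasets: int, config: SimulationConfig | None = None,
                  methods=("funpat", "bounded_area_only"), seed: int = 0,
                  single_replicate: bool = True,
                  funpat_kw: dict | None = None) -> BenchmarkReport:
    """Simulate ``n_datasets`` datasets, run the requested methods and score
    them against the truth.

    Methods: ``funpat`` (full pipeline), ``bounded_area_only`` (seeds at the
    FDR threshold, no rescue), ``hierarchical`` / ``kmeans`` (baseline
    clusterings of the genes selected by the pipeline, with the number of
    clusters set by the pipeline's output).  ``single_replicate`` adds the
    data-poor per-replicate runs (reproducibility and seeds-only counts).
    """
    unknown = set(methods) - set(_KNOWN_METHODS)
    if unknown:
        raise ValueError(f"unknown method(s): {sorted(unknown)}")
    config = config or SimulationConfig()
    funpat_kw = dict(funpat_kw or {})
    ss = np.random.SeedSequence(seed)
    dataset_seeds = [int(s) for s in ss.generate_state(2 * n_datasets) % (2**31)]
    rows = []
    for d in range(n_datasets):
        sim_seed, fit_seed = dataset_seeds[2 * d], dataset_seeds[2 * d + 1]
        dataset = generate(replace(config, seed=sim_seed))
        truth_de = dataset.de_genes
        row: dict[str, float] = {"dataset": d, "sim_seed": sim_seed}
        result = FunPat(dataset.normalized, dataset.design, dataset.catalog,
                        dataset.dag, **funpat_kw).fit(fit_seed)
        if "funpat" in methods:
            p, r = precision_recall(result.de_genes, truth_de, len(truth_de))
            row["funpat_precision"], row["funpat_recall"] = p, r
            cp, cr, mi, k = _clustering_scores(result, dataset)
            row.update(c_precision=cp, c_recall=cr, nmi=mi, n_clusters=k)
        if "bounded_area_only" in methods:
            p, r = precision_recall(result.seeds, truth_de, len(truth_de))
            row["ba_precision"], row["ba_recall"] = p, r
        for method in ("hierarchical", "kmeans"):
            if method in methods and result.de_genes:
                found = comparator_clusters(result.profiles.loc[result.de_genes],
                                            max(len(result.main_partition()), 1),
                                            method, seed=fit_seed)
                cp, cr, mi, _ = _clustering_scores(result, dataset, found)
                row[f"{method}_c_precision"] = cp
                row[f"{method}_c_recall"] = cr
                row[f"{method}_nmi"] = mi
        if single_replicate:
            row.update(_single_replicate_runs(dataset, fit_seed, funpat_kw))
        rows.append(row)
    return BenchmarkReport(pd.DataFrame(rows).set_index("dataset"), config)
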