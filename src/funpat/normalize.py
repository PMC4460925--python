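"""Between-sample normalization and log-scale profile transforms.

TMM (trimmed mean of M-values) computes one scaling factor per sample from a
doubly trimmed, precision-weighted mean of gene-wise log expression ratios
against a reference sample.  Factors are rescaled to geometric mean 1, turned
into effective library sizes, and the effective sizes are further rescaled by
their median so that normalized values stay on the count scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ExpressionSeries, SampleDesign

__all__ = ["tmm_factors", "tmm_normalize", "log2_expression", "log_ratio_profiles",
           "condition_mean_profiles"]

# default trim fractions on M-values (log ratios) and A-values (log abundances)
TRIM_M = 0.30
TRIM_A = 0.05


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray, trim_m: float, trim_a: float) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2**)."""
    n_obs, n_ref = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep] / n_obs, ref[keep] / n_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # precision weights from the delta method on binomial counts
    w = (n_obs - obs[keep]) / (n_obs * obs[keep]) + (n_ref - ref[keep]) / (n_ref * ref[keep])
    n = len(m)
    if n == 0:
        return 1.0
    rank_m = m.argsort().argsort()
    rank_a = a.argsort().argsort()
    lo_m, hi_m = np.floor(n * trim_m), np.ceil(n * (1 - trim_m)) - 1
    lo_a, hi_a = np.floor(n * trim_a), np.ceil(n * (1 - trim_a)) - 1
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame, trim_m: float = TRIM_M, trim_a: float = TRIM_A) -> pd.Series:
    """Per-sample TMM scaling factors, geometric mean 1.

    The reference sample is the one whose 75th percentile of library-size
    scaled counts is closest to the mean such percentile across samples.
    """
    arr = counts.to_numpy(float)
    if arr.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    libsize = arr.sum(axis=0)
    if (libsize == 0).any():
        bad = counts.columns[libsize == 0]
        raise ValueError(f"all-zero sample(s): {list(bad)}")
    uq = np.array([np.quantile(arr[:, j] / libsize[j], 0.75) for j in range(arr.shape[1])])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array([
        1.0 if j == ref_idx else _tmm_pair_factor(arr[:, j], arr[:, ref_idx], trim_m, trim_a)
        for j in range(arr.shape[1])
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def tmm_normalize(expr: ExpressionSeries, trim_m: float = TRIM_M,
                  trim_a: float = TRIM_A) -> tuple[ExpressionSeries, pd.Series]:
    """TMM-normalize raw counts.

    Effective library sizes (library size x factor) are rescaled by their
    median, and each sample is divided by its rescaled effective size, so the
    output stays on the scale of counts in a median-depth library.
    """
    if expr.scale != "raw":
        raise ValueError("tmm_normalize expects raw counts")
    factors = tmm_factors(expr.values, trim_m, trim_a)
    libsize = expr.values.sum(axis=0)
    eff = libsize * factors
    scaling = eff / np.median(eff)
    normalized = expr.values / scaling
    return ExpressionSeries(normalized, scale="normalized"), factors


def log2_expression(expr: ExpressionSeries, pseudocount: float = 1.0) -> ExpressionSeries:
    """log2(x + c) transform of count-scale expression."""
    if expr.scale == "log2":
        return expr
    return ExpressionSeries(np.log2(expr.values + pseudocount), scale="log2")


def condition_mean_profiles(expr: ExpressionSeries, design: SampleDesign,
                            pseudocount: float = 1.0) -> dict[str, pd.DataFrame]:
    """Replicate-averaged log2 profiles per condition.

    Returns ``{condition: N x M DataFrame}`` of mean-over-replicates
    log2(x + c), columns ordered along the shared time grid.
    """
    logx = log2_expression(expr, pseudocount).values
    out = {}
    for cond in design.conditions:
        cols = {}
        for t in design.times:
            cols[t] = logx[design.samples_at(cond, t)].mean(axis=1)
        out[cond] = pd.DataFrame(cols)
    return out


def log_ratio_profiles(expr: ExpressionSeries, design: SampleDesign,
                       pseudocount: float = 1.0,
                       treatment: str | None = None) -> pd.DataFrame:
    """N x M matrix of mean log2 fold-change (treatment minus control) over
    the time grid.

    ``treatment`` defaults to the lexicographically later condition label
    unless one of the two labels literally contains "treat".
    """
    profiles = condition_mean_profiles(expr, design, pseudocount)
    conds = design.conditions
    if treatment is None:
        named = [c for c in conds if "treat" in c.lower()]
        treatment = named[0] if named else conds[-1]
    if treatment not in conds:
        raise ValueError(f"unknown treatment condition {treatment!r}")
    control = next(c for c in conds if c != treatment)
    return profiles[treatment] - profiles[control]
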