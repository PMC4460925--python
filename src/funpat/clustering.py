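"""Linear model-based clustering of temporal expression profiles.

A cluster is a characteristic temporal pattern ``P`` (mean 0, max |value| 1 on
the shared time grid) together with member genes whose profiles are affine
transforms ``x = k * P + q`` plus noise.  Starting from a seed gene's profile,
the algorithm alternates (i) per-gene least-squares estimation of (k, q),
(ii) a membership update keeping the genes whose residuals pass both a
chi-square goodness-of-fit test and a one-sided Wald-Wolfowitz runs test and
whose slope on the pattern is significantly positive, and (iii) a weighted re-estimation of P from the members, until the
pattern stabilizes.  A cluster is significant only if it contains at least one
seed gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "fit_gene_params",
    "update_pattern",
    "runs_test_pvalue",
    "gene_fit_tests",
    "slope_test_pvalues",
    "normalize_pattern",
    "PatternModel",
    "extract_clusters",
]

_EPS_VAR = 1e-12
_EPS_RES = 1e-9  # residuals below this are numerical zeros (profiles are O(1))


def normalize_pattern(p: np.ndarray) -> np.ndarray:
    """Center to mean 0 and scale to max |value| 1 (resolves the k <-> P scale
    indeterminacy of the affine model)."""
    p = np.asarray(p, float)
    p = p - p.mean()
    m = np.abs(p).max()
    if m == 0:
        raise ValueError("degenerate pattern (constant profile)")
    return p / m


def fit_gene_params(profile, pattern) -> tuple[float, float, np.ndarray]:
    """Ordinary least squares of one profile on a pattern: x = k*P + q + res."""
    x = np.asarray(profile, float)
    p = np.asarray(pattern, float)
    if x.shape != p.shape or x.ndim != 1:
        raise ValueError("profile and pattern must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 time points")
    pc = p - p.mean()
    ss = np.dot(pc, pc)
    if ss == 0:
        raise ValueError("degenerate pattern (constant)")
    k = float(np.dot(pc, x) / ss)
    q = float(x.mean() - k * p.mean())
    return k, q, x - (k * p + q)


def _fit_all(profiles: np.ndarray, pattern: np.ndarray):
    """Vectorized OLS of many profiles on one pattern."""
    pc = pattern - pattern.mean()
    ss = np.dot(pc, pc)
    k = profiles @ pc / ss
    q = profiles.mean(axis=1) - k * pattern.mean()
    res = profiles - (np.outer(k, pattern) + q[:, None])
    return k, q, res


def update_pattern(profiles, ks, qs, noise_vars) -> np.ndarray:
    """Re-estimate the pattern from current members.

    Each member contributes its back-transformed profile (x - q) / k; since
    its error variance on the pattern scale is sigma_f^2 / k_f^2, the
    inverse-variance weight is k_f^2 / sigma_f^2, which algebraically removes
    the division by k and lets near-flat members (k -> 0) drop out smoothly.
    ``noise_vars`` is the modelled error variance of each member (the
    diagonal of the affine model's error term), not the member's observed
    residual variance: an anchor gene fits its own initialization profile
    with residuals ~0, and weighting by observed residuals would pin the
    pattern to that one noisy profile.
    """
    x = np.atleast_2d(np.asarray(profiles, float))
    k = np.atleast_1d(np.asarray(ks, float))
    q = np.atleast_1d(np.asarray(qs, float))
    v = np.maximum(np.atleast_1d(np.asarray(noise_vars, float)), _EPS_VAR)
    if np.all(k == 0):
        raise ValueError("all member slopes are zero")
    num = ((k / v)[:, None] * (x - q[:, None])).sum(axis=0)
    den = (k * k / v).sum()
    return normalize_pattern(num / den)


def runs_test_pvalue(signs: np.ndarray) -> float:
    """Exact lower-tail Wald-Wolfowitz runs test on a sign sequence.

    Too few runs indicate systematic (pattern-shaped) misfit.  Zeros must be
    removed by the caller; sequences with a single sign give p = 1.
    """
    signs = np.asarray(signs)
    n1 = int((signs > 0).sum())
    n2 = int((signs < 0).sum())
    if n1 == 0 or n2 == 0:
        return 1.0
    r_obs = 1 + int((signs[1:] != signs[:-1]).sum())
    total = comb(n1 + n2, n1)
    p = 0.0
    for r in range(2, r_obs + 1):
        if r % 2 == 0:
            kk = r // 2
            count = 2 * comb(n1 - 1, kk - 1) * comb(n2 - 1, kk - 1)
        else:
            kk = (r - 1) // 2
            count = (comb(n1 - 1, kk) * comb(n2 - 1, kk - 1)
                     + comb(n1 - 1, kk - 1) * comb(n2 - 1, kk))
        p += count / total
    return min(p, 1.0)


def gene_fit_tests(residuals, noise_sd, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Residual diagnostics for one gene against its expected noise level.

    Goodness of fit: sum((res / sigma)^2) on M - 2 degrees of freedom (upper
    tail).  Runs: exact lower-tail test on residual signs.  The gene passes
    when both p-values exceed ``alpha``.
    """
    res = np.asarray(residuals, float)
    sd = np.broadcast_to(np.asarray(noise_sd, float), res.shape)
    if np.any(sd == 0):
        if np.allclose(res, 0):
            return 1.0, 1.0, True
        return 0.0, runs_test_pvalue(np.sign(res[res != 0])), False
    stat = float(np.sum((res / sd) ** 2))
    gof_p = float(stats.chi2.sf(stat, df=len(res) - 2))
    nz = res[np.abs(res) > _EPS_RES]
    runs_p = runs_test_pvalue(np.sign(nz)) if len(nz) else 1.0
    return gof_p, runs_p, (gof_p > alpha) and (runs_p > alpha)


def slope_test_pvalues(k: np.ndarray, residual_vars: np.ndarray, pattern: np.ndarray,
                       df: int) -> np.ndarray:
    """One-sided p-values for H0: k = 0 against k > 0.

    Membership in a cluster requires the pattern to explain the profile, not
    merely residuals compatible with noise; an exactly fitting profile
    (zero residual variance) with positive slope gets p = 0.
    """
    pc = pattern - pattern.mean()
    ss = float(np.dot(pc, pc))
    v = np.asarray(residual_vars, float)
    k = np.asarray(k, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = k / np.sqrt(v / ss)
    p = stats.t.sf(t, df=df)
    exact = v <= _EPS_VAR
    return np.where(exact, np.where(k > 0, 0.0, 1.0), p)


@dataclass
class PatternModel:
    """One significant temporal pattern and its member genes."""

    pattern: np.ndarray
    members: pd.DataFrame  # index gene; columns k, q, residual_var, gof_p, runs_p, slope_p
    contains_seed: bool
    set_id: str | None = None
    n_iter: int = 0
    converged: bool = True
    pattern_id: str | None = None
    pattern_sd: float = 0.0  # estimation sd of one pattern point

    @property
    def genes(self) -> list[str]:
        return list(self.members.index)

    def __len__(self) -> int:
        return len(self.members)


def extract_clusters(profiles: pd.DataFrame, seed_ids, *, noise_sd,
                     areas: pd.Series | None = None, alpha: float = 0.05,
                     slope_alpha: float = 0.01, min_members: int = 3,
                     runs_scope: str = "gene",
                     max_iter: int = 100, tol: float = 1e-6,
                     require_association: bool = True,
                     rng_seed: int | None = None) -> list[PatternModel]:
    """Iteratively extract seed-anchored pattern clusters from a gene pool.

    Parameters
    ----------
    profiles : DataFrame (gene x time) of temporal profiles (e.g. log
        fold-changes) for the pooled seeds and candidates of one gene set.
    seed_ids : genes allowed to anchor and validate clusters.
    noise_sd : float or Series per gene - expected noise sd of one profile
        point, used by the goodness-of-fit test.
    alpha : family-wise per-gene eviction level: the three membership
        criteria (goodness of fit, runs, association) are each applied at
        ``alpha / 3`` (Bonferroni split), so a genuine member is evicted
        with probability about ``alpha`` overall.
    areas : optional per-gene ranking statistic; the unassigned seed with the
        largest value initializes each new pattern (falls back to input
        order).
    require_association : besides the residual tests, members must show a
        significantly positive slope on the pattern (one-sided t-test at
        ``slope_alpha``); this keeps marginal noise profiles out and keeps
        the pattern orientation meaningful (anti-correlated genes can anchor
        their own mirrored cluster).  ``slope_alpha`` defaults an order of
        magnitude below ``alpha`` because every gene in the pool is retested
        against each successive pattern, multiplying its chances to join one
        by luck.
    min_members : a pattern is a co-expression cluster; below this size it is
        not emitted (a lone seed stays differentially expressed as a seed).
    runs_scope : "gene" applies the runs test per member; "cluster" applies
        it once per cluster (Fisher-combined member p-values at ``alpha``),
        so a single member's unlucky sign sequence does not evict it.

    Admission is two-tier: a cluster must be *nucleated* by at least
    ``min_members`` genes (one of them a seed) whose association passes the
    strict ``slope_alpha``; once a pattern is established, genes passing the
    residual tests with association at the ordinary ``alpha`` join as
    members.  Nucleation guards against spurious clusters assembled from
    marginal profiles; the relaxed final admission keeps genuine members
    whose signal is weaker.
    rng_seed : accepted for interface stability; the procedure is
        deterministic given the input order.

    Emitted clusters are disjoint: members are removed from the pool.
    """
    if profiles.empty:
        return []
    pool = list(profiles.index)
    seed_set = [s for s in pool if s in set(seed_ids)]
    if areas is not None:
        rank = {g: (-areas.get(g, 0.0), i) for i, g in enumerate(pool)}
    else:
        rank = {g: (0.0, i) for i, g in enumerate(pool)}
    if np.isscalar(noise_sd):
        sd_of = pd.Series(float(noise_sd), index=profiles.index)
    else:
        sd_of = pd.Series(noise_sd).reindex(profiles.index)
    a3 = alpha / 3.0  # per-criterion level
    clusters: list[PatternModel] = []
    tried: set[str] = set()
    pool_set = set(pool)
    while True:
        anchors = sorted((s for s in seed_set if s in pool_set and s not in tried),
                         key=lambda g: rank[g])
        if not anchors:
            break
        anchor = anchors[0]
        try:
            pattern = normalize_pattern(profiles.loc[anchor].to_numpy())
        except ValueError:
            tried.add(anchor)
            continue
        sub = profiles.loc[[g for g in pool if g in pool_set]]
        x = sub.to_numpy(float)
        sds = sd_of.loc[sub.index].to_numpy(float)
        members_idx: np.ndarray | None = None
        n_iter, converged = 0, False
        for n_iter in range(1, max_iter + 1):
            k, q, res = _fit_all(x, pattern)
            m = x.shape[1]
            stat = np.sum((res / np.where(sds[:, None] == 0, np.inf, sds[:, None])) ** 2, axis=1)
            gof_p = stats.chi2.sf(stat, df=m - 2)
            zero_sd = sds == 0
            if zero_sd.any():
                exact = np.abs(res).max(axis=1) < 1e-12
                gof_p = np.where(zero_sd, np.where(exact, 1.0, 0.0), gof_p)
            runs_p = np.array([
                runs_test_pvalue(np.sign(rr[np.abs(rr) > _EPS_RES]))
                if np.any(np.abs(rr) > _EPS_RES) else 1.0
                for rr in res])
            ok = gof_p > a3
            if runs_scope == "gene":
                ok &= runs_p > a3
            resvar = np.sum(res ** 2, axis=1) / max(m - 2, 1)
            if require_association:
                ok &= slope_test_pvalues(k, resvar, pattern, m - 2) <= slope_alpha
            new_members = np.flatnonzero(ok)
            if len(new_members) == 0:
                members_idx = None
                break
            try:
                new_pattern = update_pattern(x[new_members], k[new_members],
                                             q[new_members], sds[new_members] ** 2)
            except ValueError:
                members_idx = None
                break
            same_members = (members_idx is not None
                            and np.array_equal(new_members, members_idx))
            delta = np.abs(new_pattern - pattern).max()
            pattern, members_idx = new_pattern, new_members
            if same_members and delta < tol:
                converged = True
                break
        if members_idx is None or len(members_idx) == 0:
            tried.add(anchor)
            continue
        # final membership pass against the converged pattern, so every
        # emitted member is guaranteed to pass both tests on that pattern
        k, q, res = _fit_all(x, pattern)
        mm = sub.shape[1]
        gof = stats.chi2.sf(
            np.sum((res / np.where(sds[:, None] == 0, np.inf, sds[:, None])) ** 2, axis=1),
            df=mm - 2)
        zero_sd = sds == 0
        if zero_sd.any():
            exact = np.abs(res).max(axis=1) < 1e-12
            gof = np.where(zero_sd, np.where(exact, 1.0, 0.0), gof)
        runs = np.array([
            runs_test_pvalue(np.sign(rr[np.abs(rr) > _EPS_RES]))
            if np.any(np.abs(rr) > _EPS_RES) else 1.0 for rr in res])
        resvar = np.sum(res ** 2, axis=1) / max(mm - 2, 1)
        slope_p = slope_test_pvalues(k, resvar, pattern, mm - 2)
        ok = gof > a3
        if runs_scope == "gene":
            ok &= runs > a3
        if require_association:
            nucleus = ok & (slope_p <= slope_alpha)
            ok &= slope_p <= max(a3, slope_alpha)
        else:
            nucleus = ok
        seed_ok = {g for g in sub.index[np.flatnonzero(nucleus)]} & set(seed_set)
        if np.count_nonzero(nucleus) < min_members or not seed_ok:
            tried.add(anchor)
            continue
        members_idx = np.flatnonzero(ok)
        member_genes = list(sub.index[members_idx])
        if runs_scope == "cluster" and len(members_idx):
            # Fisher-combined runs test across members
            pr = np.clip(runs[members_idx], 1e-300, 1.0)
            stat_f = -2.0 * np.log(pr).sum()
            if stats.chi2.sf(stat_f, 2 * len(pr)) <= alpha:
                tried.add(anchor)
                continue
        members = pd.DataFrame({
            "k": k[members_idx], "q": q[members_idx],
            "residual_var": resvar[members_idx],
            "gof_p": gof[members_idx], "runs_p": runs[members_idx],
            "slope_p": slope_p[members_idx],
        }, index=member_genes)
        info = np.sum(k[members_idx] ** 2 / np.maximum(sds[members_idx] ** 2, _EPS_VAR))
        clusters.append(PatternModel(pattern=pattern, members=members,
                                     contains_seed=True, n_iter=n_iter,
                                     converged=converged,
                                     pattern_sd=float(1.0 / np.sqrt(info))))
        pool_set -= set(member_genes)
    return clusters
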