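"""Area statistic, replicate noise model, Monte-Carlo null and selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from funpat.bounded_area import (BoundedArea, NoiseModel, assign_pvalues,
                                 compute_area, fit_noise_model,
                                 fit_null_distribution, null_area_scale,
                                 piecewise_linear_areas, sample_null,
                                 select_seeds_candidates)
from funpat.core import ExpressionSeries

from conftest import make_design, make_expression


# ---------------------------------------------------------------------------
# area statistic

class TestComputeArea:
    def test_identical_profiles_give_zero(self):
        assert compute_area([0, 1, 2], [1, 1, 1], [1, 1, 1]) == 0.0

    def test_constant_gap(self):
        assert compute_area([0, 1, 2], [0, 0, 0], [1, 1, 1]) == pytest.approx(2.0)

    def test_crossing_splits_into_triangles(self):
        # crossing at t=1: two triangles of area 1/2 each
        assert compute_area([0, 2], [0, 1], [1, 0]) == pytest.approx(1.0)

    def test_non_uniform_time_spacing(self):
        # gap of 1 over a span of 10, trapezoid on the real grid
        assert compute_area([0.0, 0.5, 10.0], [1, 1, 1], [0, 0, 0]) == pytest.approx(10.0)

    def test_requires_two_points(self):
        with pytest.raises(ValueError, match="2 time points"):
            compute_area([0.0], [1.0], [2.0])

    def test_requires_increasing_times(self):
        with pytest.raises(ValueError, match="increasing"):
            compute_area([0, 2, 1], [1, 1, 1], [0, 0, 0])

    @given(st.lists(st.tuples(
        st.floats(-50, 50), st.floats(-50, 50)), min_size=2, max_size=10),
        st.floats(-100, 100))
    @settings(max_examples=200, deadline=None)
    def test_symmetry_shift_invariance_and_quadrature(self, pairs, shift):
        """Exact area equals numerical quadrature of |a-b| on a dense grid and
        is symmetric in its arguments and invariant to common shifts."""
        times = np.arange(len(pairs), dtype=float)
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        area = compute_area(times, a, b)
        assert area == pytest.approx(compute_area(times, b, a), abs=1e-9)
        assert compute_area(times, a + shift, b + shift) == pytest.approx(area, rel=1e-9, abs=1e-9)
        dense = np.linspace(times[0], times[-1], 20001)
        gap = np.abs(np.interp(dense, times, a) - np.interp(dense, times, b))
        assert area == pytest.approx(np.trapezoid(gap, dense), abs=1e-3 * (1 + area))

    def test_vectorized_matches_scalar(self, rng):
        times = np.sort(rng.uniform(0, 10, 6))
        times[0] = 0.0
        diffs = rng.normal(size=(40, 6))
        vec = piecewise_linear_areas(times, diffs)
        for i in range(40):
            assert vec[i] == pytest.approx(
                compute_area(times, diffs[i], np.zeros(6)), abs=1e-12)


# ---------------------------------------------------------------------------
# noise model

def _replicated_expression(sd_fn, n_genes, design, rng):
    means = rng.uniform(2, 12, size=n_genes)
    sds = np.broadcast_to(np.asarray(sd_fn(means), float), means.shape)
    cols = {}
    for s in design.samples:
        cols[s] = means + rng.normal(0, sds)
    genes = [f"g{i}" for i in range(n_genes)]
    return ExpressionSeries(pd.DataFrame(cols, index=genes), scale="log2")


class TestNoiseModel:
    def test_constant_sd_recovered(self, rng):
        design = make_design(n_times=5, n_reps=2)
        expr = _replicated_expression(lambda m: 0.5, 10_000, design, rng)
        nm = fit_noise_model(expr, design)
        assert np.all(nm.bin_sds >= 0.4) and np.all(nm.bin_sds <= 0.6)

    def test_exact_duplicates_give_zero_sd(self, rng):
        design = make_design(n_times=3, n_reps=2)
        expr = _replicated_expression(lambda m: 0.0, 500, design, rng)
        nm = fit_noise_model(expr, design)
        np.testing.assert_allclose(nm.bin_sds, 0.0, atol=1e-12)

    def test_decreasing_sd_vs_mean_recovered(self, rng):
        design = make_design(n_times=5, n_reps=2)
        expr = _replicated_expression(lambda m: 0.2 + 1.0 / np.sqrt(m), 5_000, design, rng)
        nm = fit_noise_model(expr, design)
        rho = stats.spearmanr(nm.bin_centers, nm.bin_sds).statistic
        assert rho < 0

    def test_no_replicates_without_data_poor_mode(self, rng):
        design = make_design(n_times=4, n_reps=1)
        expr = make_expression(design, n_genes=50, rng=rng)
        with pytest.raises(ValueError, match="data-poor"):
            fit_noise_model(expr, design, data_poor=False)

    def test_data_poor_mode_recovers_noise_floor(self, rng):
        # flat genes + adjacent-time pairs: robust estimator near the truth
        design = make_design(n_times=13, n_reps=1)
        expr = _replicated_expression(lambda m: 0.4, 5_000, design, rng)
        nm = fit_noise_model(expr, design, data_poor=True)
        assert nm.data_poor
        assert np.all(nm.bin_sds >= 0.3) and np.all(nm.bin_sds <= 0.5)

    def test_extrapolation_is_constant(self):
        nm = NoiseModel(np.array([2.0, 4.0]), np.array([0.6, 0.2]), n_pairs=10)
        assert nm.sd(-5.0) == pytest.approx(0.6)
        assert nm.sd(50.0) == pytest.approx(0.2)


# ---------------------------------------------------------------------------
# Monte-Carlo null

class TestSampleNull:
    def test_zero_noise_gives_zero_areas(self):
        nm = NoiseModel(np.array([0.0, 10.0]), np.array([0.0, 0.0]), n_pairs=10)
        samples = sample_null(nm, np.arange(5.0), np.ones((20, 5)), 1000, seed=0)
        np.testing.assert_allclose(samples, 0.0)

    def test_deterministic_under_seed(self):
        nm = NoiseModel(np.array([0.0, 10.0]), np.array([0.3, 0.3]), n_pairs=10)
        base = np.random.default_rng(1).uniform(1, 5, size=(30, 4))
        a = sample_null(nm, np.arange(4.0), base, 2000, seed=7)
        b = sample_null(nm, np.arange(4.0), base, 2000, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_rejects_small_b(self):
        nm = NoiseModel(np.array([0.0]), np.array([0.1]), n_pairs=1)
        with pytest.raises(ValueError, match="B"):
            sample_null(nm, np.arange(3.0), np.ones((2, 3)), 10, seed=0)

    def test_mean_matches_brute_force_oracle_m2(self):
        """M=2, one replicate, constant sd: E[A] from a large direct
        simulation of the defining construction."""
        sd = 0.5
        nm = NoiseModel(np.array([0.0]), np.array([sd]), n_pairs=1)
        times = np.array([0.0, 1.0])
        samples = sample_null(nm, times, np.zeros((1, 2)), 100_000, seed=3)
        # oracle: independent draw of the same geometry
        r = np.random.default_rng(99)
        d = r.normal(0, sd * np.sqrt(2), size=(1_000_000, 2))
        same = d[:, 0] * d[:, 1] >= 0
        areas = np.where(same, 0.5 * (np.abs(d[:, 0]) + np.abs(d[:, 1])),
                         0.5 * (d[:, 0] ** 2 + d[:, 1] ** 2) / (np.abs(d[:, 0]) + np.abs(d[:, 1])))
        se = samples.std() / np.sqrt(len(samples))
        assert abs(samples.mean() - areas.mean()) < 3 * se


class TestFitNullDistribution:
    def test_gamma_samples_recovered(self):
        x = stats.gamma(2.0, scale=1.0).rvs(size=100_000, random_state=1)
        null = fit_null_distribution(x)
        assert null.family == "gamma"
        assert null.params[0] == pytest.approx(2.0, rel=0.05)
        assert null.params[1] == pytest.approx(1.0, rel=0.05)

    def test_lognormal_samples_recovered(self):
        x = stats.lognorm(1.0, scale=1.0).rvs(size=100_000, random_state=2)
        assert fit_null_distribution(x).family == "lognormal"

    def test_weibull_samples_recovered(self):
        x = stats.weibull_min(1.7, scale=2.0).rvs(size=100_000, random_state=3)
        assert fit_null_distribution(x).family == "weibull"

    def test_degenerate_samples_force_empirical(self):
        null = fit_null_distribution(np.full(5000, 3.0))
        assert null.family == "empirical"
        null0 = fit_null_distribution(np.zeros(5000))
        assert null0.family == "empirical"


class TestAssignPvalues:
    def test_zero_area_has_p_one(self):
        null = fit_null_distribution(stats.gamma(2.0).rvs(size=5000, random_state=0))
        scores = assign_pvalues(pd.Series([0.0], index=["g"]), null)
        assert scores.pvalue.iloc[0] == 1.0
        emp = assign_pvalues(pd.Series([0.0], index=["g"]), null, mode="empirical")
        assert emp.pvalue.iloc[0] == 1.0

    def test_empirical_add_one_rule(self):
        samples = np.linspace(0.001, 1.0, 999)
        null = fit_null_distribution(samples)  # < 1000 positive -> empirical
        assert null.family == "empirical"
        scores = assign_pvalues(pd.Series([2.0], index=["g"]), null, mode="empirical")
        assert scores.pvalue.iloc[0] == pytest.approx(1 / 1000)

    def test_empirical_pvalues_never_zero(self, rng):
        samples = rng.gamma(2.0, size=2000)
        null = fit_null_distribution(samples)
        p = null.pvalue(rng.uniform(0, 50, size=500), mode="empirical")
        assert (p > 0).all()

    def test_parametric_tail_matches_quadrature(self):
        x = stats.gamma(2.5, scale=0.8).rvs(size=50_000, random_state=4)
        null = fit_null_distribution(x)
        assert null.family == "gamma"
        shape, scale = null.params
        for a in (1.0, 3.0, 6.0):
            quad, _ = integrate.quad(lambda v: stats.gamma(shape, scale=scale).pdf(v),
                                     a, np.inf)
            assert null.pvalue([a])[0] == pytest.approx(quad, rel=1e-6)


def bh_oracle(pvals):
    """Step-by-step Benjamini-Hochberg: sorted p * n / rank, cumulative min
    from the largest rank, capped at 1."""
    n = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * n / rank)
        adj[i] = running
    return adj


class TestSelection:
    def test_bh_matches_stepwise_oracle(self, rng):
        p = np.concatenate([np.full(10, 0.001), np.full(90, 0.5)])
        null = fit_null_distribution(stats.gamma(2.0).rvs(size=5000, random_state=0))
        areas = pd.Series(null.dist.isf(p), index=[f"g{i}" for i in range(100)])
        scores = assign_pvalues(areas, null)
        np.testing.assert_allclose(scores.padj, bh_oracle(scores.pvalue.to_numpy()),
                                   rtol=1e-9)
        scores = select_seeds_candidates(scores, 0.05, 0.05)
        assert scores.is_seed.sum() == 10

    def test_adjusted_at_least_nominal(self, rng):
        null = fit_null_distribution(rng.gamma(2.0, size=5000))
        scores = assign_pvalues(pd.Series(rng.gamma(2.0, size=300)), null)
        assert (scores.padj >= scores.pvalue - 1e-12).all()

    def test_all_p_one_selects_nothing(self):
        scores = pd.DataFrame({"pvalue": [1.0] * 5, "padj": [1.0] * 5})
        out = select_seeds_candidates(scores)
        assert not out.is_seed.any() and not out.is_candidate.any()

    def test_soft_threshold_one_makes_all_candidates(self):
        scores = pd.DataFrame({"pvalue": [0.2, 0.9], "padj": [0.4, 0.9]})
        out = select_seeds_candidates(scores, soft_threshold=1.0)
        assert out.is_candidate.all()

    def test_seeds_are_candidates(self):
        scores = pd.DataFrame({"pvalue": [0.04, 0.2], "padj": [0.05, 0.3]})
        out = select_seeds_candidates(scores, fdr_threshold=0.05, soft_threshold=0.01)
        assert out.is_seed.iloc[0] and out.is_candidate.iloc[0]

    def test_threshold_validation(self):
        scores = pd.DataFrame({"pvalue": [0.5], "padj": [0.5]})
        with pytest.raises(ValueError):
            select_seeds_candidates(scores, fdr_threshold=0.0)
        with pytest.raises(ValueError):
            select_seeds_candidates(scores, soft_threshold=1.5)


# ---------------------------------------------------------------------------
# end-to-end calibration

class TestCalibration:
    def test_type_one_error_within_binomial_bounds(self, rng):
        """Null-only data simulated from the noise model: the fraction of
        nominal p-values below alpha stays inside 99% binomial bounds."""
        n_genes, m, reps = 4000, 8, 3
        design = make_design(n_times=m, n_reps=reps)
        sd_fn = lambda mu: 0.2 + 1.5 / np.sqrt(np.maximum(2.0 ** mu, 1.0))
        base = rng.uniform(5, 12, size=n_genes)  # keeps 2**x - 1 positive
        cols = {}
        for s in design.samples:
            cols[s] = base + rng.normal(0, sd_fn(base))
        expr = ExpressionSeries(
            pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)]),
            scale="log2")
        # feed the log-scale data directly: 2**x - 1 undoes the log transform
        lin = ExpressionSeries(2.0 ** expr.values - 1.0, scale="normalized")
        res = BoundedArea(lin, design, n_null=20_000).fit(seed=11)
        p = res.scores.pvalue.to_numpy()
        for alpha in (0.01, 0.05):
            half = 2.576 * np.sqrt(alpha * (1 - alpha) / n_genes)
            assert abs((p <= alpha).mean() - alpha) < half

    def test_fit_is_reproducible_under_seed(self, rng):
        design = make_design(n_times=5, n_reps=2)
        expr = make_expression(design, n_genes=300, rng=rng)
        a = BoundedArea(expr, design, n_null=2000).fit(seed=5)
        b = BoundedArea(expr, design, n_null=2000).fit(seed=5)
        pd.testing.assert_frame_equal(a.scores, b.scores)

    def test_null_area_scale_tracks_noise_level(self):
        nm = NoiseModel(np.array([2.0, 10.0]), np.array([1.0, 0.1]), n_pairs=10)
        times = np.arange(5.0)
        low = null_area_scale(nm, times, np.full((1, 5), 2.0), 3, 3)
        high = null_area_scale(nm, times, np.full((1, 5), 10.0), 3, 3)
        assert low[0] > high[0]
        assert low[0] == pytest.approx(1.0 * np.sqrt(2 / 3) * 4.0)
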