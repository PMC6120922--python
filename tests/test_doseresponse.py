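"""Session classification, Bayesian logistic dose-response, subsampling."""
import numpy as np
import pytest

from covattn import (LogisticPosterior, classify_session_significance,
                     fit_bayesian_logistic, posterior_predictive,
                     predictive_midpoint, subsample_control)


def cell_counts(rates, n=100):
    return {cell: (int(round(r * n)), n) for cell, r in rates.items()}


CELLS = [("in", "before"), ("out", "before"), ("in", "during"), ("out", "during")]


class TestClassification:
    def test_strong_deficit_classified(self):
        counts = cell_counts(dict(zip(CELLS, (0.9, 0.9, 0.2, 0.9))))
        y, p, deltas = classify_session_significance(counts, seed=1)
        assert y == 1
        # every binomial resample keeps the huge positive asymmetry
        assert np.all(deltas > 0)
        assert p < 1e-10

    def test_null_sessions_rarely_flagged(self):
        # noisy sham sessions: counts drawn around a common baseline rate
        rng = np.random.default_rng(42)
        flags = []
        for k in range(100):
            counts = {cell: (int(rng.binomial(160, 0.72)), 160) for cell in CELLS}
            flags.append(classify_session_significance(counts, seed=k)[0])
        assert sum(flags) <= 1

    def test_boundary_rates_defined(self):
        counts = cell_counts(dict(zip(CELLS, (1.0, 1.0, 0.0, 1.0))))
        y, p, _ = classify_session_significance(counts, seed=0)
        assert y in (0, 1) and 0 <= p <= 1

    def test_empty_cell_rejected(self):
        counts = cell_counts(dict(zip(CELLS, (0.5, 0.5, 0.5, 0.5))))
        counts[("in", "before")] = (0, 0)
        with pytest.raises(ValueError, match="change trials"):
            classify_session_significance(counts)


def point_mass_posterior(w0, w1):
    return LogisticPosterior(w_map=np.array([w0, w1]),
                             laplace_cov=np.zeros((2, 2)),
                             prior_sd=10.0, n=10, x_mean=-w0 / w1 if w1 else 0.0,
                             x_scale=30.0)


class TestLogisticFit:
    def test_null_labels_give_flat_slope(self):
        # labels independent of x: the slope should sit within its own
        # posterior uncertainty in the usual ~95% of replicates
        ok = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = r.uniform(0, 130, 200)
            y = r.integers(0, 2, 200)
            post = fit_bayesian_logistic(x, y)
            ok += abs(post.w_map[1]) < 2 * np.sqrt(post.laplace_cov[1, 1])
        assert ok >= 8

    def test_separated_data_bounded_by_prior(self):
        x = np.linspace(0, 130, 30)
        y = (x > 80).astype(int)
        post = fit_bayesian_logistic(x, y)
        assert np.isfinite(post.w_map).all()
        assert post.w_map[1] > 0
        # oracle: penalized likelihood on a coarse standardized-weight grid
        xs = (x - x.mean()) / x.std()

        def objective(w0, w1):
            eta = w0 + w1 * xs
            return (np.sum(y * eta - np.logaddexp(0, eta))
                    - (w0 ** 2 + w1 ** 2) / (2 * 10.0 ** 2))

        grid = np.linspace(-12, 12, 61)
        best = max(objective(a, b) for a in grid for b in grid)
        w_std = np.array([post.w_map[0] + post.w_map[1] * x.mean(),
                          post.w_map[1] * x.std()])
        assert objective(*w_std) >= best - 1e-6

    def test_sigmoid_recovery(self, rng):
        w0, w1 = -4.0, 0.05
        x = rng.uniform(0, 150, 300)
        y = (rng.random(300) < 1 / (1 + np.exp(-(w0 + w1 * x)))).astype(int)
        post = fit_bayesian_logistic(x, y)
        assert post.w_map[1] == pytest.approx(w1, abs=2 * np.sqrt(post.laplace_cov[1, 1]))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_bayesian_logistic([1, 2, 3], [0, 1, 1])
        with pytest.raises(ValueError, match="binary"):
            fit_bayesian_logistic([1, 2, 3, 4, 5], [0, 1, 2, 1, 0])


class TestPredictive:
    def test_point_mass_gives_zero_band(self):
        post = point_mass_posterior(-4.0, 0.05)
        grid = posterior_predictive(post, [0, 40, 80, 120], seed=0)
        assert np.allclose(grid[:, 1], grid[:, 2])
        assert np.allclose(grid[:, 2], grid[:, 3])

    def test_flat_weights_give_half_everywhere(self):
        post = point_mass_posterior(0.0, 0.0)
        grid = posterior_predictive(post, [-50, 0, 50], seed=0)
        assert np.allclose(grid[:, 1], 0.5)

    def test_midpoint_of_point_mass(self):
        post = point_mass_posterior(-4.0, 0.05)
        assert predictive_midpoint(post, seed=0) == pytest.approx(80.0, abs=1e-2)

    def test_midpoint_invariant_to_slope_scale(self):
        for w1 in (0.05, 0.5, 5.0):
            post = point_mass_posterior(-80.0 * w1, w1)
            assert predictive_midpoint(post, seed=0) == pytest.approx(80.0, abs=1e-2)

    def test_median_is_half_at_midpoint(self, rng):
        x = rng.uniform(0, 150, 100)
        y = (rng.random(100) < 1 / (1 + np.exp(-(-4 + 0.05 * x)))).astype(int)
        post = fit_bayesian_logistic(x, y)
        mid = predictive_midpoint(post, seed=3)
        val = posterior_predictive(post, [mid], seed=3)[0, 1]
        assert val == pytest.approx(0.5, abs=5e-3)

    def test_no_crossing_raises(self):
        post = point_mass_posterior(5.0, 0.001)  # p > 0.5 over the whole grid
        with pytest.raises(ValueError, match="cross"):
            predictive_midpoint(post, xgrid=np.linspace(0, 100, 50), seed=0)

    def test_weaker_coupling_needs_larger_deficit(self, rng):
        # SC-like vs FEF-like: the midpoint moves right as coupling weakens
        wins = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = r.uniform(0, 150, 60)
            y_sc = (r.random(60) < 1 / (1 + np.exp(-0.09 * (x - 55)))).astype(int)
            y_fef = (r.random(60) < 1 / (1 + np.exp(-0.09 * (x - 120)))).astype(int)
            m_sc = predictive_midpoint(fit_bayesian_logistic(x, y_sc), seed=seed)
            m_fef = predictive_midpoint(fit_bayesian_logistic(x, y_fef), seed=seed)
            wins += m_fef > m_sc
        assert wins == 5


class TestSubsampleControl:
    def _points(self, rng, slope, n):
        x = rng.uniform(10, 130, n)
        return np.column_stack([x, slope * x + rng.normal(0, 5, n)])

    def test_separated_groups_always_significant(self, rng):
        a = self._points(rng, 0.31, 46)
        b = self._points(rng, 0.08, 23)
        res = subsample_control(a, b, n_iter=20, n_sub=23, n_boot=200, seed=0)
        assert res["n_significant_sc_greater"] == 20
        assert res["slope_ratio_mean"] > 1.5

    def test_null_has_no_systematic_direction(self, rng):
        # identical groups: the rank test on bootstrap slope distributions is
        # anti-conservative for the chance offset of each subsample, but the
        # *direction* is a coin flip, so the SC>FEF count stays far from the
        # near-certain counts seen with a real slope difference
        pts = self._points(rng, 0.2, 40)
        res = subsample_control(pts, pts, n_iter=60, n_sub=23, n_boot=200, seed=1)
        assert res["n_significant_sc_greater"] <= 0.75 * 60
        assert res["slope_ratio_mean"] == pytest.approx(1.0, abs=0.15)

    def test_full_subsample_equals_full_comparison(self, rng):
        a = self._points(rng, 0.31, 30)
        b = self._points(rng, 0.08, 23)
        res = subsample_control(a, b, n_iter=3, n_sub=30, n_boot=300, seed=2)
        assert res["n_significant_sc_greater"] == 3

    def test_invalid_args(self, rng):
        pts = self._points(rng, 0.2, 10)
        with pytest.raises(ValueError):
            subsample_control(pts, pts, n_iter=0)
        with pytest.raises(ValueError):
            subsample_control(pts, pts, n_iter=1, n_sub=11)
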