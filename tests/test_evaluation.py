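"""Localization errors, profile correlations, regressions and study summaries."""

import numpy as np
import pandas as pd
import pytest

import muecho as m


class TestLocalizationError:
    def test_identical_points(self):
        assert m.localization_error((5.0, 7.0), (5.0, 7.0)) == 0.0

    def test_three_four_five(self):
        assert m.localization_error((0.0, 0.0), (3.0, 4.0)) == pytest.approx(5.0)

    def test_isometry_invariance(self):
        """Distances are invariant under translation and rotation."""
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=2), rng.normal(size=2)
        base = m.localization_error(tuple(a), tuple(b))
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        shift = np.array([3.0, -2.0])
        assert m.localization_error(tuple(R @ a + shift), tuple(R @ b + shift)) == pytest.approx(base)


class TestProfileCorrelation:
    def test_profile_equal_to_twitch(self):
        tw = m.make_twitch_profile(512.0)
        assert m.profile_correlation(tw.samples, tw) == pytest.approx(1.0)
        assert m.profile_correlation(-tw.samples, tw) == pytest.approx(-1.0)

    def test_lag_alignment(self):
        tw = m.make_twitch_profile(512.0)
        lags = np.arange(-12, tw.samples.size) / 512.0
        prof = np.concatenate([np.zeros(12), tw.samples])
        assert m.profile_correlation(prof, tw, lags) == pytest.approx(1.0)


class TestReferenceProfile:
    def test_sparse_train_reference_matches_twitch(self):
        """With widely spaced spikes and no high-pass, the reference STA is
        exactly the twitch."""
        tw = m.make_twitch_profile(512.0)
        spikes = np.arange(0.5, 9.0, 0.5)
        ref, lags = m.reference_sta_profile(spikes, tw, 10.0, highpass_hz=None)
        k0 = int(np.searchsorted(lags, -1e-9))
        np.testing.assert_allclose(ref[k0 : k0 + tw.samples.size], tw.samples, atol=1e-12)

    def test_overlapping_train_reference_differs_from_twitch(self):
        """At 15 pps consecutive twitches overlap, so the attainable profile
        deviates measurably from the bare twitch."""
        tw = m.make_twitch_profile(512.0)
        spikes = np.arange(0.2, 9.5, 1 / 15.0)
        ref, lags = m.reference_sta_profile(spikes, tw, 10.0)
        k0 = int(np.searchsorted(lags, -1e-9))
        n = tw.samples.size
        r = np.corrcoef(ref[k0 : k0 + n], tw.samples)[0, 1]
        assert r < 0.9


class TestSimpleRegression:
    def test_perfect_line(self):
        x = np.arange(10.0)
        slope, intercept, r2 = m.simple_regression(x, 2.0 * x + 1.0)
        assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_constant_response(self):
        x = np.arange(10.0)
        slope, _, r2 = m.simple_regression(x, np.full(10, 3.0))
        assert slope == pytest.approx(0.0)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        y = 0.7 * x + rng.normal(size=50)
        _, _, r2 = m.simple_regression(x, y)
        assert r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)


class TestMultipleRegression:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(2)
        x1, x2 = rng.normal(size=50), rng.normal(size=50)
        beta = np.array([1.5, 0.8, -0.3, 0.05])
        y = beta[0] + beta[1] * x1 + beta[2] * x2 + beta[3] * x1 * x2
        fit = m.multiple_regression(y, x1, x2)
        np.testing.assert_allclose(fit.coef, beta, atol=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_ci_coverage(self):
        """Monte-Carlo: 95% CIs must cover the true coefficients ~95% of the
        time under Gaussian noise."""
        rng = np.random.default_rng(3)
        beta = np.array([0.5, 1.0, -0.5, 0.2])
        n_rep, n = 300, 80
        cover = np.zeros(4)
        for _ in range(n_rep):
            x1, x2 = rng.normal(size=n), rng.normal(size=n)
            y = beta[0] + beta[1] * x1 + beta[2] * x2 + beta[3] * x1 * x2
            y = y + rng.normal(scale=0.7, size=n)
            fit = m.multiple_regression(y, x1, x2)
            cover += (fit.conf_int[:, 0] <= beta) & (beta <= fit.conf_int[:, 1])
        rate = cover / n_rep
        assert np.all(rate > 0.90) and np.all(rate < 0.99)

    def test_interaction_from_depth_diffusion_model(self):
        """Units at mixed depths, with the surrogate's depth-dependent EMG
        centroid shrinkage toward the grid centre: the interaction captures
        the stronger medio-lateral relation of superficial units."""
        rng = np.random.default_rng(4)
        n = 200
        true_x = rng.uniform(5.0, 35.0, n)
        depth = rng.uniform(4.0, 24.0, n)
        units = [
            m.MotorUnit(id=i, center_mm=(true_x[i], depth[i]), radius_mm=1.5,
                        n_fibers=500, mean_rate_pps=10.0)
            for i in range(n)
        ]
        emg_x = np.array([m.surrogate_amplitudes(u).emg_centroid_mm[0] for u in units])
        us_x = true_x + rng.normal(scale=0.5, size=n)
        fit = m.multiple_regression(us_x, emg_x, depth)
        assert fit.coef[3] > 0  # interaction strengthens the relation superficially
        assert fit.r_squared > 0.5


class TestBootstrapAndSummary:
    def test_bootstrap_ci_contains_median(self):
        rng = np.random.default_rng(5)
        vals = rng.exponential(2.0, 200)
        lo, hi = m.bootstrap_median_ci(vals, seed=0)
        assert lo <= np.median(vals) <= hi
        assert m.bootstrap_median_ci(vals, seed=0) == (lo, hi)  # seeded determinism

    def _results(self, groups):
        rows = []
        for level, errs in groups.items():
            for e in errs:
                rows.append(
                    {"level": level, "matched": True, "error_mm": e, "profile_cc": 0.9}
                )
        return pd.DataFrame(rows)

    def test_identical_groups_anova(self):
        vals = list(np.linspace(0.5, 2.5, 12))
        summ = m.summarize_study(self._results({1: vals, 2: vals, 3: vals}))
        assert summ["anova_error"]["F"] == pytest.approx(0.0, abs=1e-12)
        assert summ["anova_error"]["p"] == pytest.approx(1.0)

    def test_plot_study_summary_writes_figure(self, tmp_path):
        rng = np.random.default_rng(7)
        n = 60
        df = pd.DataFrame(
            {
                "level": rng.integers(1, 6, n),
                "matched": True,
                "error_mm": rng.exponential(1.5, n),
                "profile_cc": rng.uniform(0.7, 1.0, n),
                "emg_x_mm": rng.uniform(5, 35, n),
                "us_x_mm": rng.uniform(5, 35, n),
            }
        )
        path = tmp_path / "summary.png"
        m.plot_study_summary(df, path)
        assert path.stat().st_size > 0

    def test_pooled_median_matches_concatenation(self):
        rng = np.random.default_rng(6)
        groups = {lvl: list(rng.exponential(1.5, 20)) for lvl in range(1, 6)}
        summ = m.summarize_study(self._results(groups))
        pooled = np.concatenate(list(groups.values()))
        assert summ["median_error_mm"] == pytest.approx(np.median(pooled))
        assert summ["n_matched"] == pooled.size
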