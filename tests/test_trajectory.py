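"""Mixed-model trajectory fitting and annualized % change summaries."""

import numpy as np
import pytest

from amytrial.trajectory import (
    GroupRateSummary,
    LongitudinalSeries,
    TrajectoryFit,
    annualize_percent_change,
    fit_random_slopes,
    summarize_group_rates,
)


def _series(sid, intercept, slope, times=(0.0, 1.5, 3.0, 4.5), noise=None, rng=None):
    t = np.asarray(times)
    v = intercept + slope * t
    if noise:
        v = v + rng.normal(0, noise, size=t.size)
    return LongitudinalSeries(sid, "DVR", "cortical", t, v)


class TestSeriesValidation:
    def test_needs_two_observations(self):
        with pytest.raises(ValueError):
            LongitudinalSeries("s", "DVR", "cortical", [0.0], [1.0])

    def test_times_strictly_increasing(self):
        with pytest.raises(ValueError):
            LongitudinalSeries("s", "DVR", "cortical", [0.0, 0.0], [1.0, 1.1])

    def test_values_positive(self):
        with pytest.raises(ValueError):
            LongitudinalSeries("s", "DVR", "cortical", [0.0, 1.0], [1.0, -0.5])


class TestFitRandomSlopes:
    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            fit_random_slopes([_series("a", 1.2, 0.01)])

    def test_mixed_metrics_rejected(self):
        s1 = _series("a", 1.2, 0.01)
        s2 = LongitudinalSeries("b", "SUVR", "cortical", [0.0, 1.0], [1.3, 1.31])
        with pytest.raises(ValueError):
            fit_random_slopes([s1, s2])

    def test_noise_free_slopes_recovered_exactly(self):
        series = [_series("a", 1.20, 0.01), _series("b", 1.10, 0.02)]
        fits = fit_random_slopes(series)
        slopes = {f.subject_id: f.slope for f in fits}
        assert slopes["a"] == pytest.approx(0.01, abs=1e-8)
        assert slopes["b"] == pytest.approx(0.02, abs=1e-8)

    def test_monte_carlo_slope_recovery(self):
        rng = np.random.default_rng(42)
        true_slopes = rng.normal(0.015, 0.008, size=200)
        series = [
            _series(f"s{i:03d}", 1.2 + rng.normal(0, 0.05), true_slopes[i],
                    noise=0.004, rng=rng)
            for i in range(200)
        ]
        fits = fit_random_slopes(series)
        assert fits[0].fit_method == "lme_blup"
        est = np.array([f.slope for f in fits])
        se = true_slopes.std() / np.sqrt(200)
        assert abs(est.mean() - true_slopes.mean()) < 2 * se

    def test_shrinkage_reduces_slope_variance(self):
        rng = np.random.default_rng(7)
        series = [
            _series(f"s{i:02d}", 1.2, rng.normal(0.01, 0.01),
                    times=(0.0, 2.0, 4.0), noise=0.01, rng=rng)
            for i in range(60)
        ]
        lme = fit_random_slopes(series)
        ols = [np.polyfit(s.times_yr, s.values, 1)[0] for s in series]
        assert np.var([f.slope for f in lme]) <= np.var(ols) + 1e-12


class TestAnnualize:
    @pytest.mark.parametrize(
        "intercept,slope,expected",
        [(1.25, 0.025, 2.0), (1.4, 0.0, 0.0), (1.05, -0.0105, -1.0)],
    )
    def test_arithmetic(self, intercept, slope, expected):
        fit = TrajectoryFit("s", "DVR", "cortical", intercept, slope, "lme_blup")
        assert annualize_percent_change(fit) == pytest.approx(expected)

    def test_nonpositive_intercept_rejected(self):
        fit = TrajectoryFit("s", "DVR", "cortical", -1.0, 0.01, "lme_blup")
        with pytest.raises(ValueError):
            annualize_percent_change(fit)

    def test_scale_equivariance_through_the_fit(self):
        rng = np.random.default_rng(5)
        series = [
            _series(f"s{i}", 1.2, rng.normal(0.012, 0.006), noise=0.005, rng=rng)
            for i in range(30)
        ]
        scaled = [
            LongitudinalSeries(s.subject_id, s.metric, s.roi, s.times_yr, 3.0 * s.values)
            for s in series
        ]
        p1 = [f.annual_pct_change for f in fit_random_slopes(series)]
        p2 = [f.annual_pct_change for f in fit_random_slopes(scaled)]
        np.testing.assert_allclose(p1, p2, atol=1e-5)


class _Profile:
    def __init__(self, sid, stratum, carrier):
        self.subject_id = sid
        self.stratum_true = stratum
        self.apoe4_carrier = carrier


class TestGroupSummaries:
    def _fits(self, pcts):
        return [
            TrajectoryFit(f"s{i}", "DVR", "cortical", 1.0, p / 100.0, "lme_blup")
            for i, p in enumerate(pcts)
        ]

    def test_mean_and_sd(self):
        fits = self._fits([1.0, 3.0])
        profiles = [_Profile("s0", "low", False), _Profile("s1", "low", False)]
        g = summarize_group_rates(fits, profiles, "low")
        assert g.mean_pct == pytest.approx(2.0)
        assert g.sd_pct == pytest.approx(np.sqrt(2.0))
        assert g.effect_size == pytest.approx(2.0 / np.sqrt(2.0))

    def test_single_subject_group_rejected(self):
        fits = self._fits([1.0, 3.0])
        profiles = [_Profile("s0", "low", False), _Profile("s1", "high", False)]
        with pytest.raises(ValueError):
            summarize_group_rates(fits, profiles, "low")

    def test_pooled_and_population_filters(self):
        fits = self._fits([1.0, 2.0, 3.0, 4.0])
        profiles = [
            _Profile("s0", "intermediate", True),
            _Profile("s1", "intermediate", False),
            _Profile("s2", "high", True),
            _Profile("s3", "low", True),
        ]
        pooled = summarize_group_rates(fits, profiles, "intermediate_high")
        assert pooled.n == 3
        carriers = summarize_group_rates(fits, profiles, "whole", "carriers")
        assert carriers.n == 3
        assert carriers.mean_pct == pytest.approx((1.0 + 3.0 + 4.0) / 3)

    def test_invariants(self):
        with pytest.raises(ValueError):
            GroupRateSummary("low", "all", "DVR", "cortical", 1, 1.0, 1.0)
        with pytest.raises(ValueError):
            GroupRateSummary("low", "all", "DVR", "cortical", 5, 1.0, 0.0)
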