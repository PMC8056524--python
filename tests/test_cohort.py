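"""Synthetic cohort generator: composition, bias model, noise calibration."""

import numpy as np
import pandas as pd
import pytest

from amytrial.cohort import (
    CohortConfig,
    default_rate_curve,
    generate_cohort,
    generate_trt_pairs,
    sigma_for_trt,
    simulate_measurements,
    simulate_same_day_pairs,
)
from amytrial.trt import trt_percent


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        CohortConfig(frac_low=0.9, frac_intermediate=0.2, frac_high=0.1)
    with pytest.raises(ValueError):
        CohortConfig(n_subjects=1)
    with pytest.raises(ValueError):
        CohortConfig(noise_scale=-0.1)


def test_rate_curve_passes_through_anchors():
    a, b, c = default_rate_curve()
    for cl, rate in ((7.0, 0.49), (35.0, 2.34), (70.0, 1.55)):
        assert a * cl * cl + b * cl + c == pytest.approx(rate, abs=1e-9)


def test_single_stratum_config():
    cfg = CohortConfig(n_subjects=50, frac_low=1.0, frac_intermediate=0.0, frac_high=0.0, seed=5)
    profiles, _, _ = generate_cohort(cfg)
    assert len(profiles) == 50
    assert all(p.stratum_true == "low" for p in profiles)


def test_determinism_same_seed(small_cohort):
    cfg, profiles, trajectories, scan_times = small_cohort
    profiles2, trajectories2, scan_times2 = generate_cohort(cfg)
    assert profiles == profiles2
    assert trajectories == trajectories2
    pd.testing.assert_frame_equal(scan_times, scan_times2)
    m1 = simulate_measurements(trajectories, scan_times, cfg)
    m2 = simulate_measurements(trajectories2, scan_times2, cfg)
    pd.testing.assert_frame_equal(m1, m2)


def test_default_composition_matches_targets():
    cfg = CohortConfig(seed=11)
    profiles, trajectories, scan_times = generate_cohort(cfg)
    counts = pd.Series([p.stratum_true for p in profiles]).value_counts()
    # binomial 3-sigma bands around (194, 20, 23)
    for stratum, expected in (("low", 194), ("intermediate", 20), ("high", 23)):
        p = expected / 237
        sigma = np.sqrt(237 * p * (1 - p))
        assert abs(counts.get(stratum, 0) - expected) < 3 * sigma
    per_subj = scan_times.groupby("subject_id")["time_yr"].agg(["size", "max"])
    assert per_subj["size"].between(2, 5).all()
    assert (per_subj["max"] > 0).all()
    first = scan_times[scan_times["session"] == 0]["time_yr"]
    assert (first == 0).all()


def test_carriers_have_higher_baseline_burden():
    cfg = CohortConfig(seed=13)
    profiles, trajectories, _ = generate_cohort(cfg)
    carrier = {p.subject_id: p.apoe4_carrier for p in profiles}
    cl_c = [t.cl_baseline for t in trajectories if carrier[t.subject_id]]
    cl_n = [t.cl_baseline for t in trajectories if not carrier[t.subject_id]]
    assert np.mean(cl_c) > np.mean(cl_n)


def test_rate_curve_peaks_in_intermediate_stratum():
    cfg = CohortConfig(seed=17)
    profiles, trajectories, _ = generate_cohort(cfg)
    stratum = {p.subject_id: p.stratum_true for p in profiles}
    means = {
        s: np.mean([t.rate_pct for t in trajectories if stratum[t.subject_id] == s])
        for s in ("low", "intermediate", "high")
    }
    assert means["intermediate"] > means["low"]
    assert means["intermediate"] > means["high"]


def test_noiseless_bias_model_exact(noiseless_cohort):
    cfg, profiles, trajectories, scan_times, meas = noiseless_cohort
    base = meas[(meas["session"] == 0) & (meas["region"] == "cortical")]
    dvr = base[base["metric"] == "DVR"].set_index("subject_id")["value"]
    suvr = base[base["metric"] == "SUVR"].set_index("subject_id")["value"]
    np.testing.assert_allclose(suvr - 1.0, 1.3 * (dvr - 1.0), rtol=1e-10)
    # a forced-example spot check: DVR 1.20 -> SUVR 1.26 under 30% bias
    assert 1.0 + 1.3 * (1.20 - 1.0) == pytest.approx(1.26)


def test_noiseless_observed_pct_change_equals_truth(noiseless_cohort):
    cfg, profiles, trajectories, scan_times, meas = noiseless_cohort
    sub = meas[(meas["metric"] == "DVR") & (meas["region"] == "cortical")]
    for traj in trajectories[:10]:
        grp = sub[sub["subject_id"] == traj.subject_id].sort_values("time_yr")
        slope, intercept = np.polyfit(grp["time_yr"], grp["value"], 1)
        assert 100.0 * slope / intercept == pytest.approx(traj.rate_pct, abs=1e-8)


def test_unknown_mode_rejected(small_cohort):
    cfg, _, trajectories, scan_times = small_cohort
    with pytest.raises(ValueError, match="mode"):
        simulate_measurements(trajectories, scan_times, cfg, mode="voxel")


def test_kinetic_mode_emits_srtm_parameters(small_cohort):
    cfg, _, trajectories, scan_times = small_cohort
    kin = simulate_measurements(trajectories, scan_times, cfg, mode="kinetic")
    assert set(kin.columns) >= {"subject_id", "session", "region", "R1", "k2", "BPND"}
    assert (kin["BPND"] >= 0).all()
    assert (kin["k2"] > 0).all()


def test_trt_calibration_monotone_in_target(small_cohort):
    cfg, _, trajectories, scan_times = small_cohort
    realized = []
    for target in (0.5, 1.0, 2.0):
        c = CohortConfig(
            n_subjects=cfg.n_subjects,
            seed=cfg.seed,
            noise_trt_target={**cfg.noise_trt_target, ("DVR", "cortical"): target},
        )
        pairs = simulate_same_day_pairs(
            trajectories, scan_times, c, "DVR", "cortical", n_replicates=40, seed=99
        )
        trts = [trt_percent(t, r) for t, r in zip(pairs.value_test, pairs.value_retest)]
        realized.append(np.mean(trts))
    assert realized[0] < realized[1] < realized[2]


def test_sigma_for_trt_contract():
    with pytest.raises(ValueError):
        sigma_for_trt(1.0, [-1.5])
    with pytest.raises(ValueError):
        sigma_for_trt(-1.0)
    # value-multiplicative noise: mean same-day TRT% is 2*sigma/sqrt(pi)
    # at every burden level, so the calibration is closed-form
    assert sigma_for_trt(1.0) == pytest.approx(0.01 * np.sqrt(np.pi) / 2.0)


class TestTrtPairs:
    def test_counts(self):
        pairs = generate_trt_pairs(n_cu=4, n_impaired=7, seed=2)
        assert pairs["subject_id"].nunique() == 11
        assert len(pairs) == 44  # 2 metrics x 2 ROIs per subject
        assert set(pairs["diagnosis"]) == {"CU", "MCI", "AD"}

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_trt_pairs(n_cu=-1, n_impaired=7)

    def test_zero_noise_gives_zero_trt(self):
        levels = {(m, r): 0.0 for m in ("SUVR", "DVR") for r in ("cortical", "early")}
        pairs = generate_trt_pairs(noise_levels=levels, seed=3)
        for row in pairs.itertuples():
            assert trt_percent(row.value_test, row.value_retest) == pytest.approx(0.0)

    def test_higher_suvr_noise_yields_higher_suvr_trt(self):
        pairs = generate_trt_pairs(n_cu=200, n_impaired=0, seed=4)

        def mean_trt(metric):
            sub = pairs[(pairs["metric"] == metric) & (pairs["roi"] == "cortical")]
            return np.mean(
                [trt_percent(r.value_test, r.value_retest) for r in sub.itertuples()]
            )

        assert mean_trt("SUVR") > mean_trt("DVR")
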