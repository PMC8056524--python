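"""SRTM simulation, SUVR / reference-Logan quantification, Centiloid strata."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amytrial.kinetics import (
    CentiloidMap,
    CompositeDefinition,
    FrameSchedule,
    KineticParams,
    ReferenceShape,
    TimeActivityCurve,
    aggregate_composite,
    classify_burden_stratum,
    compute_rlogan_dvr,
    compute_suvr,
    simulate_reference_tac,
    simulate_srtm_tac,
    suvr_to_centiloid,
)

SCHED60 = FrameSchedule.default(60.0)
SCHED90 = FrameSchedule.default(90.0)
SHAPE = ReferenceShape()
REF60 = simulate_reference_tac(SCHED60, SHAPE)
REF90 = simulate_reference_tac(SCHED90, SHAPE)


class TestFrameSchedule:
    def test_default_covers_window(self):
        assert SCHED60.frame_start[0] == 0.0
        assert SCHED60.frame_end[-1] == pytest.approx(60.0)
        assert np.all(np.diff(SCHED60.mid_times) > 0)

    def test_overlapping_frames_rejected(self):
        with pytest.raises(ValueError):
            FrameSchedule([0.0, 1.0], [1.5, 2.0])
        with pytest.raises(ValueError):
            FrameSchedule([0.0], [0.0])


class TestReferenceTac:
    def test_zero_amplitude_gives_zero_tac(self):
        tac = simulate_reference_tac(SCHED60, ReferenceShape(amplitude=0.0))
        assert np.all(tac.activity == 0.0)

    def test_peak_in_first_ten_minutes(self):
        assert SHAPE.peak_time < 10.0
        peak_frame = int(np.argmax(REF60.activity))
        assert REF60.schedule.mid_times[peak_frame] < 10.0

    def test_linearity_in_amplitude(self):
        double = simulate_reference_tac(
            SCHED60, ReferenceShape(amplitude=2 * SHAPE.amplitude)
        )
        np.testing.assert_allclose(double.activity, 2 * REF60.activity, rtol=1e-12)

    def test_rate_constant_ordering_enforced(self):
        with pytest.raises(ValueError):
            ReferenceShape(lambda_slow=0.5, lambda_fast=0.2)


class TestSrtm:
    def test_identity_kinetics_reproduce_reference(self):
        tac = simulate_srtm_tac(SHAPE, KineticParams(1.0, 0.15, 0.0), SCHED60)
        np.testing.assert_allclose(tac.activity, REF60.activity, rtol=1e-6)

    def test_binding_raises_late_activity(self):
        lo = simulate_srtm_tac(SHAPE, KineticParams(1.0, 0.15, 0.0), SCHED60)
        hi = simulate_srtm_tac(SHAPE, KineticParams(1.0, 0.15, 0.5), SCHED60)
        late = SCHED60.mid_times >= 30.0
        assert np.all(hi.activity[late] > lo.activity[late])

    def test_zero_delivery_starts_at_zero(self):
        # pure convolution term: zero at t=0, so the first half-minute
        # frame average is a small fraction of the peak
        tac = simulate_srtm_tac(SHAPE, KineticParams(0.0, 0.15, 0.5), SCHED60)
        assert tac.activity[0] < 0.01 * tac.activity.max()

    def test_tac_input_accepted(self):
        tac = simulate_srtm_tac(REF60, KineticParams(1.0, 0.15, 0.3), SCHED60)
        assert np.all(np.isfinite(tac.activity))


class TestSuvr:
    def test_target_equal_reference_gives_one(self):
        assert compute_suvr(REF60, REF60) == pytest.approx(1.0)

    def test_linearity(self):
        double = TimeActivityCurve(SCHED60, 2 * REF60.activity)
        assert compute_suvr(double, REF60) == pytest.approx(2.0)

    def test_window_must_contain_frames(self):
        with pytest.raises(ValueError):
            compute_suvr(REF60, REF60, window=(70.0, 80.0))

    def test_srtm_suvr_overshoots_equilibrium_dvr(self):
        tac = simulate_srtm_tac(SHAPE, KineticParams(1.0, 0.15, 0.5), SCHED60)
        assert compute_suvr(tac, REF60) > 1.5


class TestRlogan:
    def test_target_equal_reference_gives_unit_dvr(self):
        dvr, _ = compute_rlogan_dvr(REF90, REF90, 30.0)
        assert dvr == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("c", [0.5, 2.0, 7.3])
    def test_scaled_reference_gives_scale(self, c):
        scaled = TimeActivityCurve(SCHED90, c * REF90.activity)
        dvr, _ = compute_rlogan_dvr(scaled, REF90, 30.0)
        assert dvr == pytest.approx(c, rel=1e-6)

    def test_monotone_in_binding(self):
        dvrs = []
        for bp in (0.0, 0.25, 0.5, 1.0, 1.5):
            tac = simulate_srtm_tac(SHAPE, KineticParams(1.0, 0.15, bp), SCHED90)
            dvrs.append(compute_rlogan_dvr(tac, REF90, 30.0, k2_ref=0.15)[0])
        assert all(b > a for a, b in zip(dvrs, dvrs[1:]))

    def test_global_rescale_invariance(self):
        tac = simulate_srtm_tac(SHAPE, KineticParams(1.0, 0.15, 0.5), SCHED90)
        dvr1, _ = compute_rlogan_dvr(tac, REF90, 30.0)
        tac2 = TimeActivityCurve(SCHED90, 3.7 * tac.activity)
        ref2 = TimeActivityCurve(SCHED90, 3.7 * REF90.activity)
        dvr2, _ = compute_rlogan_dvr(tac2, ref2, 30.0)
        assert dvr1 == pytest.approx(dvr2, rel=1e-9)

    def test_too_few_late_frames_rejected(self):
        with pytest.raises(ValueError):
            compute_rlogan_dvr(REF60, REF60, t_star=58.0)


class TestComposites:
    def test_uniform_values_pass_through(self):
        comp = CompositeDefinition("c", {"a": 1.0, "b": 1.0})
        assert aggregate_composite({"a": 1.2, "b": 1.2}, comp) == pytest.approx(1.2)

    def test_weighted_mean(self):
        comp = CompositeDefinition("c", {"a": 0.25, "b": 0.75})
        assert aggregate_composite({"a": 1.0, "b": 2.0}, comp) == pytest.approx(1.75)

    def test_missing_region_named(self):
        comp = CompositeDefinition("c", {"a": 1.0, "b": 1.0})
        with pytest.raises(KeyError, match="b"):
            aggregate_composite({"a": 1.0}, comp)


class TestCentiloid:
    def test_anchors(self):
        m = CentiloidMap(1.01, 1.90)
        assert suvr_to_centiloid(1.01, m) == pytest.approx(0.0)
        assert suvr_to_centiloid(1.90, m) == pytest.approx(100.0)
        assert suvr_to_centiloid(1.4555, m) == pytest.approx(50.06, abs=0.01)

    def test_degenerate_map_rejected(self):
        with pytest.raises(ValueError):
            CentiloidMap(1.5, 1.5)

    @pytest.mark.parametrize(
        "cl,expected",
        [(20.1, "low"), (49.4, "intermediate"), (49.41, "high"), (-5.0, "low"), (0.0, "low"), (20.11, "intermediate")],
    )
    def test_stratum_boundaries(self, cl, expected):
        assert classify_burden_stratum(cl) == expected

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            classify_burden_stratum(float("nan"))

    @given(st.floats(min_value=-50, max_value=200, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_strata_partition_the_line(self, cl):
        assert classify_burden_stratum(cl) in ("low", "intermediate", "high")
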