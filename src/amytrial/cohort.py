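"""Synthetic longitudinal [11C]PIB cohort generator.

Emulates the statistical structure of a cognitively-unimpaired longitudinal
amyloid-PET cohort (237 subjects, 2-5 scans each, ~4.8 y first-to-last span)
so that every downstream stage — quantification, mixed-model trajectory
fitting, test-retest cutoffs, association analyses and trial power — runs
without any data download.

Ground truth per subject is a baseline Centiloid value (log-normal within the
subject's burden stratum, shifted upward for APOE-e4 carriers) and a true
annual % change of cortical DVR following an inverted-U ("rate curve")
dependence on baseline burden: accumulation peaks at intermediate burden.
Regional values share a common specific-signal growth rate, so the cortical
composite evolves exactly as ``DVR(t) = dvr0 * (1 + rate_pct/100 * t)`` while
the early composite (higher baseline specific signal) shows a higher % rate.
SUVR is a biased transform of DVR — ``SUVR - 1 = (1 + bias_slope_baseline) *
(DVR - 1)`` at baseline, with the SUVR specific-signal growth additionally
inflated by ``bias_slope_rate`` — and measurement noise is multiplicative
Gaussian on the measured value, so the induced same-day test-retest
variability (TRT%) is the same at every burden level and is calibrated
exactly to configured per-metric/ROI targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import CentiloidMap, DEFAULT_CENTILOID_MAP

__all__ = [
    "CohortConfig",
    "SubjectProfile",
    "TrueTrajectory",
    "DEFAULT_TRT_TARGETS",
    "default_rate_curve",
    "generate_cohort",
    "simulate_measurements",
    "simulate_same_day_pairs",
    "generate_trt_pairs",
    "sigma_for_trt",
    "REGION_BASELINE_FACTOR",
]

STRATA = ("low", "intermediate", "high")

# half-normal mean: E|eps1 - eps2| = 2 sigma / sqrt(pi) for iid N(0, sigma)
_HALF_NORMAL = 2.0 / math.sqrt(math.pi)

# CU-only TRT% targets per (metric, roi); the measurement-noise level is
# solved so same-day replicate pairs reproduce these on average
DEFAULT_TRT_TARGETS: dict[tuple[str, str], float] = {
    ("DVR", "cortical"): 0.85,
    ("SUVR", "cortical"): 1.61,
    ("DVR", "early"): 2.05,
    ("SUVR", "early"): 3.46,
}

# per-region baseline specific-signal multipliers relative to the cortical
# composite; cortical members average to exactly 1, early members to 1.3
# (early regions carry proportionally more signal, as in staging systems)
REGION_BASELINE_FACTOR: dict[str, float] = {
    "frontal": 0.90,
    "parietal": 0.95,
    "temporal": 0.85,
    "precuneus": 1.30,
    "isthmus_cingulate": 1.45,
    "lateral_orbitofrontal": 1.15,
}
_CORTICAL_REGIONS = ("frontal", "parietal", "temporal", "precuneus")
_EARLY_REGIONS = ("isthmus_cingulate", "precuneus", "lateral_orbitofrontal")

# (CL, %/yr) anchors for the inverted-U rate curve: representative Centiloid
# values of the low / intermediate / high strata and their group-mean cortical
# DVR accumulation rates
_RATE_ANCHORS = ((7.0, 0.49), (35.0, 2.34), (70.0, 1.55))


def default_rate_curve() -> tuple[float, float, float]:
    """Quadratic (a, b, c) with rate(CL) = a*CL**2 + b*CL + c through the
    three stratum anchor points (exact 3x3 solve, done once)."""
    cls = np.array([p[0] for p in _RATE_ANCHORS])
    rates = np.array([p[1] for p in _RATE_ANCHORS])
    coeffs = np.linalg.solve(np.vander(cls, 3), rates)
    return tuple(float(c) for c in coeffs)


@dataclass(frozen=True)
class CohortConfig:
    """Calibration of the synthetic cohort.

    Stratum fractions, carrier composition, scan counts and spans default to
    the published cohort composition; the rate curve defaults to the quadratic
    through the three stratum-mean (CL, %/yr) anchors.
    """

    n_subjects: int = 237
    frac_low: float = 194.0 / 237.0
    frac_intermediate: float = 20.0 / 237.0
    frac_high: float = 23.0 / 237.0
    frac_carriers_by_stratum: dict[str, float] = field(
        default_factory=lambda: {
            "low": 48.0 / 194.0,
            "intermediate": 15.0 / 20.0,
            "high": 15.0 / 23.0,
        }
    )
    scan_count_mean: float = 2.5
    scan_count_sd: float = 0.6
    total_span_mean_yr: float = 4.8
    total_span_sd_yr: float = 2.1
    span_range_yr: tuple[float, float] = (1.0, 9.6)
    rate_curve: tuple[float, float, float] = field(default_factory=default_rate_curve)
    rate_sd_by_stratum: dict[str, float] = field(
        default_factory=lambda: {"low": 0.96, "intermediate": 0.72, "high": 0.93}
    )
    noise_trt_target: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_TRT_TARGETS)
    )
    noise_scale: float = 1.0  # multiplier on the calibrated noise (0 = noiseless)
    bias_slope_baseline: float = 0.30
    bias_slope_rate: float = 0.15
    # stratum-wise log-normal Centiloid parameters (median, log-sd) and the
    # additive log-shift applied to APOE-e4 carriers' baseline distribution
    cl_lognormal: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "low": (7.0, 0.80),
            "intermediate": (35.0, 0.22),
            "high": (70.0, 0.28),
        }
    )
    carrier_cl_logshift: float = 0.30
    age_by_stratum: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "low": (64.4, 9.6),
            "intermediate": (67.6, 7.4),
            "high": (71.1, 6.6),
        }
    )
    age_range: tuple[float, float] = (42.0, 95.0)
    frac_female_by_stratum: dict[str, float] = field(
        default_factory=lambda: {"low": 0.665, "intermediate": 0.65, "high": 0.522}
    )
    centiloid_map: CentiloidMap = DEFAULT_CENTILOID_MAP
    srtm_r1: float = 1.0  # kinetic-mode delivery ratio
    srtm_k2: float = 0.15  # kinetic-mode efferent rate, 1/min
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.frac_low, self.frac_intermediate, self.frac_high)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("stratum fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("stratum fractions must sum to 1")
        for s in STRATA:
            if not 0.0 <= self.frac_carriers_by_stratum[s] <= 1.0:
                raise ValueError("carrier fractions must lie in [0, 1]")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.total_span_mean_yr <= 0 or self.span_range_yr[0] <= 0:
            raise ValueError("scan spans must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")

    @property
    def stratum_fractions(self) -> dict[str, float]:
        return {
            "low": self.frac_low,
            "intermediate": self.frac_intermediate,
            "high": self.frac_high,
        }


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    age_baseline: float
    sex: str  # F | M
    apoe4_carrier: bool
    stratum_true: str


@dataclass(frozen=True)
class TrueTrajectory:
    """Ground-truth amyloid state: baseline cortical DVR, true annual %
    change (DVR scale) and per-region baseline values."""

    subject_id: str
    cl_baseline: float
    dvr0: float
    rate_pct: float
    region_baselines: dict[str, float]

    @property
    def specific_growth(self) -> float:
        """Growth rate g of the specific signal so that
        DVR(t) = dvr0 (1 + rate_pct/100 t) = 1 + (dvr0-1)(1 + g t)."""
        s0 = self.dvr0 - 1.0
        if s0 <= 0:
            return 0.0
        return self.dvr0 * self.rate_pct / 100.0 / s0

    def dvr_at(self, t_yr: float) -> float:
        return self.dvr0 * (1.0 + self.rate_pct / 100.0 * t_yr)


def _truncated_lognormal(
    rng: np.random.Generator, median: float, log_sd: float, lo: float, hi: float
) -> float:
    mu = math.log(median)
    for _ in range(10_000):
        x = float(rng.lognormal(mu, log_sd))
        if lo < x <= hi:
            return x
    raise RuntimeError(
        f"truncated log-normal sampling failed for bounds ({lo}, {hi}]"
    )  # pragma: no cover


# the high stratum is truncated at 100 CL: cognitively unimpaired cohorts
# rarely exceed it, and the inverted-U rate curve is anchored below it
_STRATUM_CL_BOUNDS = {"low": (0.0, 20.1), "intermediate": (20.1, 49.4), "high": (49.4, 100.0)}


def _cl_to_dvr(cl: float, cfg: CohortConfig) -> float:
    suvr = cfg.centiloid_map.to_suvr(cl)
    return 1.0 + max(suvr - 1.0, 0.0) / (1.0 + cfg.bias_slope_baseline)


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[SubjectProfile], list[TrueTrajectory], pd.DataFrame]:
    """Draw subject profiles, ground-truth trajectories and scan times.

    Returns ``(profiles, trajectories, scan_times)`` where ``scan_times`` is a
    DataFrame with columns ``subject_id, session, time_yr`` (first scan at 0,
    strictly increasing, 2-5 scans per subject).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    a, b, c = cfg.rate_curve

    profiles: list[SubjectProfile] = []
    trajectories: list[TrueTrajectory] = []
    scan_rows: list[dict] = []

    strata = rng.choice(
        STRATA, size=cfg.n_subjects, p=[cfg.frac_low, cfg.frac_intermediate, cfg.frac_high]
    )
    for i in range(cfg.n_subjects):
        sid = f"sub-{i:04d}"
        stratum = str(strata[i])
        carrier = bool(rng.random() < cfg.frac_carriers_by_stratum[stratum])
        female = bool(rng.random() < cfg.frac_female_by_stratum[stratum])
        age_mu, age_sd = cfg.age_by_stratum[stratum]
        age = float(np.clip(rng.normal(age_mu, age_sd), *cfg.age_range))

        median, log_sd = cfg.cl_lognormal[stratum]
        if carrier:
            median = median * math.exp(cfg.carrier_cl_logshift)
        lo, hi = _STRATUM_CL_BOUNDS[stratum]
        cl = _truncated_lognormal(rng, median, log_sd, lo, hi)
        dvr0 = _cl_to_dvr(cl, cfg)

        # the quadratic is anchored on CL in [7, 70]; clip its input so tail
        # draws beyond ~100 CL do not extrapolate to absurd decline rates
        clc = min(cl, 100.0)
        rate = a * clc * clc + b * clc + c + rng.normal(0.0, cfg.rate_sd_by_stratum[stratum])

        n_scans = int(np.clip(round(rng.normal(cfg.scan_count_mean, cfg.scan_count_sd)), 2, 5))
        span = float(
            np.clip(rng.normal(cfg.total_span_mean_yr, cfg.total_span_sd_yr), *cfg.span_range_yr)
        )

        # keep every metric's trajectory positive over the scan span: bound
        # the specific-signal growth so neither DVR nor (bias-inflated) SUVR
        # drops below 0.05 by the last scan
        s0 = dvr0 - 1.0
        if s0 > 0 and rate < 0:
            g = dvr0 * rate / 100.0 / s0
            g_min = max(
                (-0.95 / max(s0, 1e-6) - 1.0) / span,
                (-0.95 / (1.3 * 1.5 * max(s0, 1e-6)) - 1.0)
                / ((1.0 + cfg.bias_slope_rate) * span),
            )
            if g < g_min:
                rate = 100.0 * max(s0, 1e-6) * g_min / dvr0

        region_baselines = {
            r: 1.0 + (dvr0 - 1.0) * f for r, f in REGION_BASELINE_FACTOR.items()
        }
        profiles.append(SubjectProfile(sid, age, "F" if female else "M", carrier, stratum))
        trajectories.append(TrueTrajectory(sid, cl, dvr0, float(rate), region_baselines))
        interior = np.sort(rng.uniform(0.15 * span, 0.85 * span, size=n_scans - 2))
        times = np.concatenate([[0.0], interior, [span]])
        for sess, t in enumerate(times):
            scan_rows.append({"subject_id": sid, "session": sess, "time_yr": float(t)})

    return profiles, trajectories, pd.DataFrame(scan_rows)


# ---------------------------------------------------------------------------
# noise-free value model


def _specific_value(
    traj: TrueTrajectory, region_or_roi: str, metric: str, t_yr: float, cfg: CohortConfig
) -> float:
    """Noise-free specific signal (value - 1) for a region or composite."""
    if region_or_roi == "cortical":
        s0 = traj.dvr0 - 1.0
    elif region_or_roi == "early":
        s0 = (traj.dvr0 - 1.0) * float(
            np.mean([REGION_BASELINE_FACTOR[r] for r in _EARLY_REGIONS])
        )
    else:
        s0 = traj.region_baselines[region_or_roi] - 1.0
    g = traj.specific_growth
    if metric == "DVR":
        return s0 * (1.0 + g * t_yr)
    if metric == "SUVR":
        return (1.0 + cfg.bias_slope_baseline) * s0 * (
            1.0 + (1.0 + cfg.bias_slope_rate) * g * t_yr
        )
    raise ValueError(f"unknown metric {metric!r}")


def sigma_for_trt(trt_target_pct: float, specific_values=None) -> float:
    """Noise SD on the specific signal inducing a mean same-day TRT% equal to
    ``trt_target_pct`` over latent values with the given specific signals.

    For observations v (1 + eps), eps ~ N(0, sigma) iid per scan, the pair
    difference eps1 - eps2 is N(0, 2 sigma^2) with mean absolute value
    2 sigma / sqrt(pi), and the latent value cancels from the TRT ratio, so
    E[TRT%] = 100 * 2 sigma / sqrt(pi) to first order in sigma — the same for
    every burden level, matching TRT studies that span CU through AD.

    ``specific_values`` is accepted for signature stability but does not
    affect the result beyond validation.
    """
    if trt_target_pct < 0:
        raise ValueError("TRT target must be non-negative")
    if specific_values is not None:
        s = np.asarray(specific_values, dtype=float)
        if s.size == 0 or np.any(s <= -1.0):
            raise ValueError("specific signals must be non-empty and exceed -1")
    return trt_target_pct / 100.0 / _HALF_NORMAL


def _composite_sigmas(
    trajectories: list[TrueTrajectory],
    scan_times: pd.DataFrame,
    cfg: CohortConfig,
) -> dict[tuple[str, str], float]:
    """Per-(metric, roi) noise SDs calibrated against the cohort's noise-free
    session values so the induced TRT% matches the configured targets."""
    by_sid = {tr.subject_id: tr for tr in trajectories}
    sigmas = {}
    for (metric, roi), target in cfg.noise_trt_target.items():
        vals = [
            _specific_value(by_sid[row.subject_id], roi, metric, row.time_yr, cfg)
            for row in scan_times.itertuples()
        ]
        sigmas[(metric, roi)] = sigma_for_trt(target, vals)
    return sigmas


def simulate_measurements(
    trajectories: list[TrueTrajectory],
    scan_times: pd.DataFrame,
    config: CohortConfig,
    mode: str = "values",
) -> pd.DataFrame:
    """Observed metric values (or SRTM kinetic parameters) per session.

    ``values`` mode returns a long table ``subject_id, session, time_yr,
    region, metric, value`` containing the six atomic regions plus the
    ``cortical`` and ``early`` composite rows; composite noise is calibrated
    to the configured TRT% targets, region noise is the cortical-composite
    noise scaled by sqrt(n_members) (as if the composite averaged independent
    member noise).

    ``kinetic`` mode returns per-session, per-region SRTM parameters
    (``R1, k2, BPND`` with BPND = DVR - 1) for the quantification layer.
    """
    if mode not in ("values", "kinetic"):
        raise ValueError(f"unknown mode {mode!r}; expected 'values' or 'kinetic'")
    cfg = config
    by_sid = {tr.subject_id: tr for tr in trajectories}
    missing = set(scan_times["subject_id"]) - set(by_sid)
    if missing:
        raise ValueError(f"scan times reference unknown subjects: {sorted(missing)[:3]}")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))

    if mode == "kinetic":
        rows = []
        for row in scan_times.itertuples():
            traj = by_sid[row.subject_id]
            for region in REGION_BASELINE_FACTOR:
                s = _specific_value(traj, region, "DVR", row.time_yr, cfg)
                rows.append(
                    {
                        "subject_id": row.subject_id,
                        "session": row.session,
                        "time_yr": row.time_yr,
                        "region": region,
                        "R1": cfg.srtm_r1,
                        "k2": cfg.srtm_k2,
                        "BPND": max(s, 0.0),
                    }
                )
        return pd.DataFrame(rows)

    sigmas = _composite_sigmas(trajectories, scan_times, cfg)
    rows = []
    for row in scan_times.itertuples():
        traj = by_sid[row.subject_id]
        for metric in ("DVR", "SUVR"):
            sig_cort = sigmas[(metric, "cortical")] * cfg.noise_scale
            for region in REGION_BASELINE_FACTOR:
                s = _specific_value(traj, region, metric, row.time_yr, cfg)
                eps = rng.normal(0.0, sig_cort * 2.0) if sig_cort > 0 else 0.0
                rows.append(
                    {
                        "subject_id": row.subject_id,
                        "session": row.session,
                        "time_yr": row.time_yr,
                        "region": region,
                        "metric": metric,
                        "value": (1.0 + s) * (1.0 + eps),
                    }
                )
            for roi in ("cortical", "early"):
                s = _specific_value(traj, roi, metric, row.time_yr, cfg)
                sig = sigmas[(metric, roi)] * cfg.noise_scale
                eps = rng.normal(0.0, sig) if sig > 0 else 0.0
                rows.append(
                    {
                        "subject_id": row.subject_id,
                        "session": row.session,
                        "time_yr": row.time_yr,
                        "region": roi,
                        "metric": metric,
                        "value": (1.0 + s) * (1.0 + eps),
                    }
                )
    return pd.DataFrame(rows)


def simulate_same_day_pairs(
    trajectories: list[TrueTrajectory],
    scan_times: pd.DataFrame,
    config: CohortConfig,
    metric: str,
    roi: str,
    n_replicates: int = 20,
    seed: int | None = None,
) -> pd.DataFrame:
    """Duplicated same-day measurement pairs for empirical TRT% checks.

    Every session is replicated ``n_replicates`` times with two independent
    noise draws each; returns columns ``value_test, value_retest``.
    """
    cfg = config
    by_sid = {tr.subject_id: tr for tr in trajectories}
    sig = _composite_sigmas(trajectories, scan_times, cfg)[(metric, roi)] * cfg.noise_scale
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    s = np.array(
        [
            _specific_value(by_sid[row.subject_id], roi, metric, row.time_yr, cfg)
            for row in scan_times.itertuples()
        ]
    )
    s = np.repeat(s, n_replicates)
    e1 = rng.normal(0.0, sig, size=s.size) if sig > 0 else np.zeros(s.size)
    e2 = rng.normal(0.0, sig, size=s.size) if sig > 0 else np.zeros(s.size)
    return pd.DataFrame(
        {"value_test": (1.0 + s) * (1.0 + e1), "value_retest": (1.0 + s) * (1.0 + e2)}
    )


def generate_trt_pairs(
    n_cu: int = 4,
    n_impaired: int = 7,
    noise_levels: dict[tuple[str, str], float] | None = None,
    seed: int = 0,
    config: CohortConfig | None = None,
) -> pd.DataFrame:
    """Synthetic test-retest pair table emulating a small TRT study.

    One row per subject x metric x ROI with columns ``subject_id, diagnosis,
    metric, roi, value_test, value_retest``.  CU subjects draw low-burden
    latent values, impaired subjects (1 MCI, remainder AD) high-burden ones;
    ``noise_levels`` maps (metric, roi) to the TRT% each row's noise is
    calibrated to (defaults to the CU-only targets).
    """
    if n_cu < 0 or n_impaired < 0:
        raise ValueError("subject counts must be non-negative")
    cfg = config if config is not None else CohortConfig()
    levels = dict(DEFAULT_TRT_TARGETS) if noise_levels is None else dict(noise_levels)
    rng = np.random.default_rng(seed)

    early_factor = float(np.mean([REGION_BASELINE_FACTOR[r] for r in _EARLY_REGIONS]))
    rows = []
    for i in range(n_cu + n_impaired):
        impaired = i >= n_cu
        if impaired:
            dx = "MCI" if i == n_cu else "AD"
            cl = _truncated_lognormal(rng, 65.0, 0.35, 10.0, 250.0)
        else:
            dx = "CU"
            cl = _truncated_lognormal(rng, 7.0, 0.8, 0.0, 20.1)
        dvr0 = _cl_to_dvr(cl, cfg)
        for metric in ("SUVR", "DVR"):
            for roi in ("cortical", "early"):
                s = dvr0 - 1.0
                if roi == "early":
                    s *= early_factor
                if metric == "SUVR":
                    s *= 1.0 + cfg.bias_slope_baseline
                s = max(s, 1e-4)
                target = levels[(metric, roi)]
                sig = sigma_for_trt(target, [s]) if target > 0 else 0.0
                e1, e2 = (rng.normal(0.0, sig, size=2) if sig > 0 else (0.0, 0.0))
                rows.append(
                    {
                        "subject_id": f"trt-{i:02d}",
                        "diagnosis": dx,
                        "metric": metric,
                        "roi": roi,
                        "value_test": (1.0 + s) * (1.0 + e1),
                        "value_retest": (1.0 + s) * (1.0 + e2),
                    }
                )
    return pd.DataFrame(rows)
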