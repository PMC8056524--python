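"""Test-retest variability and accumulator classification.

The test-retest (TRT) statistic for a scan pair (T, R) is the percent
absolute difference relative to the pair mean,

    TRT% = |T - R| / (0.5 |T + R|) * 100,

computed per subject and averaged over a TRT cohort per metric/ROI.  The
cohort mean TRT% (by default from cognitively-unimpaired subjects only)
serves as the cutoff separating "accumulators" — subjects whose annualized %
change exceeds measurement variability — from stable subjects; ties at the
cutoff are non-accumulators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import TrajectoryFit, annualize_percent_change

__all__ = [
    "TrtSummary",
    "AccumulatorCall",
    "trt_percent",
    "trt_cohort_summary",
    "classify_accumulators",
]


@dataclass(frozen=True)
class TrtSummary:
    metric: str
    roi: str
    population: str  # CU_only | all
    n: int
    trt_pct: float

    def __post_init__(self) -> None:
        if self.trt_pct < 0:
            raise ValueError("trt_pct must be non-negative")


@dataclass(frozen=True)
class AccumulatorCall:
    subject_id: str
    metric: str
    roi: str
    annual_pct_change: float
    cutoff_pct: float

    @property
    def is_accumulator(self) -> bool:
        return self.annual_pct_change > self.cutoff_pct


def trt_percent(value_test: float, value_retest: float) -> float:
    """Percent absolute test-retest difference relative to the pair mean."""
    t, r = float(value_test), float(value_retest)
    denom = 0.5 * abs(t + r)
    if denom == 0:
        raise ZeroDivisionError("test + retest must be non-zero")
    return abs(t - r) / denom * 100.0


def trt_cohort_summary(
    pairs: pd.DataFrame, metric: str, roi: str, population: str = "CU_only"
) -> TrtSummary:
    """Mean per-subject TRT% for one metric/ROI over a population filter.

    ``pairs`` has columns ``subject_id, diagnosis, metric, roi, value_test,
    value_retest`` (see :func:`amytrial.cohort.generate_trt_pairs`);
    ``population`` is ``CU_only`` or ``all``.
    """
    if population not in ("CU_only", "all"):
        raise ValueError(f"unknown population {population!r}")
    sub = pairs[(pairs["metric"] == metric) & (pairs["roi"] == roi)]
    if population == "CU_only":
        sub = sub[sub["diagnosis"] == "CU"]
    if len(sub) == 0:
        raise ValueError(
            f"no TRT pairs for metric={metric!r}, roi={roi!r}, population={population!r}"
        )
    vals = [
        trt_percent(row.value_test, row.value_retest) for row in sub.itertuples()
    ]
    return TrtSummary(metric, roi, population, len(vals), float(np.mean(vals)))


def classify_accumulators(
    fits: list[TrajectoryFit],
    trt: TrtSummary,
    stratum_by_subject: dict[str, str] | None = None,
) -> tuple[list[AccumulatorCall], pd.DataFrame]:
    """Classify subjects as accumulators against a TRT cutoff.

    A subject is an accumulator iff annualized % change is strictly above the
    cutoff.  Returns the per-subject calls and a per-stratum count table
    (stratum "all" row included; strata come from ``stratum_by_subject`` when
    given, otherwise a single pooled stratum is reported).
    """
    if not fits:
        raise ValueError("no trajectory fits to classify")
    if trt.trt_pct < 0:
        raise ValueError("cutoff must be non-negative")
    calls = [
        AccumulatorCall(
            f.subject_id, f.metric, f.roi, annualize_percent_change(f), trt.trt_pct
        )
        for f in fits
    ]
    rows = []
    strata: dict[str, list[AccumulatorCall]] = {"all": calls}
    if stratum_by_subject is not None:
        for c in calls:
            strata.setdefault(stratum_by_subject[c.subject_id], []).append(c)
    for stratum, group in strata.items():
        n_acc = sum(c.is_accumulator for c in group)
        rows.append(
            {
                "stratum": stratum,
                "n": len(group),
                "n_accumulators": n_acc,
                "pct_accumulators": 100.0 * n_acc / len(group),
            }
        )
    return calls, pd.DataFrame(rows)


def discordant_accumulators(
    calls_ref: list[AccumulatorCall], calls_other: list[AccumulatorCall]
) -> list[str]:
    """Subjects classified as accumulators by the reference metric's calls but
    not by the other metric's (e.g. accumulator by DVR, not by SUVR)."""
    other = {c.subject_id: c.is_accumulator for c in calls_other}
    return [
        c.subject_id
        for c in calls_ref
        if c.is_accumulator and not other.get(c.subject_id, False)
    ]
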