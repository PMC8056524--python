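"""Sample-size engine for two-arm trials on annualized amyloid accumulation rates.

The design throughout is a 1:1 randomized placebo-controlled trial whose
endpoint is the annualized % change of an amyloid-PET metric (SUVR or DVR,
cortical or early composite).  The treatment is assumed to reduce the group
mean accumulation rate by a stated fraction (default 20%) while leaving the
between-subject standard deviation unchanged.  Power is computed exactly from
the noncentral t distribution of the two-sample equal-variance t statistic
(df = 2n - 2, noncentrality ``delta = mean_diff / (sd * sqrt(2/n))``), i.e.
the same semantics as MATLAB's ``sampsizepwr`` — a normal approximation is
off by one subject in the large-n regime and is deliberately not used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TrialScenario",
    "SampleSizeResult",
    "power_two_sample_t",
    "required_n_per_arm",
    "power_curve",
    "effect_size_sweep",
    "scenario_table",
    "DEFAULT_SCENARIOS",
]


@dataclass(frozen=True)
class TrialScenario:
    """One hypothetical prevention-trial design.

    ``stratum`` names the baseline Centiloid inclusion window:
    ``intermediate_high`` (CL > 20.1, secondary prevention), ``intermediate``
    (20.1 < CL <= 49.4, early secondary prevention) or ``low`` (CL <= 20.1,
    primary prevention).
    """

    name: str
    stratum: str
    population: str = "all"  # all | carriers
    reduction_fraction: float = 0.20
    alpha: float = 0.05
    target_power: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 < self.reduction_fraction < 1.0:
            raise ValueError("reduction_fraction must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.target_power < 1.0:
            raise ValueError("target_power must be in (0, 1)")


@dataclass(frozen=True)
class SampleSizeResult:
    """Smallest per-arm n reaching the target power, with the bracketing powers."""

    mean_pct: float
    sd_pct: float
    mean_diff: float
    n_per_arm: int
    achieved_power: float
    power_at_n_minus_1: float
    scenario: TrialScenario | None = None


DEFAULT_SCENARIOS: tuple[TrialScenario, ...] = tuple(
    TrialScenario(name=name, stratum=stratum, population=pop)
    for name, stratum in [
        ("secondary_prevention", "intermediate_high"),
        ("early_secondary_prevention", "intermediate"),
        ("primary_prevention", "low"),
    ]
    for pop in ("all", "carriers")
)


def power_two_sample_t(
    n_per_arm: int, mean_diff: float, sd: float, alpha: float = 0.05
) -> float:
    """Exact power of the two-sided two-sample t-test with equal arms.

    Parameters
    ----------
    n_per_arm : subjects per arm (>= 2).
    mean_diff : true difference in group means (endpoint units, e.g. %/yr).
    sd : common between-subject standard deviation (> 0).
    alpha : two-sided type-I error rate.
    """
    if n_per_arm < 2:
        raise ValueError("n_per_arm must be >= 2")
    if sd <= 0:
        raise ValueError("sd must be positive")
    df = 2 * n_per_arm - 2
    delta = mean_diff / (sd * math.sqrt(2.0 / n_per_arm))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(
        1.0 - stats.nct.cdf(tcrit, df, delta) + stats.nct.cdf(-tcrit, df, delta)
    )


def required_n_per_arm(
    mean_pct: float,
    sd_pct: float,
    reduction_fraction: float = 0.20,
    alpha: float = 0.05,
    target_power: float = 0.80,
    scenario: TrialScenario | None = None,
) -> SampleSizeResult:
    """Smallest integer per-arm n detecting a fractional reduction of the mean rate.

    The detectable difference is ``reduction_fraction * mean_pct``; the search
    brackets the target power by doubling, then bisects to the minimal n.
    Minimality (power(n-1) < target <= power(n)) is asserted on every call.
    """
    if mean_pct <= 0:
        raise ValueError(
            "mean_pct must be positive: a fractional reduction of a non-positive "
            "accumulation rate is not a well-defined trial effect"
        )
    if sd_pct <= 0:
        raise ValueError("sd_pct must be positive")
    mean_diff = reduction_fraction * mean_pct

    lo, hi = 2, 2
    while power_two_sample_t(hi, mean_diff, sd_pct, alpha) < target_power:
        lo, hi = hi, hi * 2
        if hi > 10**8:  # pragma: no cover - absurd inputs
            raise RuntimeError("required n exceeds 1e8; check inputs")
    # invariant: power(hi) >= target; power(lo) may or may not reach it
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_two_sample_t(mid, mean_diff, sd_pct, alpha) >= target_power:
            hi = mid
        else:
            lo = mid
    n = hi if power_two_sample_t(lo, mean_diff, sd_pct, alpha) < target_power else lo
    p_n = power_two_sample_t(n, mean_diff, sd_pct, alpha)
    p_nm1 = power_two_sample_t(n - 1, mean_diff, sd_pct, alpha) if n > 2 else float("nan")
    assert p_n >= target_power and not (n > 2 and p_nm1 >= target_power), (
        "minimal-n bracketing violated"
    )
    return SampleSizeResult(
        mean_pct=mean_pct,
        sd_pct=sd_pct,
        mean_diff=mean_diff,
        n_per_arm=n,
        achieved_power=p_n,
        power_at_n_minus_1=p_nm1,
        scenario=scenario,
    )


def power_curve(
    mean_pct: float,
    sd_pct: float,
    reduction_fraction: float,
    n_grid,
    alpha: float = 0.05,
):
    """Achieved power along an increasing grid of per-arm sample sizes."""
    n_grid = np.asarray(n_grid, dtype=int)
    if n_grid.size == 0:
        raise ValueError("n_grid must be non-empty")
    if np.any(np.diff(n_grid) <= 0):
        raise ValueError("n_grid must be strictly increasing")
    mean_diff = reduction_fraction * mean_pct
    powers = np.array(
        [power_two_sample_t(int(n), mean_diff, sd_pct, alpha) for n in n_grid]
    )
    return n_grid, powers


def effect_size_sweep(
    mean_pct: float,
    sd_pct: float,
    reductions=(0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
    alpha: float = 0.05,
    target_power: float = 0.80,
) -> dict[float, SampleSizeResult]:
    """Required per-arm n across a range of treatment-effect sizes."""
    return {
        float(r): required_n_per_arm(mean_pct, sd_pct, r, alpha, target_power)
        for r in reductions
    }


def scenario_table(group_summaries, scenarios=DEFAULT_SCENARIOS):
    """Per-arm sample sizes for every scenario x metric x ROI combination.

    ``group_summaries`` is an iterable of objects with attributes
    ``stratum, population, metric, roi, mean_pct, sd_pct`` (see
    :class:`amytrial.trajectory.GroupRateSummary`).  Returns a pandas
    DataFrame shaped like the published per-arm requirement table, with the
    achieved power at n and at n - 1 carried along.
    """
    import pandas as pd

    lookup = {
        (g.stratum, g.population, g.metric, g.roi): g for g in group_summaries
    }
    rows = []
    for sc in scenarios:
        for metric in ("SUVR", "DVR"):
            for roi in ("cortical", "early"):
                key = (sc.stratum, sc.population, metric, roi)
                if key not in lookup:
                    raise KeyError(
                        f"no group summary for scenario {sc.name!r} "
                        f"({sc.stratum}/{sc.population}/{metric}/{roi})"
                    )
                g = lookup[key]
                res = required_n_per_arm(
                    g.mean_pct,
                    g.sd_pct,
                    sc.reduction_fraction,
                    sc.alpha,
                    sc.target_power,
                    scenario=sc,
                )
                rows.append(
                    {
                        "scenario": sc.name,
                        "stratum": sc.stratum,
                        "population": sc.population,
                        "metric": metric,
                        "roi": roi,
                        "mean_pct": g.mean_pct,
                        "sd_pct": g.sd_pct,
                        "n_per_arm": res.n_per_arm,
                        "achieved_power": res.achieved_power,
                        "power_at_n_minus_1": res.power_at_n_minus_1,
                    }
                )
    return pd.DataFrame(rows)
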