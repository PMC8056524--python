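"""Longitudinal trajectory estimation: random-intercept/random-slope mixed
models and annualized % change summaries.

Per-subject accumulation is estimated from a linear mixed-effects model
``value ~ time`` with correlated subject-level random intercepts and slopes,
fitted by maximum likelihood (ML rather than REML so that AIC comparisons
across fixed-effect structures remain valid).  Per-subject intercepts and
slopes are the empirical-Bayes (shrunken) predictions; if the mixed fit fails
to converge the model falls back to per-subject ordinary least squares and
flags it.  Annualized % change is 100 * slope / intercept, normalizing to the
model-estimated baseline rather than the noisy first observation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LongitudinalSeries",
    "TrajectoryFit",
    "GroupRateSummary",
    "fit_random_slopes",
    "annualize_percent_change",
    "summarize_group_rates",
    "series_from_frame",
]


@dataclass(frozen=True)
class LongitudinalSeries:
    """Observed values of one metric/ROI for one subject over sessions."""

    subject_id: str
    metric: str  # SUVR | DVR
    roi: str  # cortical | early
    times_yr: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_yr, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times_yr", t)
        object.__setattr__(self, "values", v)
        if t.size < 2 or t.shape != v.shape:
            raise ValueError("need >= 2 aligned (time, value) observations")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v <= 0):
            raise ValueError("metric values must be positive")


@dataclass(frozen=True)
class TrajectoryFit:
    subject_id: str
    metric: str
    roi: str
    intercept: float
    slope: float
    fit_method: str  # lme_blup | ols_fallback

    @property
    def annual_pct_change(self) -> float:
        return annualize_percent_change(self)


@dataclass(frozen=True)
class GroupRateSummary:
    """Group-level annualized accumulation: mean, SD and mean/SD effect size."""

    stratum: str
    population: str  # all | carriers | noncarriers
    metric: str
    roi: str
    n: int
    mean_pct: float
    sd_pct: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summaries need n >= 2")
        if self.sd_pct <= 0:
            raise ValueError("sd_pct must be positive")

    @property
    def effect_size(self) -> float:
        return self.mean_pct / self.sd_pct


def series_from_frame(frame: pd.DataFrame, metric: str, roi: str) -> list[LongitudinalSeries]:
    """Extract per-subject series for one metric/ROI from a long-format table
    with columns ``subject_id, time_yr, region, metric, value``."""
    sub = frame[(frame["metric"] == metric) & (frame["region"] == roi)]
    out = []
    for sid, grp in sub.groupby("subject_id", sort=True):
        grp = grp.sort_values("time_yr")
        if len(grp) < 2:
            continue
        out.append(
            LongitudinalSeries(
                str(sid), metric, roi, grp["time_yr"].to_numpy(), grp["value"].to_numpy()
            )
        )
    return out


def _ols_fits(series_set: list[LongitudinalSeries], method: str) -> list[TrajectoryFit]:
    fits = []
    for s in series_set:
        slope, intercept = np.polyfit(s.times_yr, s.values, 1)
        fits.append(
            TrajectoryFit(s.subject_id, s.metric, s.roi, float(intercept), float(slope), method)
        )
    return fits


def fit_random_slopes(series_set: list[LongitudinalSeries]) -> list[TrajectoryFit]:
    """Empirical-Bayes per-subject intercepts and slopes from a random
    intercept + random slope mixed model (ML).

    Falls back to per-subject OLS with ``fit_method='ols_fallback'`` and a
    warning if the variance components cannot be estimated.
    """
    if len(series_set) < 2:
        raise ValueError("mixed-model variance components need >= 2 subjects")
    metrics = {(s.metric, s.roi) for s in series_set}
    if len(metrics) != 1:
        raise ValueError("fit one metric/ROI at a time")
    times = np.concatenate([s.times_yr for s in series_set])
    values = np.concatenate([s.values for s in series_set])
    groups = np.concatenate(
        [np.repeat(s.subject_id, s.times_yr.size) for s in series_set]
    )
    if np.ptp(values) == 0 and np.ptp(times) == 0:
        raise ValueError("degenerate input: no variation in times or values")

    # degenerate zero-noise limit: per-subject residuals vanish, variance
    # components are unidentifiable and the OLS lines ARE the trajectories
    scale = float(np.max(np.abs(values)))
    max_resid = 0.0
    for s in series_set:
        coef = np.polyfit(s.times_yr, s.values, 1)
        max_resid = max(max_resid, float(np.max(np.abs(s.values - np.polyval(coef, s.times_yr)))))
    if max_resid <= 1e-10 * max(scale, 1.0):
        warnings.warn(
            "per-subject trajectories are exactly linear; mixed-model variance "
            "components are unidentifiable, using per-subject OLS",
            stacklevel=2,
        )
        return _ols_fits(series_set, "ols_fallback")

    import statsmodels.api as sm

    exog = sm.add_constant(times)
    result = None
    last_err = "optimizer did not converge"
    # powell first: quasi-Newton methods often stall on the near-boundary
    # variance components typical of 2-3 scans per subject
    for method in ("powell", "lbfgs", None):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(values, exog, groups=groups, exog_re=exog)
                kwargs = {} if method is None else {"method": method}
                candidate = model.fit(reml=False, **kwargs)
            if candidate.converged:
                result = candidate
                break
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_err = str(exc)
    if result is None:
        warnings.warn(
            f"mixed model did not converge ({last_err}); "
            "falling back to per-subject OLS",
            stacklevel=2,
        )
        return _ols_fits(series_set, "ols_fallback")

    fe_int, fe_slope = result.fe_params
    fits = []
    ranef = result.random_effects
    for s in series_set:
        re = ranef[s.subject_id]
        fits.append(
            TrajectoryFit(
                s.subject_id,
                s.metric,
                s.roi,
                float(fe_int + re.iloc[0]),
                float(fe_slope + re.iloc[1]),
                "lme_blup",
            )
        )
    return fits


def annualize_percent_change(fit: TrajectoryFit) -> float:
    """Annualized % change: 100 * slope / intercept."""
    if fit.intercept <= 0:
        raise ValueError("intercept must be positive to annualize % change")
    return 100.0 * fit.slope / fit.intercept


def summarize_group_rates(
    fits: list[TrajectoryFit],
    profiles,
    stratum: str,
    population: str = "all",
    stratum_by_subject: dict[str, str] | None = None,
) -> GroupRateSummary:
    """Mean, SD (n-1) and effect size of annualized % change within a stratum
    and population filter.

    ``stratum`` may be a single stratum name, ``intermediate_high`` (pooled
    CL > 20.1 subjects) or ``whole``.  Stratum membership defaults to the
    profiles' true stratum; pass ``stratum_by_subject`` to stratify on
    observed Centiloid instead.
    """
    by_sid = {p.subject_id: p for p in profiles}
    if stratum == "whole":
        member = lambda s: True  # noqa: E731
    elif stratum == "intermediate_high":
        member = lambda s: s in ("intermediate", "high")  # noqa: E731
    else:
        member = lambda s: s == stratum  # noqa: E731

    pcts = []
    metric = roi = None
    for f in fits:
        p = by_sid.get(f.subject_id)
        if p is None:
            raise KeyError(f"no profile for subject {f.subject_id!r}")
        s = (
            stratum_by_subject[f.subject_id]
            if stratum_by_subject is not None
            else p.stratum_true
        )
        if not member(s):
            continue
        if population == "carriers" and not p.apoe4_carrier:
            continue
        if population == "noncarriers" and p.apoe4_carrier:
            continue
        pcts.append(annualize_percent_change(f))
        metric, roi = f.metric, f.roi
    if len(pcts) < 2:
        raise ValueError(
            f"fewer than 2 subjects in stratum={stratum!r}, population={population!r}"
        )
    arr = np.asarray(pcts)
    return GroupRateSummary(
        stratum=stratum,
        population=population,
        metric=metric,
        roi=roi,
        n=arr.size,
        mean_pct=float(arr.mean()),
        sd_pct=float(arr.std(ddof=1)),
    )
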