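"""Cross-metric agreement and covariate analyses.

Three analyses accompany the power calculations to characterize the cohort:

* Bland-Altman comparison of SUVR against DVR (the reference metric), at
  baseline and for annualized % change.  Because a reference standard exists,
  the proportional bias slope is estimated by regressing the difference
  (SUVR - DVR) on the *reference* metric; the conventional slope against the
  pair mean is reported alongside.  Correlation is rank-based (Spearman rho)
  for baseline values and product-moment (Pearson r) for rates; the paired
  test is a t test when a Shapiro-Wilk screen on the differences does not
  reject normality at alpha = 0.05, and a Wilcoxon signed-rank test otherwise.
* Baseline-vs-rate curve shape: linear, quadratic and natural cubic spline
  (one interior knot at the median) fits compared by AIC under a Gaussian
  likelihood; the reported deltas are AIC(quadratic) - AIC(competitor), so a
  negative delta favors the quadratic.
* Covariate effects: a general linear model of baseline burden on age, sex
  and APOE-e4 carriership, and a baseline-adjusted linear model of per-subject
  accumulation rates on the same covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BlandAltmanFit",
    "CurveModelComparison",
    "CovariateEffect",
    "bland_altman",
    "compare_baseline_rate_models",
    "fit_covariate_models",
    "natural_cubic_spline_basis",
]


@dataclass(frozen=True)
class BlandAltmanFit:
    mean_bias: float
    bias_slope: float  # d(SUVR - DVR) per unit of the reference metric
    bias_slope_vs_mean: float  # conventional Bland-Altman slope vs pair mean
    intercept: float
    correlation: float
    correlation_kind: str  # spearman | pearson
    paired_test: str  # t | wilcoxon
    paired_test_p: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.correlation <= 1.0 + 1e-12:
            raise ValueError("correlation must lie in [-1, 1]")


def bland_altman(suvr, dvr, level: str = "baseline") -> BlandAltmanFit:
    """Agreement between SUVR and the reference metric DVR.

    ``level`` is ``baseline`` (Spearman correlation) or ``annual_pct``
    (Pearson correlation).  Differences are SUVR - DVR.
    """
    suvr = np.asarray(suvr, dtype=float)
    dvr = np.asarray(dvr, dtype=float)
    if suvr.shape != dvr.shape:
        raise ValueError("paired arrays must have equal length")
    if suvr.size < 3:
        raise ValueError("need at least 3 pairs")
    if level not in ("baseline", "annual_pct"):
        raise ValueError(f"unknown level {level!r}")

    diff = suvr - dvr
    pair_mean = 0.5 * (suvr + dvr)
    if np.ptp(dvr) > 0:
        slope_ref, intercept = np.polyfit(dvr, diff, 1)
    else:
        slope_ref, intercept = 0.0, float(diff.mean())
    slope_mean = float(np.polyfit(pair_mean, diff, 1)[0]) if np.ptp(pair_mean) > 0 else 0.0

    if np.allclose(suvr, dvr):
        corr, kind = 1.0, "identical"
        test_name, p = "t", 1.0
    else:
        if level == "baseline":
            corr, kind = stats.spearmanr(suvr, dvr)[0], "spearman"
        else:
            corr, kind = stats.pearsonr(suvr, dvr)[0], "pearson"
        if np.ptp(diff) == 0:
            test_name, p = "t", (1.0 if diff[0] == 0 else 0.0)
        else:
            shapiro_p = stats.shapiro(diff).pvalue
            if shapiro_p >= 0.05:
                test_name, p = "t", float(stats.ttest_rel(suvr, dvr).pvalue)
            else:
                test_name, p = "wilcoxon", float(stats.wilcoxon(suvr, dvr).pvalue)
    return BlandAltmanFit(
        mean_bias=float(diff.mean()),
        bias_slope=float(slope_ref),
        bias_slope_vs_mean=slope_mean,
        intercept=float(intercept),
        correlation=float(corr),
        correlation_kind=kind,
        paired_test=test_name,
        paired_test_p=float(p),
    )


def natural_cubic_spline_basis(x: np.ndarray, interior_knots, boundary=None) -> np.ndarray:
    """Natural cubic spline basis (without intercept or the linear column).

    Truncated-power construction with linearity constraints beyond the
    boundary knots; with K total knots the full spline space has dimension K,
    spanned by {1, x} plus the K - 2 columns returned here.
    """
    x = np.asarray(x, dtype=float)
    interior = np.atleast_1d(np.asarray(interior_knots, dtype=float))
    lo, hi = (x.min(), x.max()) if boundary is None else boundary
    knots = np.sort(np.concatenate([[lo], interior, [hi]]))
    kmax = knots[-1]
    k_last = knots[-2]

    def d(k):
        return (np.clip(x - k, 0, None) ** 3 - np.clip(x - kmax, 0, None) ** 3) / (
            kmax - k
        )

    cols = [d(k) - d(k_last) for k in knots[:-2]]
    return np.column_stack(cols)


@dataclass(frozen=True)
class CurveModelComparison:
    r_squared: dict[str, float]
    aic: dict[str, float]
    selected_model: str
    delta_aic: dict[str, float]  # AIC(quadratic) - AIC(model)

    def __post_init__(self) -> None:
        if self.aic[self.selected_model] > min(self.aic.values()) + 1e-9:
            raise ValueError("selected model must have minimal AIC")


def _gaussian_aic(y: np.ndarray, resid: np.ndarray, n_coef: int) -> float:
    n = y.size
    sigma2 = float(resid @ resid) / n  # ML variance estimate
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    k = n_coef + 1  # + sigma
    return 2.0 * k - 2.0 * loglik


def compare_baseline_rate_models(baseline, annual_pct) -> CurveModelComparison:
    """Which curve shape best links baseline burden to accumulation rate?

    Fits linear, quadratic and 1-interior-knot natural cubic spline models of
    annual % change on baseline value by least squares and compares AICs.
    """
    x = np.asarray(baseline, dtype=float)
    y = np.asarray(annual_pct, dtype=float)
    if x.shape != y.shape:
        raise ValueError("baseline and annual_pct must have equal length")
    if x.size < 10:
        raise ValueError("need at least 10 points for curve comparison")

    designs = {
        "linear": np.column_stack([np.ones_like(x), x]),
        "quadratic": np.column_stack([np.ones_like(x), x, x * x]),
        "natural_cubic_spline_1knot": np.column_stack(
            [np.ones_like(x), x, natural_cubic_spline_basis(x, [np.median(x)])]
        ),
    }
    aics, r2s = {}, {}
    for name, X in designs.items():
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError(f"rank-deficient design for {name} model")
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        aics[name] = _gaussian_aic(y, resid, X.shape[1])
        tss = float(((y - y.mean()) ** 2).sum())
        r2s[name] = 1.0 - float(resid @ resid) / tss if tss > 0 else 1.0
    selected = min(aics, key=aics.get)
    deltas = {name: aics["quadratic"] - a for name, a in aics.items()}
    return CurveModelComparison(r2s, aics, selected, deltas)


@dataclass(frozen=True)
class CovariateEffect:
    outcome: str  # baseline | rate
    term: str  # age | sex | apoe4 | baseline_adjustment
    beta: float
    t_stat: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def _ols_effects(y, columns: dict[str, np.ndarray], outcome: str) -> list[CovariateEffect]:
    import statsmodels.api as sm

    kept, names = [], []
    for name, col in columns.items():
        if np.ptp(col) == 0:
            warnings.warn(
                f"covariate {name!r} is constant and was dropped from the "
                f"{outcome} model",
                stacklevel=3,
            )
            continue
        kept.append(col)
        names.append(name)
    X = sm.add_constant(np.column_stack(kept))
    res = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return [
        CovariateEffect(
            outcome=outcome,
            term=name,
            beta=float(res.params[i + 1]),
            t_stat=float(res.tvalues[i + 1]),
            p_value=float(res.pvalues[i + 1]),
        )
        for i, name in enumerate(names)
    ]


def fit_covariate_models(
    baselines: dict[str, float],
    fits,
    profiles,
) -> list[CovariateEffect]:
    """Effects of age, sex and APOE-e4 on baseline burden and accumulation.

    ``baselines`` maps subject_id to baseline metric value; ``fits`` are
    :class:`~amytrial.trajectory.TrajectoryFit` objects (their annualized %
    change is the rate outcome); ``profiles`` supply the covariates.  The rate
    model additionally adjusts for baseline burden.  Constant covariates are
    dropped with a warning.
    """
    prof = {p.subject_id: p for p in profiles}
    missing = [f.subject_id for f in fits if f.subject_id not in prof]
    if missing:
        raise KeyError(f"profiles missing for subjects: {missing[:3]}")
    sids = [f.subject_id for f in fits]
    for sid in sids:
        if sid not in baselines:
            raise KeyError(f"baseline value missing for subject {sid!r}")

    age = np.array([prof[s].age_baseline for s in sids])
    sex = np.array([1.0 if prof[s].sex == "F" else 0.0 for s in sids])
    apoe = np.array([1.0 if prof[s].apoe4_carrier else 0.0 for s in sids])
    base = np.array([baselines[s] for s in sids])
    rate = np.array([f.annual_pct_change for f in fits])

    effects = _ols_effects(
        base, {"age": age, "sex": sex, "apoe4": apoe}, outcome="baseline"
    )
    effects += _ols_effects(
        rate,
        {"age": age, "sex": sex, "apoe4": apoe, "baseline_adjustment": base},
        outcome="rate",
    )
    return effects
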