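"""Treatment-effect estimation: binary and time-to-event endpoints.

Every endpoint is estimated three ways — unadjusted, ATT-weighted, and
multivariable covariate-adjusted — with patient-clustered robust
(sandwich) variance wherever a patient can contribute repeated LOTs.
The one exception is the *unadjusted* binary contrast, whose confidence
interval uses the classical Wald variance of the 2x2 table.

The hazard-ratio models use the Efron tie correction (day-resolution
real-world data tie often) and the Lin-Wei robust variance aggregated
over patients; the sandwich is CR0 (no small-sample correction) by
default, with the CR1 G/(G-1) rescaling available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy import stats

from .model import COVARIATES, RWPC, TRIAL, AnalysisSet
from .weighting import COVARIATE_LEVELS, WeightFit, design_matrix

ENDPOINTS = ("pfs", "ttnt", "os")
METHODS = ("unadjusted", "att", "multivariable")

Z95 = stats.norm.ppf(0.975)


class ZeroCellError(ValueError):
    """A 2x2 cell is empty; rerun with continuity=True to add 0.5 to all cells."""


class MonotoneLikelihoodError(ValueError):
    """No events in one arm: the partial likelihood is monotone."""


@dataclass
class EffectEstimate:
    endpoint: str  # ORR | pfs | ttnt | os
    measure: str  # odds_ratio | rate_ratio | hazard_ratio
    method: str  # unadjusted | att | multivariable
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_trial: int
    n_control: int
    note: str = ""

    def __post_init__(self) -> None:
        assert self.ci_low <= self.estimate <= self.ci_high


def _wald(log_est: float, se: float) -> tuple[float, float, float, float]:
    z = log_est / se
    p = 2 * stats.norm.sf(abs(z))
    return np.exp(log_est), np.exp(log_est - Z95 * se), np.exp(log_est + Z95 * se), p


@dataclass
class KMCurve:
    """Weighted product-limit estimate with exponential-Greenwood CIs."""

    times: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    at_risk: np.ndarray
    median: float  # inf when the curve never reaches 0.5
    median_ci: tuple[float, float]

    @property
    def median_defined(self) -> bool:
        return np.isfinite(self.median)

    def median_months(self, divisor: float = 30.4375) -> float:
        return self.median / divisor

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "at_risk": self.at_risk,
            }
        )


@dataclass
class ForestTerm:
    term: str
    level: str
    reference: bool
    estimate: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_value: Optional[float]
    n_trial: int
    n_control: int


@dataclass
class CoefficientForest:
    endpoint: str
    measure: str
    terms: list[ForestTerm] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.terms])


# ---------------------------------------------------------------------------
# Binary endpoint


def _orr_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Response-evaluable records only (missing responses excluded)."""
    return frame[frame["response"].notna()].copy()


def _counts_2x2(frame: pd.DataFrame) -> tuple[float, float, float, float]:
    t = frame["treat"] == 1
    a = float(((frame["response"] == 1) & t).sum())  # trial responders
    b = float(((frame["response"] == 0) & t).sum())
    c = float(((frame["response"] == 1) & ~t).sum())  # control responders
    d = float(((frame["response"] == 0) & ~t).sum())
    return a, b, c, d


def _unadjusted_binary(frame: pd.DataFrame, continuity: bool) -> tuple[EffectEstimate, EffectEstimate]:
    a, b, c, d = _counts_2x2(frame)
    note = ""
    if 0.0 in (a, b, c, d):
        if not continuity:
            raise ZeroCellError(
                "zero cell in the response 2x2 table; pass continuity=True to "
                "add 0.5 to every cell"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        note = "continuity correction: 0.5 added to all cells"
    n_t, n_c = int(a + b), int(c + d)

    log_or = np.log(a * d / (b * c))
    se_or = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    est, lo, hi, p = _wald(log_or, se_or)
    or_est = EffectEstimate("ORR", "odds_ratio", "unadjusted", est, lo, hi, p, n_t, n_c, note)

    p1, p0 = a / (a + b), c / (c + d)
    log_rr = np.log(p1 / p0)
    se_rr = np.sqrt((1 - p1) / (a + b) / p1 + (1 - p0) / (c + d) / p0)
    est, lo, hi, p = _wald(log_rr, se_rr)
    rr_est = EffectEstimate("ORR", "rate_ratio", "unadjusted", est, lo, hi, p, n_t, n_c, note)
    return or_est, rr_est


def _glm_binary(
    frame: pd.DataFrame,
    weights: Optional[np.ndarray],
    covariates: Optional[Sequence[str]],
    family,
    cr1: bool,
) -> tuple[float, float]:
    """Fit treat (+ covariates) GLM; return (log estimate, cluster-robust SE)."""
    y = frame["response"].to_numpy(float)
    X = pd.DataFrame({"treat": frame["treat"].to_numpy(float)}, index=frame.index)
    if covariates:
        X = pd.concat([X, design_matrix(frame, covariates)], axis=1)
    exog = sm.add_constant(X, has_constant="add")
    w = np.ones(len(frame)) if weights is None else np.asarray(weights, float)
    groups = pd.factorize(frame["patient_id"])[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, exog, family=family, var_weights=w)
        res = model.fit(
            maxiter=100, cov_type="cluster", cov_kwds={"groups": groups}
        )
        if not getattr(res, "converged", True):
            raise RuntimeError("GLM did not converge")
    i = list(exog.columns).index("treat")
    se = float(res.bse.iloc[i])
    if cr1:
        g = len(np.unique(groups))
        se *= np.sqrt(g / (g - 1))
    return float(res.params.iloc[i]), se


def binary_effect(
    analysis_set: AnalysisSet | pd.DataFrame,
    method: str,
    weights: Optional[np.ndarray] = None,
    covariates: Sequence[str] = COVARIATES,
    continuity: bool = False,
    cr1: bool = False,
) -> tuple[EffectEstimate, EffectEstimate]:
    """Odds ratio and response rate ratio for the binary response endpoint.

    ``weights`` must align with the full analysis frame; rows with a
    missing response are dropped here (together with their weights).
    The rate ratio comes from a log-link binomial model, falling back to
    a robust-variance Poisson model when the log-binomial fit fails.
    """
    frame = analysis_set.to_frame() if isinstance(analysis_set, AnalysisSet) else analysis_set
    if weights is not None:
        frame = frame.assign(_w=np.asarray(weights, float))
    frame = _orr_frame(frame)
    if method == "unadjusted":
        return _unadjusted_binary(frame, continuity)
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")

    w = frame["_w"].to_numpy() if "_w" in frame else None
    covs: Optional[Sequence[str]] = None
    if method == "multivariable":
        w, covs = None, covariates

    n_t = int((frame["treat"] == 1).sum())
    n_c = int((frame["treat"] == 0).sum())

    log_or, se_or = _glm_binary(frame, w, covs, sm.families.Binomial(), cr1)
    est, lo, hi, p = _wald(log_or, se_or)
    or_est = EffectEstimate("ORR", "odds_ratio", method, est, lo, hi, p, n_t, n_c)

    note = ""
    try:
        log_rr, se_rr = _glm_binary(
            frame, w, covs, sm.families.Binomial(link=sm.families.links.Log()), cr1
        )
    except Exception:
        log_rr, se_rr = _glm_binary(frame, w, covs, sm.families.Poisson(), cr1)
        note = "log-binomial fit failed; robust-Poisson fallback"
    est, lo, hi, p = _wald(log_rr, se_rr)
    rr_est = EffectEstimate("ORR", "rate_ratio", method, est, lo, hi, p, n_t, n_c, note)
    return or_est, rr_est


# ---------------------------------------------------------------------------
# Weighted Kaplan-Meier


def weighted_km(
    times: np.ndarray,
    events: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> KMCurve:
    """Weighted product-limit curve; the survival scale is invariant to
    rescaling all weights by a common factor."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    w = np.ones_like(times) if weights is None else np.asarray(weights, float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")

    kmf = KaplanMeierFitter(alpha=0.05)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(times, events, weights=w, label="s")
    surv = kmf.survival_function_["s"]
    ci = kmf.confidence_interval_
    med = float(kmf.median_survival_time_)
    med_ci_df = median_survival_times(kmf.confidence_interval_)
    med_lo = float(med_ci_df.iloc[0, 0])
    med_hi = float(med_ci_df.iloc[0, 1])
    at_risk = (
        kmf.event_table["at_risk"].reindex(surv.index).ffill().to_numpy(float)
    )
    return KMCurve(
        times=surv.index.to_numpy(float),
        survival=surv.to_numpy(float),
        ci_low=ci.iloc[:, 0].to_numpy(float),
        ci_high=ci.iloc[:, 1].to_numpy(float),
        at_risk=at_risk,
        median=med,
        median_ci=(med_lo, med_hi),
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards


def _cox_frame(
    frame: pd.DataFrame,
    endpoint: str,
    weights: Optional[np.ndarray],
    covariates: Optional[Sequence[str]],
) -> pd.DataFrame:
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}")
    df = pd.DataFrame(
        {
            "duration": frame[f"{endpoint}_days"].to_numpy(float),
            "event": frame[f"{endpoint}_event"].to_numpy(int),
            "treat": frame["treat"].to_numpy(float),
            "patient_id": frame["patient_id"].to_numpy(),
        },
        index=frame.index,
    )
    # Efron's partial likelihood needs strictly positive durations.
    df.loc[df["duration"] == 0, "duration"] = 0.5
    df["_w"] = np.ones(len(df)) if weights is None else np.asarray(weights, float)
    if covariates:
        df = pd.concat([df, design_matrix(frame, covariates)], axis=1)
    return df


def cox_model(
    analysis_set: AnalysisSet | pd.DataFrame,
    method: str,
    endpoint: str,
    weights: Optional[np.ndarray] = None,
    covariates: Sequence[str] = COVARIATES,
    robust: bool = True,
    cr1: bool = False,
) -> tuple[EffectEstimate, CoefficientForest]:
    """Weighted Cox PH model with Efron ties.

    ``method='att'`` uses the supplied weights and the treatment term
    only; ``method='multivariable'`` uses unit weights and adds all
    covariates; ``method='unadjusted'`` is treatment-only, unit weights.
    With ``robust=True`` the variance is the patient-clustered Lin-Wei
    sandwich (CR0; ``cr1=True`` applies the G/(G-1) rescaling).
    """
    frame = analysis_set.to_frame() if isinstance(analysis_set, AnalysisSet) else analysis_set
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if method != "att":
        weights = None
    covs: Optional[Sequence[str]] = covariates if method == "multivariable" else None

    df = _cox_frame(frame, endpoint, weights, covs)
    for arm, label in ((1, TRIAL), (0, RWPC)):
        if df.loc[df["treat"] == arm, "event"].sum() == 0:
            raise MonotoneLikelihoodError(
                f"no {endpoint} events in the {label} arm: hazard ratio is not identifiable"
            )

    cph = CoxPHFitter()
    fit_kwargs = dict(duration_col="duration", event_col="event", weights_col="_w")
    if robust:
        fit_kwargs["cluster_col"] = "patient_id"
        fit_df = df
    else:
        fit_df = df.drop(columns=["patient_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(fit_df, **fit_kwargs)

    summary = cph.summary
    g = frame["patient_id"].nunique()
    scale = np.sqrt(g / (g - 1)) if (cr1 and robust) else 1.0

    def extract(term: str) -> tuple[float, float, float, float]:
        log_hr = float(summary.loc[term, "coef"])
        se = float(summary.loc[term, "se(coef)"]) * scale
        return _wald(log_hr, se)

    est, lo, hi, p = extract("treat")
    n_t = int((frame["treat"] == 1).sum())
    n_c = int((frame["treat"] == 0).sum())
    effect = EffectEstimate(endpoint, "hazard_ratio", method, est, lo, hi, p, n_t, n_c)

    forest = CoefficientForest(endpoint=endpoint, measure="hazard_ratio")
    forest.terms.append(
        ForestTerm("treatment", "trial vs control", False, est, lo, hi, p, n_t, n_c)
    )
    if covs:
        _append_covariate_terms(forest, frame, summary, covs, extract)
    return effect, forest


def _append_covariate_terms(forest, frame, summary, covariates, extract) -> None:
    from .weighting import _level_indicator

    t = frame["treat"] == 1
    for cov in covariates:
        ref, levels = COVARIATE_LEVELS[cov]
        for level in (ref,) + levels:
            ind = _level_indicator(frame, cov, level).astype(bool)
            n_t, n_c = int((ind & t).sum()), int((ind & ~t).sum())
            name = f"{cov}={level}"
            if level == ref:
                forest.terms.append(
                    ForestTerm(cov, f"{level} (ref)", True, None, None, None, None, n_t, n_c)
                )
            else:
                est, lo, hi, p = extract(name)
                forest.terms.append(ForestTerm(cov, level, False, est, lo, hi, p, n_t, n_c))


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class ResultsBundle:
    effects: list[EffectEstimate] = field(default_factory=list)
    km: dict[str, KMCurve] = field(default_factory=dict)  # "{endpoint}:{arm}:{adjustment}"
    forests: dict[str, CoefficientForest] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def effect(self, endpoint: str, measure: str, method: str) -> EffectEstimate:
        for e in self.effects:
            if (e.endpoint, e.measure, e.method) == (endpoint, measure, method):
                return e
        raise KeyError((endpoint, measure, method))

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "effects": [vars(e) for e in self.effects],
            "medians_months": {
                key: (
                    None
                    if not curve.median_defined
                    else {
                        "median": curve.median_months(),
                        "ci_low": curve.median_ci[0] / 30.4375,
                        "ci_high": (
                            None
                            if not np.isfinite(curve.median_ci[1])
                            else curve.median_ci[1] / 30.4375
                        ),
                    }
                )
                for key, curve in self.km.items()
            },
        }


def run_all_endpoints(
    analysis_set: AnalysisSet | pd.DataFrame,
    fit: WeightFit,
    covariates: Sequence[str] = COVARIATES,
    continuity: bool = False,
    cr1: bool = False,
) -> ResultsBundle:
    """Full results grid: ORR three ways, and per time-to-event endpoint
    the unadjusted + ATT KM curves and unadjusted/ATT/multivariable HRs."""
    frame = analysis_set.to_frame() if isinstance(analysis_set, AnalysisSet) else analysis_set
    if fit.weight is None:
        raise ValueError("weights not computed: call att_weights() first")
    if len(frame) == 0 or (frame["treat"] == 0).sum() == 0 or (frame["treat"] == 1).sum() == 0:
        raise ValueError("both cohorts must be non-empty")
    w = fit.weight

    bundle = ResultsBundle()
    bundle.counts = {
        "n_trial": int((frame["treat"] == 1).sum()),
        "n_control_lots": int((frame["treat"] == 0).sum()),
        "n_control_patients": int(frame.loc[frame["treat"] == 0, "patient_id"].nunique()),
    }

    for method in METHODS:
        or_est, rr_est = binary_effect(
            frame, method, weights=w, covariates=covariates, continuity=continuity, cr1=cr1
        )
        bundle.effects += [or_est, rr_est]
        if method == "multivariable":
            bundle.forests["ORR"] = _orr_forest(frame, covariates, cr1)

    for endpoint in ENDPOINTS:
        tmask = frame["treat"] == 1
        tt, te = frame.loc[tmask, f"{endpoint}_days"], frame.loc[tmask, f"{endpoint}_event"]
        ct, ce = frame.loc[~tmask, f"{endpoint}_days"], frame.loc[~tmask, f"{endpoint}_event"]
        bundle.km[f"{endpoint}:trial:unadjusted"] = weighted_km(tt, te)
        bundle.km[f"{endpoint}:control:unadjusted"] = weighted_km(ct, ce)
        bundle.km[f"{endpoint}:trial:att"] = weighted_km(tt, te, w[tmask.to_numpy()])
        bundle.km[f"{endpoint}:control:att"] = weighted_km(ct, ce, w[~tmask.to_numpy()])
        for method in METHODS:
            effect, forest = cox_model(
                frame, method, endpoint, weights=w, covariates=covariates, cr1=cr1
            )
            bundle.effects.append(effect)
            if method == "multivariable":
                bundle.forests[endpoint] = forest
    return bundle


def _orr_forest(frame: pd.DataFrame, covariates: Sequence[str], cr1: bool) -> CoefficientForest:
    """Forest of multivariable odds ratios for the response endpoint."""
    sub = _orr_frame(frame)
    y = sub["response"].to_numpy(float)
    X = pd.DataFrame({"treat": sub["treat"].to_numpy(float)}, index=sub.index)
    X = pd.concat([X, design_matrix(sub, covariates)], axis=1)
    exog = sm.add_constant(X, has_constant="add")
    groups = pd.factorize(sub["patient_id"])[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, exog, family=sm.families.Binomial()).fit(
            maxiter=100, cov_type="cluster", cov_kwds={"groups": groups}
        )
    scale = np.sqrt(len(np.unique(groups)) / (len(np.unique(groups)) - 1)) if cr1 else 1.0

    def extract(term: str):
        i = list(exog.columns).index(term)
        return _wald(float(res.params.iloc[i]), float(res.bse.iloc[i]) * scale)

    forest = CoefficientForest(endpoint="ORR", measure="odds_ratio")
    t = sub["treat"] == 1
    est, lo, hi, p = extract("treat")
    forest.terms.append(
        ForestTerm("treatment", "trial vs control", False, est, lo, hi, p, int(t.sum()), int((~t).sum()))
    )
    summary = None
    _append_covariate_terms(forest, sub, summary, covariates, extract)
    return forest
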