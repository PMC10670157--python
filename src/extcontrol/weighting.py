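"""Propensity-score ATT weighting and covariate balance diagnostics.

The propensity score is the modelled probability of belonging to the
trial cohort given the baseline covariates.  Trial records keep weight
1 (the trial arm is the target population); each control record gets
the odds weight ps/(1-ps), then all control weights are rescaled by a
common factor so they sum to the number of control records — the
original sample size is preserved so that weighted analyses reflect the
real amount of information.

Balance is summarized by standardized mean differences (SMD), defined
here as (trial minus weighted-control) difference in level proportions
over the pooled binomial standard deviation; three-level covariates
additionally get a non-negative Mahalanobis-type summary across levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .model import AGE_LEVELS, COVARIATES, MET_SITES, PRIOR_LINES_LEVELS, AnalysisSet


class SeparationError(ValueError):
    """A covariate perfectly separates the two cohorts."""


class ConvergenceError(RuntimeError):
    """The propensity model did not converge."""


#: Covariate → (reference level, non-reference levels), in model order.
COVARIATE_LEVELS: dict[str, tuple[str, tuple[str, ...]]] = {
    "ecog": ("0", ("1",)),
    "prior_lines": (PRIOR_LINES_LEVELS[0], tuple(PRIOR_LINES_LEVELS[1:])),
    **{s: ("no", ("yes",)) for s in MET_SITES},
    "age_cat": (AGE_LEVELS[0], tuple(AGE_LEVELS[1:])),
}


def _level_indicator(frame: pd.DataFrame, covariate: str, level: str) -> np.ndarray:
    col = frame[covariate]
    if covariate == "ecog":
        return (col.astype(int).astype(str) == level).to_numpy(float)
    if covariate in MET_SITES:
        vals = col.to_numpy(float)
        if np.isnan(vals).any():
            raise ValueError(
                f"covariate {covariate!r} has missing values; impute before weighting"
            )
        return (vals == 1.0).astype(float) if level == "yes" else (vals == 0.0).astype(float)
    return (col.astype(str) == level).to_numpy(float)


def design_matrix(frame: pd.DataFrame, covariates: Sequence[str] = COVARIATES) -> pd.DataFrame:
    """Dummy-coded main-effects design (no intercept column).

    Reference levels: ECOG 0, one prior line, each metastatic site
    absent, age < 65.
    """
    cols = {}
    for cov in covariates:
        if cov not in COVARIATE_LEVELS:
            raise ValueError(f"unknown covariate {cov!r}")
        _, levels = COVARIATE_LEVELS[cov]
        for level in levels:
            cols[f"{cov}={level}"] = _level_indicator(frame, cov, level)
    return pd.DataFrame(cols, index=frame.index)


@dataclass
class WeightFit:
    """Propensity model fit plus per-record ATT weights."""

    coefficients: dict[str, float]
    ps: np.ndarray  # P(trial | covariates), aligned with the frame
    treat: np.ndarray  # 0/1 trial indicator
    patient_id: np.ndarray
    raw_weight: Optional[np.ndarray] = None
    weight: Optional[np.ndarray] = None
    renorm_factor: Optional[float] = None
    n_iterations: int = 0
    ridge_fallback: bool = False

    def overlap_summary(self) -> dict[str, tuple[float, float]]:
        """Min/max propensity score per cohort — an overlap diagnostic."""
        t = self.treat.astype(bool)
        return {
            "trial": (float(self.ps[t].min()), float(self.ps[t].max())),
            "control": (float(self.ps[~t].min()), float(self.ps[~t].max())),
        }


def _check_separation(y: np.ndarray, X: pd.DataFrame) -> None:
    # A binary dummy with a zero cell in its 2x2 against the outcome
    # drives the corresponding coefficient to +/- infinity.
    for name in X.columns:
        x = X[name].to_numpy()
        if x.min() == x.max():
            continue
        cells = [
            ((x == 1) & (y == 1)).sum(),
            ((x == 1) & (y == 0)).sum(),
            ((x == 0) & (y == 1)).sum(),
            ((x == 0) & (y == 0)).sum(),
        ]
        if 0 in cells:
            raise SeparationError(
                f"covariate level {name!r} perfectly separates the cohorts "
                f"(2x2 cells {cells})"
            )


def _irls_ridge(y: np.ndarray, X: np.ndarray, alpha: float = 1e-8, maxiter: int = 100) -> np.ndarray:
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta
        p = 1 / (1 + np.exp(-eta))
        w = np.clip(p * (1 - p), 1e-12, None)
        z = eta + (y - p) / w
        A = X.T @ (w[:, None] * X) + alpha * np.eye(X.shape[1])
        beta_new = np.linalg.solve(A, X.T @ (w * z))
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            return beta_new
        beta = beta_new
    return beta


def fit_propensity(
    analysis_set: AnalysisSet | pd.DataFrame,
    covariates: Sequence[str] = COVARIATES,
) -> WeightFit:
    """Multivariable logistic propensity model for trial membership.

    Raises :class:`SeparationError` naming the separating covariate
    level, or :class:`ConvergenceError` with the iteration count.
    """
    frame = analysis_set.to_frame() if isinstance(analysis_set, AnalysisSet) else analysis_set
    y = frame["treat"].to_numpy(float)
    X = design_matrix(frame, covariates)
    _check_separation(y, X)
    exog = sm.add_constant(X, has_constant="add")

    ridge = False
    n_iter = 0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, exog).fit(method="newton", maxiter=100, tol=1e-10, disp=0)
        if not res.mle_retvals.get("converged", False):
            raise ConvergenceError(
                f"propensity model did not converge: {res.mle_retvals}"
            )
        params = np.asarray(res.params, float)
        n_iter = int(res.mle_retvals.get("iterations", 0))
    except PerfectSeparationError as e:  # pragma: no cover - pre-check usually catches
        raise SeparationError(str(e)) from None
    except np.linalg.LinAlgError:
        # exact singularity: tiny ridge, reported loudly
        warnings.warn("singular design in propensity fit; using ridge(1e-8) fallback")
        params = _irls_ridge(y, exog.to_numpy(float))
        ridge = True

    ps = 1 / (1 + np.exp(-(exog.to_numpy(float) @ params)))
    coef = dict(zip(exog.columns, (float(b) for b in params)))
    return WeightFit(
        coefficients=coef,
        ps=ps,
        treat=y.astype(int),
        patient_id=frame["patient_id"].to_numpy(),
        n_iterations=n_iter,
        ridge_fallback=ridge,
    )


def att_weights(fit: WeightFit) -> WeightFit:
    """Fill in raw odds weights and sample-size-renormalized weights."""
    t = fit.treat.astype(bool)
    if np.any(fit.ps[~t] >= 1.0):
        raise ValueError("a control record has propensity score 1: infinite ATT weight")
    raw = np.where(t, 1.0, fit.ps / (1.0 - fit.ps))
    n_control = int((~t).sum())
    control_sum = raw[~t].sum()
    factor = n_control / control_sum if n_control else 1.0
    weight = np.where(t, 1.0, raw * factor)
    fit.raw_weight = raw
    fit.weight = weight
    fit.renorm_factor = float(factor)
    return fit


def smd_proportion(p_t: float, p_c: float) -> float:
    """Standardized difference of two proportions (trial minus control)."""
    var = (p_t * (1 - p_t) + p_c * (1 - p_c)) / 2
    if var == 0:
        return 0.0 if p_t == p_c else float("inf")
    return (p_t - p_c) / np.sqrt(var)


def smd_multilevel(p_t: np.ndarray, p_c: np.ndarray) -> float:
    """Mahalanobis-type summary SMD over the non-reference level proportions."""
    d = np.asarray(p_t) - np.asarray(p_c)
    k = len(d)
    S = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            S[i, j] = 0.5 * (
                p_t[i] * ((i == j) - p_t[j]) + p_c[i] * ((i == j) - p_c[j])
            )
    return float(np.sqrt(max(0.0, d @ np.linalg.pinv(S) @ d)))


@dataclass
class BalanceRow:
    covariate: str
    level: str
    freq_trial: float
    freq_control: float
    freq_control_weighted: float
    smd_unweighted: Optional[float]  # on the covariate summary row only
    smd_weighted: Optional[float]


@dataclass
class BalanceTable:
    rows: list[BalanceRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])

    def max_abs_smd(self, weighted: bool = True) -> float:
        vals = [
            abs(r.smd_weighted if weighted else r.smd_unweighted)
            for r in self.rows
            if (r.smd_weighted if weighted else r.smd_unweighted) is not None
        ]
        return max(vals)

    def summary_smds(self, weighted: bool = True) -> dict[str, float]:
        return {
            r.covariate: (r.smd_weighted if weighted else r.smd_unweighted)
            for r in self.rows
            if (r.smd_weighted if weighted else r.smd_unweighted) is not None
        }


def _weighted_prop(ind: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(ind * w) / np.sum(w))


def balance_table(
    analysis_set: AnalysisSet | pd.DataFrame,
    fit: WeightFit,
    covariates: Sequence[str] = COVARIATES,
) -> BalanceTable:
    """Per-covariate level frequencies and SMDs before/after weighting.

    For two-level covariates the summary SMD is the standardized
    difference for the index level; for three-level covariates it is the
    Mahalanobis-type summary, with per-level SMDs on the level rows.
    """
    if fit.weight is None:
        raise ValueError("call att_weights() before balance_table()")
    frame = analysis_set.to_frame() if isinstance(analysis_set, AnalysisSet) else analysis_set
    t = fit.treat.astype(bool)
    w_c = fit.weight[~t]

    table = BalanceTable()
    for cov in covariates:
        ref, levels = COVARIATE_LEVELS[cov]
        all_levels = (ref,) + levels
        p_t, p_c, p_cw, lvl_smd_u, lvl_smd_w = {}, {}, {}, {}, {}
        for level in all_levels:
            ind = _level_indicator(frame, cov, level)
            p_t[level] = float(ind[t].mean())
            p_c[level] = float(ind[~t].mean())
            p_cw[level] = _weighted_prop(ind[~t], w_c)
            lvl_smd_u[level] = smd_proportion(p_t[level], p_c[level])
            lvl_smd_w[level] = smd_proportion(p_t[level], p_cw[level])
        if len(levels) == 1:
            smd_u: float = lvl_smd_u[levels[0]]
            smd_w: float = lvl_smd_w[levels[0]]
        else:
            smd_u = smd_multilevel(
                [p_t[l] for l in levels], [p_c[l] for l in levels]
            )
            smd_w = smd_multilevel(
                [p_t[l] for l in levels], [p_cw[l] for l in levels]
            )
        table.rows.append(
            BalanceRow(cov, "(summary)", float("nan"), float("nan"), float("nan"), smd_u, smd_w)
        )
        for level in all_levels:
            table.rows.append(
                BalanceRow(
                    cov,
                    level,
                    p_t[level],
                    p_c[level],
                    p_cw[level],
                    None,
                    None,
                )
            )
    return table
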