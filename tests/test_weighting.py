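"""Propensity fitting, ATT weights and balance diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from extcontrol import (
    SeparationError,
    att_weights,
    balance_table,
    fit_propensity,
    smd_multilevel,
    smd_proportion,
)
from extcontrol.weighting import WeightFit


def _frame(treat, ecog, brain, pid=None):
    n = len(treat)
    return pd.DataFrame(
        {
            "patient_id": pid if pid is not None else [f"P{i}" for i in range(n)],
            "treat": treat,
            "ecog": ecog,
            "brain_met": [float(b) for b in brain],
        }
    )


def test_identical_covariate_distributions_give_constant_ps():
    # control records mirror the trial records exactly: the model has no
    # discriminating information, so every ps equals the trial fraction
    ecog = [0, 1, 0, 1, 1, 0] * 2
    brain = [1, 0, 0, 1, 1, 0] * 2
    frame = _frame([1] * 6 + [0] * 6, ecog, brain)
    fit = fit_propensity(frame, covariates=("ecog", "brain_met"))
    assert np.allclose(fit.ps, 0.5, atol=1e-6)


def test_logistic_fit_matches_direct_likelihood_maximization():
    """Newton-fitted coefficients agree with a brute-force optimizer on the
    exact log-likelihood for a small two-covariate dataset."""
    treat = [1, 1, 1, 1, 0, 0, 0, 0]
    ecog = [1, 0, 1, 0, 1, 0, 0, 0]
    brain = [1, 1, 0, 0, 1, 0, 1, 0]
    frame = _frame(treat, ecog, brain)
    fit = fit_propensity(frame, covariates=("ecog", "brain_met"))

    y = np.array(treat, float)
    X = np.column_stack([np.ones(8), ecog, brain]).astype(float)

    def nll(beta):
        eta = X @ beta
        return -np.sum(y * eta - np.log1p(np.exp(eta)))

    res = optimize.minimize(
        nll, np.zeros(3), method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000},
    )
    ours = np.array([fit.coefficients["const"], fit.coefficients["ecog=1"],
                     fit.coefficients["brain_met=yes"]])
    assert np.allclose(ours, res.x, atol=1e-4)


def test_separation_error_names_covariate():
    # brain metastasis present only among trial records
    frame = _frame([1, 1, 1, 0, 0, 0], [0, 1, 0, 1, 0, 1], [1, 1, 0, 0, 0, 0])
    with pytest.raises(SeparationError, match="brain_met"):
        fit_propensity(frame, covariates=("ecog", "brain_met"))


def test_fit_is_invariant_to_record_order(imputed_fixture):
    imputed, _ = imputed_fixture
    frame = imputed.to_frame()
    fit1 = fit_propensity(frame)
    shuffled = frame.sample(frac=1.0, random_state=0).reset_index(drop=True)
    fit2 = fit_propensity(shuffled)
    for k, v in fit1.coefficients.items():
        assert math.isclose(v, fit2.coefficients[k], rel_tol=1e-6, abs_tol=1e-8)


# -- ATT weights -------------------------------------------------------------


def test_ps_half_gives_raw_weight_one():
    fit = WeightFit(
        coefficients={},
        ps=np.array([0.8, 0.5]),
        treat=np.array([1, 0]),
        patient_id=np.array(["a", "b"]),
    )
    att_weights(fit)
    assert fit.raw_weight[1] == pytest.approx(1.0)
    assert fit.raw_weight[0] == 1.0


def test_control_ps_of_one_is_an_error():
    fit = WeightFit(
        coefficients={},
        ps=np.array([0.5, 1.0]),
        treat=np.array([1, 0]),
        patient_id=np.array(["a", "b"]),
    )
    with pytest.raises(ValueError, match="infinite"):
        att_weights(fit)


def test_control_weights_sum_to_n_control(imputed_fixture):
    imputed, _ = imputed_fixture
    fit = att_weights(fit_propensity(imputed.to_frame()))
    control = fit.treat == 0
    assert fit.weight[control].sum() == pytest.approx(55, abs=1e-9)
    assert np.all(fit.weight[~control] == 1.0)
    assert np.all(fit.weight > 0)


def test_renormalization_preserves_weight_ratios(imputed_fixture):
    imputed, _ = imputed_fixture
    fit = att_weights(fit_propensity(imputed.to_frame()))
    c = fit.treat == 0
    ratios = fit.weight[c][1:] / fit.weight[c][0]
    raw_ratios = fit.raw_weight[c][1:] / fit.raw_weight[c][0]
    assert np.allclose(ratios, raw_ratios, rtol=1e-12)


def test_balanced_cohorts_have_unit_renorm_factor():
    ecog = [0, 1, 0, 1, 1, 0] * 2
    brain = [1, 0, 0, 1, 1, 0] * 2
    frame = _frame([1] * 6 + [0] * 6, ecog, brain)
    fit = att_weights(fit_propensity(frame, covariates=("ecog", "brain_met")))
    assert fit.renorm_factor == pytest.approx(1.0, abs=1e-6)


# -- SMD ---------------------------------------------------------------------


def test_smd_formula_hand_value():
    # ECOG 1: 81/114 trial vs 32/55 control
    # hand evaluation: (0.710526 - 0.581818) / sqrt((0.205679 + 0.243306) / 2)
    assert smd_proportion(81 / 114, 32 / 55) == pytest.approx(0.271647, abs=5e-6)


def test_smd_zero_for_equal_proportions():
    assert smd_proportion(0.4, 0.4) == 0.0


def test_smd_degenerate_variance():
    assert smd_proportion(0.0, 0.0) == 0.0
    assert smd_proportion(1.0, 1.0) == 0.0
    assert math.isinf(smd_proportion(1.0, 0.0))


def test_multilevel_smd_nonnegative_and_zero_at_equality():
    p = np.array([0.3, 0.2])
    assert smd_multilevel(p, p) == pytest.approx(0.0, abs=1e-12)
    assert smd_multilevel([0.3, 0.2], [0.25, 0.3]) > 0


def test_balance_table_structure(imputed_fixture):
    imputed, _ = imputed_fixture
    frame = imputed.to_frame()
    fit = att_weights(fit_propensity(frame))
    table = balance_table(frame, fit)
    df = table.to_frame()
    assert set(df["covariate"]) == set(
        ("ecog", "prior_lines", "age_cat")
        + tuple(s for s in df["covariate"] if s.endswith("_met"))
    )
    # weighted level frequencies sum to 1 per covariate
    for cov, grp in df[df["level"] != "(summary)"].groupby("covariate"):
        assert grp["freq_control_weighted"].sum() == pytest.approx(1.0, abs=1e-9)
    assert np.isfinite(list(table.summary_smds(weighted=True).values())).all()


def test_weighting_balances_large_well_specified_cohorts():
    """Weighted control covariate means approach the trial means as n grows
    under a correctly specified propensity model."""
    from extcontrol import SimConfig, simulate_cohort

    frame = simulate_cohort(
        SimConfig(seed=101, n_trial=2000, n_control_patients=800, missing_block_prob=0.0)
    ).to_frame()
    fit = att_weights(fit_propensity(frame))
    table = balance_table(frame, fit)
    assert table.max_abs_smd(weighted=True) < 0.1
    assert table.max_abs_smd(weighted=True) < table.max_abs_smd(weighted=False)


def test_overlap_summary_bounds(imputed_fixture):
    imputed, _ = imputed_fixture
    fit = fit_propensity(imputed.to_frame())
    ov = fit.overlap_summary()
    for lo, hi in ov.values():
        assert 0 < lo <= hi < 1
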