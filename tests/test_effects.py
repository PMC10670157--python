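"""Effect estimation: binary contrasts, weighted KM, Cox models."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from extcontrol import (
    MonotoneLikelihoodError,
    ZeroCellError,
    binary_effect,
    cox_model,
    run_all_endpoints,
    weighted_km,
)


def orr_frame(n1, r1, n0, r0):
    """Two-arm response frame from counts (r responders of n)."""
    rows = []
    for i in range(n1):
        rows.append(dict(patient_id=f"T{i}", treat=1, response=float(i < r1)))
    for i in range(n0):
        rows.append(dict(patient_id=f"C{i}", treat=0, response=float(i < r0)))
    return pd.DataFrame(rows)


# -- binary endpoint ---------------------------------------------------------


def test_unadjusted_or_and_rr_from_published_counts():
    or_est, rr_est = binary_effect(orr_frame(114, 42, 54, 9), "unadjusted")
    assert (round(or_est.estimate, 2), round(or_est.ci_low, 2), round(or_est.ci_high, 2)) == (
        2.92, 1.30, 6.56,
    )
    assert (round(rr_est.estimate, 2), round(rr_est.ci_low, 2), round(rr_est.ci_high, 2)) == (
        2.21, 1.16, 4.20,
    )
    assert round(or_est.p_value, 4) == 0.0096
    assert round(rr_est.p_value, 4) == 0.0156


def test_identical_response_rates_give_unit_or_and_rr():
    or_est, rr_est = binary_effect(orr_frame(40, 10, 20, 5), "unadjusted")
    assert or_est.estimate == pytest.approx(1.0)
    assert rr_est.estimate == pytest.approx(1.0)


def test_zero_cell_raises_with_remedy():
    with pytest.raises(ZeroCellError, match="continuity"):
        binary_effect(orr_frame(10, 0, 10, 3), "unadjusted")
    or_est, _ = binary_effect(orr_frame(10, 0, 10, 3), "unadjusted", continuity=True)
    assert "continuity" in or_est.note
    assert or_est.estimate > 0


@settings(max_examples=100, derandomize=True)
@given(
    a=st.integers(1, 40), b=st.integers(1, 40),
    c=st.integers(1, 40), d=st.integers(1, 40),
)
def test_or_at_least_rr_for_harmful_direction(a, b, c, d):
    """Algebraic identity on 2x2 tables: OR >= RR whenever RR >= 1."""
    or_est, rr_est = binary_effect(orr_frame(a + b, a, c + d, c), "unadjusted")
    if rr_est.estimate >= 1:
        assert or_est.estimate >= rr_est.estimate - 1e-12


def test_weighted_logistic_reduces_to_unadjusted_with_unit_weights():
    frame = orr_frame(60, 20, 40, 8)
    or_u, _ = binary_effect(frame, "unadjusted")
    or_w, _ = binary_effect(frame, "att", weights=np.ones(100))
    assert or_w.estimate == pytest.approx(or_u.estimate, rel=1e-6)


# -- weighted Kaplan-Meier ---------------------------------------------------


def test_km_hand_product_limit():
    curve = weighted_km([1.0, 2.0], [True, True])
    assert np.allclose(curve.survival, [1.0, 0.5, 0.0])
    assert list(curve.times) == [0.0, 1.0, 2.0]


def test_km_weight_scale_invariance():
    rng = np.random.default_rng(0)
    t = rng.exponential(10, 60)
    e = rng.random(60) < 0.8
    w = rng.uniform(0.5, 2.0, 60)
    c1 = weighted_km(t, e, w)
    c2 = weighted_km(t, e, 2 * w)
    assert np.allclose(c1.survival, c2.survival)
    assert c1.median == c2.median


def test_km_unit_weights_match_classical_product_limit():
    rng = np.random.default_rng(1)
    t = np.round(rng.exponential(10, 50), 1)
    e = rng.random(50) < 0.7
    curve = weighted_km(t, e)

    # hand-rolled classical estimator
    order = np.argsort(t)
    surv, s = {}, 1.0
    at_risk = len(t)
    for time in np.unique(t[order]):
        d = int(np.sum((t == time) & e))
        n = int(np.sum(t >= time))
        if d:
            s *= 1 - d / n
        surv[time] = s
    for time, sval in surv.items():
        i = np.searchsorted(curve.times, time)
        assert curve.survival[i] == pytest.approx(sval, abs=1e-12)


def test_km_all_censored_median_undefined_not_fatal():
    curve = weighted_km([5.0, 7.0, 9.0], [False, False, False])
    assert not curve.median_defined
    assert np.allclose(curve.survival, 1.0)


# -- Cox ---------------------------------------------------------------------

TINY = pd.DataFrame(
    {
        "patient_id": list("abcdef"),
        "treat": [1, 1, 1, 0, 0, 0],
        "pfs_days": [3, 10, 7, 1, 5, 8],
        "pfs_event": [1, 0, 1, 1, 1, 1],
    }
)


def _partial_loglik(beta, t, e, x):
    ll = 0.0
    for i in range(len(t)):
        if e[i]:
            risk = x[t >= t[i]]
            ll += beta * x[i] - math.log(np.sum(np.exp(beta * risk)))
    return ll


def test_cox_coefficient_matches_bruteforce_partial_likelihood():
    est, _ = cox_model(TINY, "unadjusted", "pfs", robust=False)
    t = TINY["pfs_days"].to_numpy(float)
    e = TINY["pfs_event"].to_numpy(bool)
    x = TINY["treat"].to_numpy(float)
    res = optimize.minimize_scalar(
        lambda b: -_partial_loglik(b, t, e, x), bounds=(-10, 10), method="bounded",
        options={"xatol": 1e-12},
    )
    assert math.log(est.estimate) == pytest.approx(res.x, abs=1e-5)


def test_cox_naive_se_matches_numerical_information():
    est, _ = cox_model(TINY, "unadjusted", "pfs", robust=False)
    t = TINY["pfs_days"].to_numpy(float)
    e = TINY["pfs_event"].to_numpy(bool)
    x = TINY["treat"].to_numpy(float)
    b = math.log(est.estimate)
    h = 1e-5
    second = (
        _partial_loglik(b + h, t, e, x)
        - 2 * _partial_loglik(b, t, e, x)
        + _partial_loglik(b - h, t, e, x)
    ) / h**2
    se_oracle = 1 / math.sqrt(-second)
    se_ours = (math.log(est.ci_high) - math.log(est.estimate)) / 1.959963984540054
    assert se_ours == pytest.approx(se_oracle, abs=1e-4)


def test_cox_unit_weights_singleton_clusters_reduce_to_plain_fit():
    import lifelines

    est, _ = cox_model(TINY, "unadjusted", "pfs", robust=False)
    df = TINY[["pfs_days", "pfs_event", "treat"]].astype(float)
    cph = lifelines.CoxPHFitter().fit(df, "pfs_days", "pfs_event")
    assert math.log(est.estimate) == pytest.approx(
        float(cph.summary.loc["treat", "coef"]), abs=1e-8
    )
    se_ours = (math.log(est.ci_high) - math.log(est.estimate)) / 1.959963984540054
    assert se_ours == pytest.approx(float(cph.summary.loc["treat", "se(coef)"]), abs=1e-8)


def test_monotone_likelihood_error_names_arm():
    df = TINY.copy()
    df.loc[df["treat"] == 1, "pfs_event"] = 0
    with pytest.raises(MonotoneLikelihoodError, match="TRIAL"):
        cox_model(df, "unadjusted", "pfs")


def test_cluster_robust_se_exceeds_naive_under_frailty():
    from extcontrol import SimConfig, simulate_cohort
    from extcontrol.simulate import HazardModel

    hz = {
        "pfs": HazardModel(rate=math.log(2) / 148),
        "os": HazardModel(rate=math.log(2) / 349),
        "ttnt": HazardModel(rate=1 / 33.0),
    }
    frame = simulate_cohort(
        SimConfig(seed=31, n_trial=150, n_control_patients=80, lot_rate=3.0,
                  frailty_variance=2.0, hazard_models=hz, missing_block_prob=0.0)
    ).to_frame()
    robust, _ = cox_model(frame, "unadjusted", "os", robust=True)
    naive, _ = cox_model(frame, "unadjusted", "os", robust=False)

    def se(e):
        return (math.log(e.ci_high) - math.log(e.estimate)) / 1.959963984540054

    assert se(robust) > se(naive)


# -- orchestration -----------------------------------------------------------


def test_run_all_endpoints_bundle_shape(imputed_fixture):
    from extcontrol import att_weights, fit_propensity

    imputed, _ = imputed_fixture
    frame = imputed.to_frame()
    fit = att_weights(fit_propensity(frame))
    bundle = run_all_endpoints(frame, fit)
    assert len(bundle.effects) == 6 + 9  # ORR OR+RR x3 methods, HR x3 endpoints x3
    assert len(bundle.km) == 12  # 3 endpoints x 2 arms x 2 adjustments
    assert set(bundle.forests) == {"ORR", "pfs", "ttnt", "os"}
    assert bundle.counts["n_control_patients"] == 38
    # every CI covers its point estimate
    for e in bundle.effects:
        assert e.ci_low <= e.estimate <= e.ci_high


def test_run_all_endpoints_empty_control_is_structured_error(imputed_fixture):
    from extcontrol import att_weights, fit_propensity

    imputed, _ = imputed_fixture
    frame = imputed.to_frame()
    fit = att_weights(fit_propensity(frame))
    trial_only = frame[frame["treat"] == 1]
    with pytest.raises(ValueError, match="non-empty"):
        run_all_endpoints(trial_only, fit)


def test_forest_reference_levels_carry_no_estimate(imputed_fixture):
    from extcontrol import att_weights, fit_propensity

    imputed, _ = imputed_fixture
    frame = imputed.to_frame()
    fit = att_weights(fit_propensity(frame))
    _, forest = cox_model(frame, "multivariable", "os", weights=fit.weight)
    refs = [t for t in forest.terms if t.reference]
    assert len(refs) == 10  # one per covariate
    assert all(t.estimate is None for t in refs)
    nonrefs = [t for t in forest.terms if not t.reference]
    assert all(t.estimate is not None for t in nonrefs)
    for t in forest.terms:
        if t.term != "treatment":
            assert t.n_trial + t.n_control > 0
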