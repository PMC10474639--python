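"""Censoring models and inverse-probability weights.

The hand cohort gives known censoring-process durations in both arms and a
single varying binary covariate (sex), so the Cox coefficient can be checked
against a direct numeric optimization of the written-out Breslow partial
likelihood (and against statsmodels), and the treated arm even has a closed
form: with censoring events only at grace end, the score equation solves to
beta = log(0.6) on this data.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from cloneweight import CensoringWeightModel, compute_weights, truncate_weights
from cloneweight.coxph import CoxBreslowFit
from cloneweight.errors import (
    ConfigurationError,
    NoCensoringEventsError,
    WeightUnderflowError,
)
from cloneweight.ipcw import (
    CensoringModel,
    balance_smd,
    censoring_durations,
    fit_censoring_model,
    weights_at,
)
from cloneweight.simulate import DESIGN_COLUMNS

SEX_IDX = DESIGN_COLUMNS.index("sex")


def _arm(clones, arm):
    return clones.loc[clones["arm"] == arm].reset_index(drop=True)


def breslow_negloglik(beta, time, delta, x):
    """Written-out Breslow partial log-likelihood, one covariate."""
    ll = 0.0
    for u in np.unique(time[delta]):
        tied = delta & (time == u)
        risk = time >= u
        ll += beta * x[tied].sum() - tied.sum() * np.log(np.exp(beta * x[risk]).sum())
    return -ll


def reference_beta(time, delta, x):
    res = minimize_scalar(
        breslow_negloglik, bounds=(-10, 10), args=(time, delta, x), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def test_hand_censoring_durations(hand_clones):
    time_c, delta_c = censoring_durations(_arm(hand_clones, "control"), 5)
    assert time_c.tolist() == [2.0, 4.0, 1.0, 1.0, 5.0, 5.0, 2.5, 5.0, 5.0, 4.5]
    assert delta_c.tolist() == [True, True, True, True, False, False, False, False, False, False]
    time_t, delta_t = censoring_durations(_arm(hand_clones, "treated"), 5)
    assert time_t.tolist() == [5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 2.5, 5.0, 5.0, 4.5]
    assert delta_t.tolist() == [False, False, False, False, True, True, False, True, True, False]


def test_hand_cox_coefficient_matches_numeric_optimum(hand_clones):
    for arm in ("treated", "control"):
        sub = _arm(hand_clones, arm)
        model = fit_censoring_model(sub, DESIGN_COLUMNS, grace_days=5)
        time, delta = censoring_durations(sub, 5)
        x = sub["sex"].to_numpy(dtype=float)
        ref = reference_beta(time, delta, x)
        assert model.coefficients[SEX_IDX] == pytest.approx(ref, abs=1e-4)
        # every constant covariate gets a zero coefficient
        others = np.delete(model.coefficients, SEX_IDX)
        assert np.allclose(others, 0.0)


def test_hand_treated_cox_coefficient_closed_form(hand_clones):
    # single censoring time at day 5: score = 2 - 4 * 5r/(5r+3) = 0 => r = 0.6
    model = fit_censoring_model(_arm(hand_clones, "treated"), DESIGN_COLUMNS, 5)
    assert model.coefficients[SEX_IDX] == pytest.approx(np.log(0.6), abs=1e-6)


def test_hand_cox_coefficient_matches_statsmodels(hand_clones):
    from statsmodels.duration.hazard_regression import PHReg

    for arm in ("treated", "control"):
        sub = _arm(hand_clones, arm)
        time, delta = censoring_durations(sub, 5)
        x = sub["sex"].to_numpy(dtype=float)[:, None]
        sm_beta = float(PHReg(time, x, status=delta.astype(int), ties="breslow").fit().params[0])
        model = fit_censoring_model(sub, DESIGN_COLUMNS, 5)
        assert model.coefficients[SEX_IDX] == pytest.approx(sm_beta, abs=1e-5)


def test_constant_covariates_reduce_to_nelson_aalen(hand_clones):
    # all-constant design: beta = 0 and the baseline cumulative hazard equals
    # the Nelson-Aalen estimator of the censoring times
    sub = _arm(hand_clones, "control")
    model = fit_censoring_model(sub, ("age", "charlson_ge2"), grace_days=5)
    assert np.allclose(model.coefficients, 0.0)
    # hand Nelson-Aalen: events at 1 (2/10), 2 (1/8), 4 (1/6)
    expected = {1.0: 2 / 10, 2.0: 2 / 10 + 1 / 8, 4.0: 2 / 10 + 1 / 8 + 1 / 6}
    base = model.baseline_cumhaz
    assert dict(zip(base.index, base.to_numpy())) == pytest.approx(expected)


def test_uncensored_probability_closed_forms():
    fit = CoxBreslowFit(
        coef=np.array([np.log(2.0)]),
        mean=np.zeros(1),
        baseline_times=np.array([3.0, 5.0]),
        baseline_cumhaz_mean=np.array([0.2, 0.5]),
        loglik=0.0,
        n_iter=1,
        converged=True,
    )
    model = CensoringModel("control", ("z",), 5, fit)
    Z0 = np.zeros((1, 1))
    Z1 = np.ones((1, 1))
    assert model.uncensored_probability(Z0, 0.0) == pytest.approx(1.0)
    assert model.uncensored_probability(Z0, 3.0) == pytest.approx(np.exp(-0.2))
    assert model.uncensored_probability(Z1, 5.0) == pytest.approx(np.exp(-1.0))
    # constant beyond the grace period
    assert model.uncensored_probability(Z1, 30.0) == pytest.approx(np.exp(-1.0))


def test_weight_is_reciprocal_and_constant_after_grace():
    fit = CoxBreslowFit(
        coef=np.zeros(1),
        mean=np.zeros(1),
        baseline_times=np.array([5.0]),
        baseline_cumhaz_mean=np.array([np.log(2.0)]),
        loglik=0.0,
        n_iter=1,
        converged=True,
    )
    model = CensoringModel("treated", ("z",), 5, fit)
    clones = pd.DataFrame(
        {"patient_id": [1], "arm": ["treated"], "z": [0.0], "followup_end": [45]}
    )
    # S_C(5) = 0.5 => weight 2 from day 5 onward
    for day in (5, 20, 45):
        w = weights_at({"treated": model}, clones, day, grace_days=5)
        assert w[0] == pytest.approx(2.0)
    assert weights_at({"treated": model}, clones, 0, grace_days=5)[0] == pytest.approx(1.0)


def test_no_censoring_events_raise_or_degenerate(hand_clones):
    sub = _arm(hand_clones, "control")
    uncens = sub.loc[sub["censor_indicator"] == 0].reset_index(drop=True)
    with pytest.raises(NoCensoringEventsError):
        fit_censoring_model(uncens, DESIGN_COLUMNS, 5, on_no_events="raise")
    model = fit_censoring_model(uncens, DESIGN_COLUMNS, 5, on_no_events="degenerate")
    assert model.degenerate
    X = np.zeros((3, len(DESIGN_COLUMNS)))
    assert np.allclose(model.uncensored_probability(X, 5.0), 1.0)


def test_weight_table_structure(hand_clones):
    wm = CensoringWeightModel().fit(hand_clones)
    table = wm.transform(hand_clones)
    assert list(table.columns) == ["patient_id", "arm", "day", "weight"]
    # one row per clone-day at risk
    expected_rows = int((hand_clones["followup_end"] + 1).sum())
    assert len(table) == expected_rows
    assert (table.loc[table["day"] == 0, "weight"] == 1.0).all()
    for (_, _), grp in table.groupby(["patient_id", "arm"]):
        w = grp.sort_values("day")["weight"].to_numpy()
        assert (np.diff(w) >= -1e-12).all()
        after = grp.loc[grp["day"] >= 5, "weight"].to_numpy()
        if after.size:
            assert np.allclose(after, after[0])


def test_weight_underflow_error_names_patients(hand_clones):
    wm = CensoringWeightModel(min_survival=0.999).fit(hand_clones)
    with pytest.raises(WeightUnderflowError):
        wm.transform(hand_clones)


def test_truncation_caps_at_quantile():
    table = pd.DataFrame(
        {
            "patient_id": [1, 2, 3, 4],
            "arm": ["treated"] * 4,
            "day": [5] * 4,
            "weight": [1.0, 1.0, 2.0, 10.0],
        }
    )
    out = truncate_weights(table, 0.75)
    cap = float(np.quantile([1.0, 1.0, 2.0, 10.0], 0.75))
    assert out["weight"].tolist() == [1.0, 1.0, 2.0, cap]
    assert truncate_weights(table, 1.0)["weight"].tolist() == [1.0, 1.0, 2.0, 10.0]
    with pytest.raises(ConfigurationError):
        truncate_weights(table, 0.4)


def test_balance_smd_arithmetic():
    clones = pd.DataFrame(
        {
            "patient_id": [1, 2, 3, 4],
            "arm": ["treated", "treated", "control", "control"],
            "censor_indicator": [0, 0, 0, 0],
            "x": [1.0, 3.0, 2.0, 6.0],
            "b": [1.0, 1.0, 0.0, 1.0],
        }
    )
    w = np.ones(4)
    out = balance_smd(clones, w, ("x", "b"), at_day=5, grace_days=5)
    # continuous: |2-4| / sqrt((1+4)/2); binary: |1-0.5| / sqrt((0+0.25)/2)
    x_row = out.loc[out["covariate"] == "x"].iloc[0]
    assert x_row["smd_unweighted"] == pytest.approx(2.0 / np.sqrt(2.5))
    b_row = out.loc[out["covariate"] == "b"].iloc[0]
    assert b_row["smd_unweighted"] == pytest.approx(0.5 / np.sqrt(0.125))
    with pytest.raises(ConfigurationError):
        balance_smd(clones, w, ("x",), at_day=3, grace_days=5)


def test_weighting_improves_balance(small_cohort):
    from cloneweight import apply_eligibility, clone_and_censor

    eligible, _ = apply_eligibility(small_cohort)
    clones = clone_and_censor(eligible)
    wm = CensoringWeightModel().fit(clones)
    bal = wm.balance(clones)
    assert bal["smd_weighted"].max() < bal["smd_unweighted"].max()


def test_estimator_is_sklearn_clonable(hand_clones):
    from sklearn.base import clone as sk_clone

    wm = CensoringWeightModel(truncation_quantile=0.99)
    wm2 = sk_clone(wm)
    assert wm2.get_params() == wm.get_params()
    t1 = wm.fit_transform(hand_clones)
    t2 = wm2.fit(hand_clones).transform(hand_clones)
    pd.testing.assert_frame_equal(t1, t2)
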