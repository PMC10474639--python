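"""Weighted Nelson-Aalen / Aalen-Johansen estimation.

Reductions are checked against lifelines (Nelson-Aalen, Kaplan-Meier) and the
classical cumulative-incidence formula; the hand fixture is checked against an
independent from-first-principles product-integral that never touches the
package's long-format machinery; row-stochasticity is property-based.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cloneweight import (
    CensoringWeightModel,
    WeightedAalenJohansen,
    aalen_johansen,
    build_long_format,
    state_occupation,
    weighted_nelson_aalen,
)
from cloneweight.errors import EstimationError, SchemaError
from cloneweight.multistate import CumulativeHazardSet, LONG_COLUMNS
from cloneweight.states import DEATH, HCF, HOME, ICU, WARD, TransitionStructure

TWO_STATE = TransitionStructure(states=(WARD, DEATH), allowed=((WARD, DEATH),),
                                absorbing=frozenset({DEATH}))
COMPETING = TransitionStructure(states=(WARD, DEATH, HOME),
                                allowed=((WARD, DEATH), (WARD, HOME)),
                                absorbing=frozenset({DEATH, HOME}))


def make_clones(specs):
    """Clone rows from (followup_end, event_state, icu_day) tuples; an
    event_state of 0 means administrative censoring at followup_end."""
    rows = []
    for i, (fe, es, icu) in enumerate(specs):
        rows.append(
            {
                "patient_id": i + 1,
                "arm": "treated",
                "censor_day": np.nan,
                "censor_indicator": 0,
                "followup_end": int(fe),
                "end_reason": "event" if es else "administrative",
                "terminal_state": es if es else (ICU if not np.isnan(icu) else WARD),
                "icu_day": icu,
                "event_day": float(fe) if es else np.nan,
                "event_state": int(es),
            }
        )
    return pd.DataFrame(rows)


def test_long_format_single_death():
    clones = make_clones([(1, DEATH, np.nan), (3, 0, np.nan)])
    long = build_long_format(clones, None)
    assert list(long.columns) == list(LONG_COLUMNS)
    # clone 1: one day at risk, four ward destinations; clone 2: three days
    assert len(long) == 4 * (1 + 3)
    ev = long.loc[long["status"] == 1]
    assert len(ev) == 1
    row = ev.iloc[0]
    assert (row["day"], row["from_state"], row["to_state"]) == (1, WARD, DEATH)
    assert (long["weight"] == 1.0).all()


def test_long_format_icu_start_of_day_convention():
    clones = make_clones([(10, DEATH, 4.0)])
    long = build_long_format(clones, None)
    # transfer day 4 still counts as a ward day (transition out of ward)
    assert set(long.loc[long["day"] <= 4, "from_state"]) == {WARD}
    assert set(long.loc[long["day"] > 4, "from_state"]) == {ICU}
    ev = long.loc[long["status"] == 1]
    assert {(r["day"], r["from_state"], r["to_state"]) for _, r in ev.iterrows()} == {
        (4, WARD, ICU),
        (10, ICU, DEATH),
    }


def test_long_format_rejects_disallowed_transition():
    clones = make_clones([(6, DEATH, 2.0)])
    no_icu_edge = TransitionStructure(
        states=(WARD, ICU, DEATH), allowed=((WARD, DEATH), (ICU, DEATH)),
        absorbing=frozenset({DEATH}),
    )
    with pytest.raises(SchemaError):
        build_long_format(clones, None, no_icu_edge)


def test_long_format_missing_weight_raises():
    clones = make_clones([(2, DEATH, np.nan)])
    table = pd.DataFrame(
        {"patient_id": [1], "arm": ["treated"], "day": [0], "weight": [1.0]}
    )  # day 1 (for risk day 2) is missing
    with pytest.raises(SchemaError):
        build_long_format(clones, table)


def test_hand_nelson_aalen_increment():
    # two unit-weight clones, one death at day 1: increment 1/2, and the
    # one-day transition probability P(ward, death) = 0.5
    clones = make_clones([(1, DEATH, np.nan), (5, 0, np.nan)])
    long = build_long_format(clones, None, TWO_STATE)
    cumhaz = weighted_nelson_aalen(long, TWO_STATE)
    inc = cumhaz.increments(WARD, DEATH)
    assert inc["day"].tolist() == [1]
    assert inc["increment"].tolist() == [0.5]
    series = aalen_johansen(cumhaz, TWO_STATE, s=0, horizon=5)
    P1 = series.matrix(1)
    assert P1[0, 0] == pytest.approx(0.5)
    assert P1[0, 1] == pytest.approx(0.5)


def test_unit_weight_nelson_aalen_matches_lifelines():
    from lifelines import NelsonAalenFitter

    specs = [(1, DEATH, np.nan), (2, 0, np.nan), (2, DEATH, np.nan),
             (4, DEATH, np.nan), (4, DEATH, np.nan), (6, 0, np.nan), (7, DEATH, np.nan)]
    clones = make_clones(specs)
    long = build_long_format(clones, None, TWO_STATE)
    inc = weighted_nelson_aalen(long, TWO_STATE).increments(WARD, DEATH)
    naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
    durations = [fe for fe, _, _ in specs]
    observed = [1 if es else 0 for _, es, _ in specs]
    naf.fit(durations, observed)
    for _, row in inc.iterrows():
        expected = float(naf.cumulative_hazard_.loc[row["day"]].iloc[0])
        assert row["cumulative"] == pytest.approx(expected, abs=1e-12)


def test_two_state_equals_one_minus_kaplan_meier():
    from lifelines import KaplanMeierFitter

    specs = [(1, DEATH, np.nan), (2, 0, np.nan), (3, DEATH, np.nan), (3, DEATH, np.nan),
             (5, 0, np.nan), (6, DEATH, np.nan), (8, 0, np.nan), (9, DEATH, np.nan)]
    clones = make_clones(specs)
    occ = state_occupation(clones, None, TWO_STATE, horizon=10)
    kmf = KaplanMeierFitter().fit([fe for fe, _, _ in specs],
                                  [1 if es else 0 for _, es, _ in specs])
    for t in range(0, 11):
        km = float(kmf.survival_function_at_times(t).iloc[0])
        assert occ.loc[t, DEATH] == pytest.approx(1.0 - km, abs=1e-12)


def test_competing_risks_equal_classical_cifs():
    specs = [(1, DEATH, np.nan), (2, HOME, np.nan), (3, 0, np.nan), (4, DEATH, np.nan),
             (5, HOME, np.nan), (6, HOME, np.nan), (8, 0, np.nan), (9, DEATH, np.nan),
             (9, HOME, np.nan), (10, 0, np.nan)]
    clones = make_clones(specs)
    occ = state_occupation(clones, None, COMPETING, horizon=10)
    # classical CIF: sum over event days of S(u-) * d_k(u) / n(u)
    times = np.array([fe for fe, _, _ in specs], dtype=float)
    states = np.array([es for _, es, _ in specs])
    surv = 1.0
    cif = {DEATH: np.zeros(11), HOME: np.zeros(11)}
    for u in sorted(np.unique(times[states > 0])):
        n_at_risk = float((times >= u).sum())
        d_total = float(((times == u) & (states > 0)).sum())
        for k in (DEATH, HOME):
            d_k = float(((times == u) & (states == k)).sum())
            cif[k][int(u):] += surv * d_k / n_at_risk
        surv *= 1.0 - d_total / n_at_risk
    for k in (DEATH, HOME):
        for t in range(11):
            assert occ.loc[t, k] == pytest.approx(cif[k][t], abs=1e-12)
    # all occupation rows sum to one
    assert np.allclose(occ.sum(axis=1).to_numpy(), 1.0, atol=1e-12)


def test_competing_risks_match_lifelines_aalen_johansen():
    from lifelines import AalenJohansenFitter

    # untied event times so lifelines applies no jitter
    specs = [(1, DEATH, np.nan), (2, HOME, np.nan), (3, 0, np.nan), (4, DEATH, np.nan),
             (6, HOME, np.nan), (8, 0, np.nan), (9, DEATH, np.nan), (10, 0, np.nan)]
    clones = make_clones(specs)
    occ = state_occupation(clones, None, COMPETING, horizon=10)
    durations = [fe for fe, _, _ in specs]
    events = [es for _, es, _ in specs]
    for k in (DEATH, HOME):
        ajf = AalenJohansenFitter(calculate_variance=False)
        ajf.fit(durations, events, event_of_interest=k)
        cd = ajf.cumulative_density_
        for t in (1, 4, 7, 10):
            expected = float(cd[cd.index <= t].iloc[-1, 0]) if (cd.index <= t).any() else 0.0
            assert occ.loc[t, k] == pytest.approx(expected, abs=1e-12)


def direct_product_integral(clones, weight_pivot, horizon=45):
    """Independent weighted Aalen-Johansen from first principles: explicit
    per-clone risk sets and transitions per day, never via build_long_format."""
    states = (WARD, ICU, DEATH, HOME, HCF)
    pos = {s: i for i, s in enumerate(states)}
    P = np.eye(5)
    series = [P.copy()]
    for t in range(1, horizon + 1):
        dN = np.zeros((5, 5))
        Y = np.zeros(5)
        for _, row in clones.iterrows():
            if t > row["followup_end"]:
                continue
            w = weight_pivot[(row["patient_id"], row["arm"])][t - 1]
            icu = row["icu_day"]
            from_state = WARD if (np.isnan(icu) or t <= icu) else ICU
            Y[pos[from_state]] += w
            if not np.isnan(icu) and icu == t:
                dN[pos[WARD], pos[ICU]] += w
            if row["end_reason"] == "event" and row["event_day"] == t:
                dN[pos[from_state], pos[int(row["event_state"])]] += w
        dA = np.zeros((5, 5))
        for l in range(5):
            if Y[l] > 0:
                dA[l] = dN[l] / Y[l]
        np.fill_diagonal(dA, 0.0)
        np.fill_diagonal(dA, 1.0 - dA.sum(axis=1))
        P = P @ dA
        series.append(P.copy())
    return series


def test_hand_fixture_matches_direct_product_integral(hand_clones):
    wm = CensoringWeightModel().fit(hand_clones)
    table = wm.transform(hand_clones)
    pivot = {
        key: dict(zip(grp["day"], grp["weight"]))
        for key, grp in table.groupby(["patient_id", "arm"])
    }
    for arm in ("treated", "control"):
        sub = hand_clones.loc[hand_clones["arm"] == arm]
        occ = state_occupation(sub, table.loc[table["arm"] == arm])
        direct = direct_product_integral(sub, pivot)
        for t in (1, 5, 10, 25, 45):
            np.testing.assert_allclose(
                occ.loc[t].to_numpy(), direct[t][0], atol=1e-12
            )
    # and the unit-weight run reduces exactly to weight_table=None
    sub = hand_clones.loc[hand_clones["arm"] == "control"]
    unit = table.loc[table["arm"] == "control"].copy()
    unit["weight"] = 1.0
    pd.testing.assert_frame_equal(
        state_occupation(sub, unit), state_occupation(sub, None)
    )


def test_aalen_johansen_identity_at_s_and_absorbing_rows():
    clones = make_clones([(2, DEATH, np.nan), (4, HOME, 1.0), (6, 0, np.nan)])
    long = build_long_format(clones, None)
    cumhaz = weighted_nelson_aalen(long)
    series = aalen_johansen(cumhaz, s=0, horizon=10)
    np.testing.assert_array_equal(series.matrix(0), np.eye(5))
    for t in (3, 10):
        P = series.matrix(t)
        for absorbing in (DEATH, HOME, HCF):
            i = series.states.index(absorbing)
            expected = np.zeros(5)
            expected[i] = 1.0
            np.testing.assert_allclose(P[i], expected, atol=1e-15)


def test_aalen_johansen_excess_increment_raises():
    table = pd.DataFrame(
        {
            "from_state": [WARD, WARD],
            "to_state": [DEATH, HOME],
            "day": [2, 2],
            "increment": [0.7, 0.7],
            "cumulative": [0.7, 0.7],
        }
    )
    cumhaz = CumulativeHazardSet(TransitionStructure(), table)
    with pytest.raises(EstimationError, match="day 2"):
        aalen_johansen(cumhaz, s=0, horizon=5)


def test_zero_at_risk_weight_raises():
    clones = make_clones([(2, DEATH, np.nan)])
    table = pd.DataFrame(
        {
            "patient_id": [1, 1, 1],
            "arm": ["treated"] * 3,
            "day": [0, 1, 2],
            "weight": [1.0, 0.0, 0.0],
        }
    )
    long = build_long_format(clones, table)
    with pytest.raises(EstimationError):
        weighted_nelson_aalen(long)


def test_estimator_class_exposes_fitted_attributes():
    clones = make_clones([(2, DEATH, np.nan), (5, HOME, np.nan), (7, 0, np.nan)])
    long = build_long_format(clones, None)
    est = WeightedAalenJohansen(horizon=10).fit(long)
    assert est.occupation_.shape == (11, 5)
    np.testing.assert_array_equal(est.transition_matrix(0), np.eye(5))
    assert est.cumhaz_.cumulative(WARD, DEATH, 10) > 0


@st.composite
def random_clone_table(draw):
    n = draw(st.integers(min_value=1, max_value=8))
    specs = []
    weights = {}
    for i in range(n):
        fe = draw(st.integers(min_value=1, max_value=8))
        kind = draw(st.sampled_from(["event", "admin", "artificial"]))
        icu = np.nan
        if fe >= 2 and draw(st.booleans()):
            icu = float(draw(st.integers(min_value=1, max_value=fe - 1)))
        if kind == "event":
            es = draw(st.sampled_from([DEATH, HOME, HCF]))
        else:
            es = 0
        specs.append((fe, es, icu))
        weights[i + 1] = [
            draw(st.floats(min_value=0.25, max_value=4.0, allow_nan=False))
            for _ in range(fe + 1)
        ]
    clones = make_clones(specs)
    rows = []
    for pid, ws in weights.items():
        for day, w in enumerate(ws):
            rows.append({"patient_id": pid, "arm": "treated", "day": day, "weight": w})
    return clones, pd.DataFrame(rows)


@settings(max_examples=60, deadline=None)
@given(random_clone_table())
def test_row_stochasticity_property(data):
    clones, weight_table = data
    long = build_long_format(clones, weight_table, horizon=10)
    cumhaz = weighted_nelson_aalen(long)
    for s in (0, 2):
        series = aalen_johansen(cumhaz, s=s, horizon=10)
        for t in range(s, 11):
            P = series.matrix(t)
            np.testing.assert_allclose(P.sum(axis=1), np.ones(5), atol=1e-10)
            assert (P >= -1e-15).all()
        occ = series.occupation(WARD).to_numpy()
        for j, state in enumerate(series.states):
            if state in (DEATH, HOME, HCF):
                assert (np.diff(occ[:, j]) >= -1e-12).all()
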