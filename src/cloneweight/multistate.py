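"""Weighted multi-state estimation on a discrete day grid.

Builds the long-format counting-process table (one block of rows per
clone-day at risk, one row per allowed destination) and computes

* weighted Nelson-Aalen cumulative transition hazards
      A_lm(t) = sum_{u <= t} dN_lm(u) / Y_l(u)
  with dN and Y aggregating clone weights, and
* weighted Aalen-Johansen transition probabilities as the matrix
  product-integral  P(s, t) = prod_{u in (s, t]} (I + dA(u)).

Event times are integer days; simultaneous transitions across clones on the
same day are aggregated into one product factor.  With all weights equal to
1 both estimators reduce exactly to their classical unweighted forms.  The
state-occupation vector is the initial-state row of P(0, t); under the
weighted design it estimates per-protocol occupation probabilities per arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import EstimationError, SchemaError
from .states import WARD, TransitionStructure, default_structure

LONG_COLUMNS = ("clone_id", "patient_id", "arm", "day", "from_state", "to_state", "status", "weight")


def build_long_format(
    clones: pd.DataFrame,
    weight_table: pd.DataFrame | None,
    structure: TransitionStructure | None = None,
    horizon: int = 45,
) -> pd.DataFrame:
    """Long-format counting-process table.

    For each clone and each day t in (0, followup_end], one row per allowed
    destination from the clone's current (start-of-day) state; ``status`` is
    1 exactly on the observed transition's (day, destination).  Artificial
    and administrative censoring produce no status-1 row.  The weight applied
    to day t is the clone's weight at t - 1 (left-continuous carry-forward);
    ``weight_table`` must cover every clone-day at risk, or be None for unit
    weights.
    """
    structure = structure or default_structure()
    fe = np.minimum(clones["followup_end"].to_numpy(dtype=int), horizon)
    icu_day = clones["icu_day"].to_numpy(dtype=float)
    event_day = clones["event_day"].to_numpy(dtype=float)
    event_state = clones["event_state"].to_numpy(dtype=int)
    ends_event = (clones["end_reason"].to_numpy() == "event") & (event_day <= horizon)

    # validate observed transitions against the allowed set
    allowed = set(structure.allowed)
    has_icu = ~np.isnan(icu_day) & (icu_day <= fe)
    if has_icu.any() and (WARD, 2) not in allowed:
        raise SchemaError("observed transition (1, 2) is not in the allowed set")
    for es in np.unique(event_state[ends_event]):
        from_states = np.where(has_icu[ends_event & (event_state == es)], 2, WARD)
        for l in np.unique(from_states):
            if (int(l), int(es)) not in allowed:
                raise SchemaError(
                    f"observed transition ({int(l)}, {int(es)}) is not in the allowed set"
                )

    n = len(clones)
    clone_idx = np.repeat(np.arange(n), fe)
    day = np.concatenate([np.arange(1, k + 1) for k in fe]) if n else np.zeros(0, int)
    icu_rep = icu_day[clone_idx]
    from_state = np.where(np.isnan(icu_rep) | (day <= icu_rep), WARD, 2).astype(int)

    # expand clone-days by destination, one group of rows per transient state
    parts = []
    for l in structure.transient:
        dests = structure.destinations(l)
        mask = from_state == l
        if not mask.any() or not dests:
            continue
        k = len(dests)
        rows = {
            "clone_id": np.repeat(clone_idx[mask], k),
            "day": np.repeat(day[mask], k),
            "from_state": np.full(int(mask.sum()) * k, l, dtype=int),
            "to_state": np.tile(np.array(dests, dtype=int), int(mask.sum())),
        }
        parts.append(pd.DataFrame(rows))
    if parts:
        long = pd.concat(parts, ignore_index=True)
    else:
        long = pd.DataFrame(
            {c: np.zeros(0, dtype=int) for c in ("clone_id", "day", "from_state", "to_state")}
        )

    ci = long["clone_id"].to_numpy()
    dd = long["day"].to_numpy()
    tt = long["to_state"].to_numpy()
    status = np.zeros(len(long), dtype=np.int8)
    icu_l = icu_day[ci]
    status |= ((~np.isnan(icu_l)) & (dd == icu_l) & (tt == 2)).astype(np.int8)
    ev_l = np.where(ends_event[ci], event_day[ci], np.nan)
    status |= ((~np.isnan(ev_l)) & (dd == ev_l) & (tt == event_state[ci])).astype(np.int8)
    long["status"] = status
    long["patient_id"] = clones["patient_id"].to_numpy()[ci]
    long["arm"] = clones["arm"].to_numpy()[ci]

    if weight_table is None:
        long["weight"] = 1.0
    else:
        wt = weight_table[["patient_id", "arm", "day", "weight"]].copy()
        wt = wt.rename(columns={"day": "weight_day"})
        long["weight_day"] = long["day"] - 1
        merged = long.merge(wt, on=["patient_id", "arm", "weight_day"], how="left")
        if merged["weight"].isna().any():
            missing = merged.loc[merged["weight"].isna(), ["patient_id", "arm", "day"]]
            raise SchemaError(
                "missing weight for clone-days at risk, e.g. "
                f"{missing.head(3).to_dict('records')}"
            )
        long = merged.drop(columns=["weight_day"])
    return long[list(LONG_COLUMNS)].sort_values(
        ["clone_id", "day", "from_state", "to_state"], kind="stable", ignore_index=True
    )


@dataclass
class CumulativeHazardSet:
    """Weighted Nelson-Aalen step functions for every allowed transition."""

    structure: TransitionStructure
    table: pd.DataFrame  # columns: from_state, to_state, day, increment, cumulative

    def increments(self, l: int, m: int) -> pd.DataFrame:
        sel = (self.table["from_state"] == l) & (self.table["to_state"] == m)
        return self.table.loc[sel].reset_index(drop=True)

    def cumulative(self, l: int, m: int, t: float) -> float:
        inc = self.increments(l, m)
        sel = inc["day"] <= t
        return float(inc.loc[sel, "increment"].sum())

    @property
    def event_days(self) -> np.ndarray:
        return np.unique(self.table["day"].to_numpy())


def weighted_nelson_aalen(
    long_table: pd.DataFrame, structure: TransitionStructure | None = None
) -> CumulativeHazardSet:
    """Weighted Nelson-Aalen cumulative hazards from a long-format table.

    For each transition l -> m and each day u with observed transitions, the
    increment is (sum of weights of transitioning clones) / (sum of weights
    of clones at risk in l at u).  With unit weights this is the standard
    Nelson-Aalen estimator.
    """
    structure = structure or default_structure()
    if len(long_table) == 0:
        table = pd.DataFrame(
            columns=["from_state", "to_state", "day", "increment", "cumulative"]
        )
        return CumulativeHazardSet(structure, table)
    # one row per clone-day (weights are repeated across destinations)
    per_clone_day = long_table.drop_duplicates(subset=["clone_id", "day"])
    risk = (
        per_clone_day.groupby(["from_state", "day"], sort=True)["weight"].sum().rename("at_risk")
    )
    events = long_table.loc[long_table["status"] == 1]
    if len(events) == 0:
        table = pd.DataFrame(
            columns=["from_state", "to_state", "day", "increment", "cumulative"]
        )
        return CumulativeHazardSet(structure, table)
    dn = (
        events.groupby(["from_state", "to_state", "day"], sort=True)["weight"]
        .sum()
        .rename("dn")
        .reset_index()
    )
    dn = dn.join(risk, on=["from_state", "day"])
    if (dn["at_risk"] <= 0).any() or dn["at_risk"].isna().any():
        bad = dn.loc[(dn["at_risk"].isna()) | (dn["at_risk"] <= 0)].head(3)
        raise EstimationError(
            f"event day with zero at-risk weight: {bad.to_dict('records')}"
        )
    dn["increment"] = dn["dn"] / dn["at_risk"]
    dn = dn.sort_values(["from_state", "to_state", "day"], ignore_index=True)
    dn["cumulative"] = dn.groupby(["from_state", "to_state"])["increment"].cumsum()
    table = dn[["from_state", "to_state", "day", "increment", "cumulative"]]
    return CumulativeHazardSet(structure, table)


@dataclass
class ProbabilityMatrixSeries:
    """Aalen-Johansen transition-probability matrices P(s, t) on a day grid."""

    s: int
    days: np.ndarray  # integer days s..horizon
    states: tuple[int, ...]
    matrices: np.ndarray  # (len(days), n_states, n_states)

    def matrix(self, t: int) -> np.ndarray:
        idx = int(t) - self.s
        if idx < 0 or idx >= len(self.days):
            raise ValueError(f"t={t} outside the computed grid [{self.s}, {self.days[-1]}]")
        return self.matrices[idx]

    def occupation(self, from_state: int = WARD) -> pd.DataFrame:
        """State-occupation probabilities by day, starting from ``from_state``."""
        row = self.states.index(from_state)
        data = self.matrices[:, row, :]
        return pd.DataFrame(data, index=pd.Index(self.days, name="day"), columns=list(self.states))


def aalen_johansen(
    cumhaz: CumulativeHazardSet,
    structure: TransitionStructure | None = None,
    s: int = 0,
    horizon: int = 45,
) -> ProbabilityMatrixSeries:
    """Weighted Aalen-Johansen estimator: ordered matrix product of
    (I + dA(u)) over event days u in (s, horizon].

    Off-diagonal entries of each increment matrix are the Nelson-Aalen
    increments for the allowed transitions; diagonals are one minus the row
    sums, which must stay nonnegative (a negative diagonal signals a
    pathological weight configuration and raises EstimationError naming the
    day).  Matrices are reported for every integer day; P(s, s) is the
    identity and absorbing-state rows stay unit vectors.
    """
    structure = structure or cumhaz.structure or default_structure()
    states = tuple(structure.states)
    k = len(states)
    pos = {st: i for i, st in enumerate(states)}
    tab = cumhaz.table
    days = np.arange(s, horizon + 1)
    matrices = np.zeros((len(days), k, k))
    P = np.eye(k)
    matrices[0] = P
    if len(tab):
        event_days = np.unique(tab["day"].to_numpy())
        event_days = event_days[(event_days > s) & (event_days <= horizon)]
    else:
        event_days = np.zeros(0)
    by_day = {d: g for d, g in tab.groupby("day")} if len(tab) else {}
    for i, t in enumerate(days[1:], start=1):
        if t in by_day:
            g = by_day[t]
            dA = np.zeros((k, k))
            for l, m, inc in zip(g["from_state"], g["to_state"], g["increment"]):
                dA[pos[int(l)], pos[int(m)]] = float(inc)
            rowsum = dA.sum(axis=1)
            if np.any(rowsum > 1.0 + 1e-12):
                worst = states[int(np.argmax(rowsum))]
                raise EstimationError(
                    f"negative Aalen-Johansen diagonal at day {int(t)} for state "
                    f"{worst}: total increment {float(rowsum.max()):.6f} > 1 "
                    "(too-coarse grid or pathological weights)"
                )
            np.fill_diagonal(dA, np.maximum(1.0 - rowsum, 0.0))
            P = P @ dA
        matrices[i] = P
    return ProbabilityMatrixSeries(s=s, days=days, states=states, matrices=matrices)


def state_occupation(
    clones: pd.DataFrame,
    weight_table: pd.DataFrame | None,
    structure: TransitionStructure | None = None,
    horizon: int = 45,
) -> pd.DataFrame:
    """Convenience pipeline: long table -> weighted Nelson-Aalen -> weighted
    Aalen-Johansen -> occupation probabilities from the ward at day 0."""
    structure = structure or default_structure()
    long = build_long_format(clones, weight_table, structure, horizon)
    cumhaz = weighted_nelson_aalen(long, structure)
    series = aalen_johansen(cumhaz, structure, s=0, horizon=horizon)
    return series.occupation(WARD)


class WeightedAalenJohansen(BaseEstimator):
    """Weighted Nelson-Aalen / Aalen-Johansen estimator over a long-format
    counting-process table (scikit-learn style).

    ``fit`` consumes the table from :func:`build_long_format` and exposes
    ``cumhaz_`` (the weighted Nelson-Aalen set), ``series_`` (the
    probability-matrix series) and ``occupation_`` (state-occupation
    probabilities from the initial state).
    """

    def __init__(
        self,
        structure: TransitionStructure | None = None,
        s: int = 0,
        horizon: int = 45,
        initial_state: int = WARD,
    ):
        self.structure = structure
        self.s = s
        self.horizon = horizon
        self.initial_state = initial_state

    def fit(self, long_table: pd.DataFrame, y=None) -> "WeightedAalenJohansen":
        structure = self.structure or default_structure()
        self.cumhaz_ = weighted_nelson_aalen(long_table, structure)
        self.series_ = aalen_johansen(self.cumhaz_, structure, s=self.s, horizon=self.horizon)
        self.occupation_ = self.series_.occupation(self.initial_state)
        return self

    def transition_matrix(self, t: int) -> np.ndarray:
        return self.series_.matrix(t)
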