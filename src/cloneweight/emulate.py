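"""Trial emulation: eligibility screening, cloning, and artificial censoring.

Every eligible patient is duplicated into both protocol arms at admission
(day 0).  Clones are artificially censored when the patient's observed
treatment history deviates from their arm's protocol within the grace
period:

* control clone -- censored on the day treatment is initiated, if that
  happens within the grace period;
* treated clone -- censored at the end of the grace period if treatment was
  never initiated within it (including patients first treated afterwards,
  who count as controls).

Clones reaching an absorbing state within the grace period before treatment
are never artificially censored in either arm: their protocol adherence is
vacuously complete.  When treatment and the outcome fall on the same day,
treatment is taken to precede the outcome (a dose recorded on the event day
was administered in hospital), so the control clone is censored and the
treated clone keeps the event.  A day-0 initiator's control clone is censored
at day 1, the first day of the discrete risk grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError
from .simulate import COVARIATE_COLUMNS, FLAG_COLUMNS
from .states import ICU, WARD

#: exclusion rules in protocol order; each excluded patient is logged once
#: under the first rule it violates
EXCLUSION_RULES = (
    "hospital_acquired",
    "readmission",
    "pre_treatment",
    "outcome_on_admission",
)

CLONE_COLUMNS = (
    "patient_id",
    "arm",
    "censor_day",
    "censor_indicator",
    "followup_end",
    "end_reason",
    "terminal_state",
)


@dataclass(frozen=True)
class EmulationConfig:
    grace_days: int = 5
    admin_censor_day: int = 45

    def __post_init__(self) -> None:
        if self.grace_days < 1:
            raise ConfigurationError("grace_days must be a positive integer")
        if not self.grace_days < self.admin_censor_day:
            raise ConfigurationError("grace_days must be smaller than admin_censor_day")


def apply_eligibility(
    patients: pd.DataFrame, rules: tuple[str, ...] = EXCLUSION_RULES
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter a cohort by the exclusion rules, in order.

    A patient is excluded if flagged for hospital-acquired infection,
    readmission, or pre-admission treatment, or if an absorbing event occurred
    on the admission day (day 0).  Returns the eligible cohort and a log
    counting removals per rule; patients violating several rules are counted
    once, under the first rule in ``rules``.
    """
    for col in FLAG_COLUMNS + ("event_day",):
        if col not in patients.columns:
            raise SchemaError(f"cohort table is missing required column {col!r}")
    violations = {
        "hospital_acquired": patients["hospital_acquired"].astype(bool).to_numpy(),
        "readmission": patients["readmission"].astype(bool).to_numpy(),
        "pre_treatment": patients["pre_treatment"].astype(bool).to_numpy(),
        "outcome_on_admission": (patients["event_day"].to_numpy(dtype=float) == 0.0),
    }
    excluded = np.zeros(len(patients), dtype=bool)
    log: dict[str, int] = {}
    for rule in rules:
        if rule not in violations:
            raise ConfigurationError(f"unknown exclusion rule {rule!r}")
        hit = violations[rule] & ~excluded
        log[rule] = int(hit.sum())
        excluded |= hit
    return patients.loc[~excluded].reset_index(drop=True), log


def _clone_arrays(
    tau: np.ndarray,
    event_day: np.ndarray,
    event_state: np.ndarray,
    icu_day: np.ndarray,
    config: EmulationConfig,
) -> dict[str, np.ndarray]:
    """Vectorized clone construction; one treated and one control clone per
    patient, concatenated treated-first.  All day arrays are floats with NaN
    for 'absent'."""
    g = float(config.grace_days)
    admin = float(config.admin_censor_day)
    has_event = event_state > 0
    e = np.where(has_event, event_day, np.inf)

    if np.any(tau < 0) or np.any(e < 0):
        raise SchemaError("negative treatment or event days are not allowed")

    tau_f = np.where(np.isnan(tau), np.inf, tau)
    # treated within grace (same-day tie: treatment precedes the outcome)
    treated_within = (tau_f <= g) & (tau_f <= e)
    # absorbing event within the grace period before any treatment
    event_first = (e <= g) & ~treated_within

    followup_natural = np.minimum(e, admin)
    natural_event = e <= admin

    def natural(arrs: dict[str, np.ndarray], mask: np.ndarray) -> None:
        arrs["followup_end"][mask] = followup_natural[mask]
        arrs["end_reason"][mask] = np.where(natural_event[mask], "event", "administrative")

    def empty(n: int) -> dict[str, np.ndarray]:
        return {
            "censor_day": np.full(n, np.nan),
            "censor_indicator": np.zeros(n, dtype=int),
            "followup_end": np.zeros(n),
            "end_reason": np.full(n, "", dtype=object),
        }

    n = len(tau)
    treated = empty(n)
    control = empty(n)

    # control arm: censored at the treatment day when initiation falls in the
    # grace period, otherwise follows the full observed history (treatment
    # after the grace period classifies the patient as a control, with no
    # later artificial censoring)
    control["censor_day"][treated_within] = np.maximum(tau_f[treated_within], 1.0)
    control["censor_indicator"][treated_within] = 1
    control["followup_end"][treated_within] = control["censor_day"][treated_within]
    control["end_reason"][treated_within] = "artificial_censor"
    natural(control, ~treated_within)

    # treated arm: uncensored if treated within grace; ends at the event if it
    # precedes treatment within grace; otherwise censored at grace end
    natural(treated, treated_within)
    treated["followup_end"][event_first] = e[event_first]
    treated["end_reason"][event_first] = "event"
    rest = ~treated_within & ~event_first
    treated["censor_day"][rest] = g
    treated["censor_indicator"][rest] = 1
    treated["followup_end"][rest] = g
    treated["end_reason"][rest] = "artificial_censor"

    out: dict[str, np.ndarray] = {}
    for key in ("censor_day", "censor_indicator", "followup_end", "end_reason"):
        out[key] = np.concatenate([treated[key], control[key]])
    out["arm"] = np.concatenate([np.full(n, "treated", object), np.full(n, "control", object)])
    out["patient_index"] = np.concatenate([np.arange(n), np.arange(n)])

    fe = out["followup_end"]
    ev = np.concatenate([event_state, event_state])
    icu2 = np.concatenate([icu_day, icu_day])
    is_event_end = out["end_reason"] == "event"
    transient = np.where(~np.isnan(icu2) & (icu2 <= fe), ICU, WARD)
    out["terminal_state"] = np.where(is_event_end, ev, transient).astype(int)
    out["followup_end"] = fe.astype(int)
    return out


def clone_and_censor(
    patients: pd.DataFrame, config: EmulationConfig | None = None
) -> pd.DataFrame:
    """Clone each (eligible) patient into both arms and impose artificial
    censoring over the grace period.

    Returns one row per clone: ``patient_id, arm, censor_day,
    censor_indicator, followup_end, end_reason, terminal_state`` followed by
    the baseline covariates, and the event-history columns (``icu_day``,
    ``event_day``, ``event_state``) needed downstream.
    """
    config = config or EmulationConfig()
    for col in ("patient_id", "treatment_day", "event_day", "event_state", "icu_day"):
        if col not in patients.columns:
            raise SchemaError(f"cohort table is missing required column {col!r}")
    tau = patients["treatment_day"].to_numpy(dtype=float)
    event_day = patients["event_day"].to_numpy(dtype=float)
    event_state = patients["event_state"].to_numpy()
    event_state = np.where(pd.isna(event_state), 0, event_state).astype(int)
    icu_day = patients["icu_day"].to_numpy(dtype=float)

    arrs = _clone_arrays(tau, event_day, event_state, icu_day, config)
    idx = arrs.pop("patient_index")
    base = patients.iloc[idx].reset_index(drop=True)
    clones = pd.DataFrame(
        {
            "patient_id": base["patient_id"].to_numpy(),
            "arm": arrs["arm"],
            "censor_day": arrs["censor_day"],
            "censor_indicator": arrs["censor_indicator"],
            "followup_end": arrs["followup_end"],
            "end_reason": arrs["end_reason"],
            "terminal_state": arrs["terminal_state"],
        }
    )
    for col in COVARIATE_COLUMNS:
        if col in base.columns:
            clones[col] = base[col].to_numpy()
    for col in ("icu_day", "event_day", "event_state"):
        clones[col] = base[col].to_numpy()
    # clones whose follow-up ends before the event never observe it
    ends_event = clones["end_reason"].to_numpy() == "event"
    ev_day = clones["event_day"].to_numpy(dtype=float)
    hide = ~ends_event & ~np.isnan(ev_day)
    clones.loc[hide, "event_day"] = np.nan
    clones.loc[hide, "event_state"] = 0
    fe = clones["followup_end"].to_numpy(dtype=float)
    icu2 = clones["icu_day"].to_numpy(dtype=float)
    clones.loc[~np.isnan(icu2) & (icu2 > fe), "icu_day"] = np.nan
    clones["event_state"] = clones["event_state"].astype(int)
    return clones
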