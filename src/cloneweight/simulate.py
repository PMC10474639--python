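"""Synthetic hospitalized-cohort simulator.

Generates patient records with the covariate structure a clone-censor-weight
analysis of an in-hospital treatment assumes: baseline covariates (age, sex,
dichotomized comorbidity index, inflammation markers, pandemic wave),
covariate-dependent (confounded) daily treatment initiation, and forward-only
Markov trajectories over the 5-state structure of :mod:`cloneweight.states`
on a discrete integer-day grid with administrative censoring at day 45.

Time is discrete: all hazards are daily transition probabilities, and
competing destinations within a day are drawn from a single categorical
distribution (probabilities = cause-specific daily probabilities, remainder =
stay), so destinations are mutually exclusive by construction.  Covariates and
current treatment status act multiplicatively on the daily probabilities
(discrete-hazard scale); the treatment effect applies from the initiation day
onward, inclusive.

A Monte-Carlo ``occupation_oracle`` provides ground-truth state-occupation
probabilities under a fixed treatment policy, used to validate the weighted
Aalen-Johansen pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SimulationError
from .states import (
    DEATH,
    HCF,
    HOME,
    ICU,
    WARD,
    TransitionStructure,
    default_structure,
)

#: columns of the analysis design matrix, in order (wave enters as dummies)
DESIGN_COLUMNS = (
    "age",
    "sex",
    "charlson_ge2",
    "crp",
    "ldh",
    "log_ddimer",
    "lymphocytes",
    "wave_2",
    "wave_3",
)

#: raw covariate columns stored in a cohort table
COVARIATE_COLUMNS = (
    "age",
    "sex",
    "charlson_ge2",
    "crp",
    "ldh",
    "log_ddimer",
    "lymphocytes",
    "wave",
)

FLAG_COLUMNS = ("hospital_acquired", "readmission", "pre_treatment")

COHORT_COLUMNS = (
    ("patient_id",)
    + COVARIATE_COLUMNS
    + ("treatment_day", "icu_day", "event_day", "event_state")
    + FLAG_COLUMNS
)


def _check_prob(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name} must be a probability in [0, 1], got {value!r}")


@dataclass
class CovariateParams:
    """Distribution parameters for the baseline covariates.

    Continuous biomarkers are log-normal: CRP (mg/L), LDH (U/L), D-dimer
    (ng/mL; stored log-transformed as ``log_ddimer``) and lymphocytes
    (x10^6/L).  Age is normal (years); sex, comorbidity (Charlson index
    dichotomized at 2) and pandemic wave are categorical.
    """

    age_mean: float = 62.0
    age_sd: float = 14.0
    male_p: float = 0.60
    charlson_ge2_p: float = 0.35
    crp_log_mean: float = 4.3
    crp_log_sd: float = 0.8
    ldh_log_mean: float = 5.7
    ldh_log_sd: float = 0.35
    ddimer_log_mean: float = 6.6
    ddimer_log_sd: float = 0.9
    lymph_log_mean: float = 6.9
    lymph_log_sd: float = 0.5
    wave_probs: tuple[float, float, float] = (0.45, 0.35, 0.20)

    def validate(self) -> None:
        _check_prob(self.male_p, "covariate_params.male_p")
        _check_prob(self.charlson_ge2_p, "covariate_params.charlson_ge2_p")
        if len(self.wave_probs) != 3:
            raise ConfigurationError("covariate_params.wave_probs must have 3 entries")
        for p in self.wave_probs:
            _check_prob(p, "covariate_params.wave_probs")
        if abs(sum(self.wave_probs) - 1.0) > 1e-9:
            raise ConfigurationError("covariate_params.wave_probs must sum to 1")
        for name in ("age_sd", "crp_log_sd", "ldh_log_sd", "ddimer_log_sd", "lymph_log_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"covariate_params.{name} must be positive")

    def design_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Theoretical (mean, sd) of each design-matrix column.

        The simulator's structural models are linear in *standardized*
        design columns, so the analysis models (linear in the raw columns)
        remain correctly specified.
        """

        def lognorm_moments(mu: float, sigma: float) -> tuple[float, float]:
            m = math.exp(mu + sigma**2 / 2.0)
            s = m * math.sqrt(math.exp(sigma**2) - 1.0)
            return m, s

        def bern_moments(p: float) -> tuple[float, float]:
            return p, math.sqrt(max(p * (1.0 - p), 1e-12))

        moments = [
            (self.age_mean, self.age_sd),
            bern_moments(self.male_p),
            bern_moments(self.charlson_ge2_p),
            lognorm_moments(self.crp_log_mean, self.crp_log_sd),
            lognorm_moments(self.ldh_log_mean, self.ldh_log_sd),
            (self.ddimer_log_mean, self.ddimer_log_sd),
            lognorm_moments(self.lymph_log_mean, self.lymph_log_sd),
            bern_moments(self.wave_probs[1]),
            bern_moments(self.wave_probs[2]),
        ]
        mu = np.array([m for m, _ in moments])
        sd = np.array([s for _, s in moments])
        return mu, sd

    def hazard_design_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """(mean, sd) for the hazard design, where the log-normal biomarkers
        enter on the log scale (their natural, light-tailed scale)."""

        def bern_moments(p: float) -> tuple[float, float]:
            return p, math.sqrt(max(p * (1.0 - p), 1e-12))

        moments = [
            (self.age_mean, self.age_sd),
            bern_moments(self.male_p),
            bern_moments(self.charlson_ge2_p),
            (self.crp_log_mean, self.crp_log_sd),
            (self.ldh_log_mean, self.ldh_log_sd),
            (self.ddimer_log_mean, self.ddimer_log_sd),
            (self.lymph_log_mean, self.lymph_log_sd),
            bern_moments(self.wave_probs[1]),
            bern_moments(self.wave_probs[2]),
        ]
        mu = np.array([m for m, _ in moments])
        sd = np.array([s for _, s in moments])
        return mu, sd


def _coef_vector(coefs: Mapping[str, float], field_name: str) -> np.ndarray:
    vec = np.zeros(len(DESIGN_COLUMNS))
    for key, value in coefs.items():
        if key not in DESIGN_COLUMNS:
            raise ConfigurationError(
                f"{field_name}: unknown covariate {key!r}; valid names: {DESIGN_COLUMNS}"
            )
        vec[DESIGN_COLUMNS.index(key)] = float(value)
    return vec


@dataclass
class InitiationModel:
    """Confounded daily treatment-initiation model.

    The probability of initiating treatment within the grace period given
    the standardized design vector z is

        U(z) = P(tau <= grace | z) = exp(-exp(-(intercept + coefs . z)))

    a complementary log-log law: the *treated-arm* proportional-hazards
    censoring model, whose only censoring time is the grace end and whose
    survival function therefore has exactly this form, is correctly
    specified by construction.  (With covariate-dependent initiation the
    censoring models of both arms can never be exact simultaneously; the
    treated arm carries the large weights, so it gets the exact form.)

    The initiation day spreads U(z) over the grid with day weights
    ``w_d proportional to exp(day_coef * d)`` normalized to sum to one over
    days 0..grace: while untreated and in a transient state, the day-d
    initiation probability is ``h_d(z) = 1 - (1 - U(z))**w_d``.  Days after
    the grace period continue the same declining ``w_d`` sequence (late
    initiators count as protocol controls).

    ``law="daily_cloglog"`` instead makes the *daily* initiation hazard
    proportional-hazards in z, ``h_d(z) = 1 - exp(-exp(intercept +
    day_coef * d + coefs . z))``, the form under which the *control-arm*
    censoring model (censoring at the initiation day) is exactly specified;
    ``intercept`` is then a daily log-hazard, not a grace-period log-log
    probability."""

    intercept: float = 0.15
    day_coef: float = -0.15
    grace_days: int = 5
    law: str = "grace_cloglog"
    coefs: dict[str, float] = field(
        default_factory=lambda: {
            "age": 0.21,
            "sex": 0.06,
            "charlson_ge2": 0.24,
            "crp": 0.09,
            "ldh": 0.06,
            "log_ddimer": 0.17,
            "lymphocytes": -0.06,
            "wave_2": 0.09,
            "wave_3": 0.15,
        }
    )

    def coef_vector(self) -> np.ndarray:
        return _coef_vector(self.coefs, "initiation_coefs")

    def within_grace_probability(self, lp: np.ndarray | float) -> np.ndarray | float:
        """U(z) = P(initiation within the grace period | z), lp = coefs . z."""
        return np.exp(-np.exp(-(self.intercept + np.asarray(lp, dtype=float))))

    def day_weight(self, day: int) -> float:
        """w_d: share of the within-grace log-survival assigned to day d."""
        if self.grace_days < 1:
            raise ConfigurationError("initiation.grace_days must be >= 1")
        norm = sum(math.exp(self.day_coef * k) for k in range(self.grace_days + 1))
        return math.exp(self.day_coef * day) / norm

    def daily_probability(self, lp: np.ndarray | float, day: int) -> np.ndarray:
        """P(initiate on day d | untreated, transient, z)."""
        if self.law == "daily_cloglog":
            return -np.expm1(-np.exp(self.intercept + self.day_coef * day + np.asarray(lp, float)))
        if self.law != "grace_cloglog":
            raise ConfigurationError(f"unknown initiation law {self.law!r}")
        U = self.within_grace_probability(lp)
        return -np.expm1(self.day_weight(day) * np.log1p(-U))


@dataclass
class TransitionHazard:
    """Daily cause-specific transition probability: baseline value times
    ``exp(log_hr . z)`` times ``exp(treatment_log_hr)`` once treated, where z
    is the standardized hazard design (log-normal biomarkers on the log
    scale, clipped at +-4 SD; see ``_hazard_design``)."""

    base_daily_prob: float
    log_hr: dict[str, float] = field(default_factory=dict)
    treatment_log_hr: float = 0.0

    def validate(self, name: str) -> None:
        _check_prob(self.base_daily_prob, f"hazard_spec[{name}].base_daily_prob")
        _coef_vector(self.log_hr, f"hazard_spec[{name}].log_hr")


def default_hazards() -> dict[tuple[int, int], TransitionHazard]:
    """Daily baseline probabilities and covariate log hazard ratios for the
    seven allowed transitions, chosen to give an in-hospital course broadly
    like a severe-pneumonia cohort (most ward stays resolved within ~30 days,
    death/home/HCF all common, ICU an intermediate pathway) with mortality
    risk sharing covariates with treatment initiation (confounding)."""
    return {
        (WARD, ICU): TransitionHazard(
            0.015,
            {"age": 0.20, "charlson_ge2": 0.20, "crp": 0.35, "ldh": 0.25,
             "log_ddimer": 0.20, "lymphocytes": -0.20},
        ),
        (WARD, DEATH): TransitionHazard(
            0.012,
            {"age": 0.50, "charlson_ge2": 0.35, "crp": 0.30, "ldh": 0.25,
             "log_ddimer": 0.25, "lymphocytes": -0.20, "wave_2": 0.05, "wave_3": 0.10},
        ),
        (WARD, HOME): TransitionHazard(
            0.035,
            {"age": -0.30, "charlson_ge2": -0.20, "crp": -0.25, "lymphocytes": 0.15},
        ),
        (WARD, HCF): TransitionHazard(
            0.018, {"age": 0.30, "charlson_ge2": 0.25}
        ),
        (ICU, DEATH): TransitionHazard(
            0.045, {"age": 0.40, "crp": 0.20, "ldh": 0.15}
        ),
        (ICU, HOME): TransitionHazard(0.018, {"age": -0.25}),
        (ICU, HCF): TransitionHazard(0.022, {"age": 0.20, "charlson_ge2": 0.15}),
    }


@dataclass
class SimulationConfig:
    """Full specification of a synthetic cohort."""

    n_patients: int = 500
    seed: int = 0
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    initiation: InitiationModel = field(default_factory=InitiationModel)
    hazards: dict[tuple[int, int], TransitionHazard] = field(default_factory=default_hazards)
    admin_censor_day: int = 45
    ineligible_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "hospital_acquired": 0.03,
            "readmission": 0.03,
            "pre_treatment": 0.02,
            "outcome_day0": 0.01,
        }
    )
    structure: TransitionStructure = field(default_factory=default_structure)

    def validate(self) -> None:
        if not isinstance(self.n_patients, (int, np.integer)) or self.n_patients < 0:
            raise ConfigurationError(
                f"n_patients must be a nonnegative integer, got {self.n_patients!r}"
            )
        if self.admin_censor_day < 1:
            raise ConfigurationError("admin_censor_day must be >= 1")
        self.covariate_params.validate()
        self.initiation.coef_vector()
        allowed = set(self.structure.allowed)
        if set(self.hazards) != allowed:
            raise ConfigurationError(
                "hazard_spec must cover exactly the allowed transition set; "
                f"got {sorted(self.hazards)}, allowed {sorted(allowed)}"
            )
        for (l, m), hz in self.hazards.items():
            hz.validate(f"{l}->{m}")
        for key, p in self.ineligible_fractions.items():
            if key not in ("hospital_acquired", "readmission", "pre_treatment", "outcome_day0"):
                raise ConfigurationError(f"ineligible_fractions: unknown rule {key!r}")
            _check_prob(p, f"ineligible_fractions[{key}]")
        for l in self.structure.transient:
            total = sum(
                hz.base_daily_prob for (a, _), hz in self.hazards.items() if a == l
            )
            if total >= 1.0:
                raise ConfigurationError(
                    f"total baseline daily exit probability from state {l} is {total} >= 1"
                )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "n_patients": int(self.n_patients),
            "seed": int(self.seed),
            "covariate_params": asdict(self.covariate_params),
            "initiation": asdict(self.initiation),
            "hazards": {
                f"{l}->{m}": asdict(hz) for (l, m), hz in sorted(self.hazards.items())
            },
            "admin_censor_day": int(self.admin_censor_day),
            "ineligible_fractions": dict(self.ineligible_fractions),
        }
        d["covariate_params"]["wave_probs"] = list(self.covariate_params.wave_probs)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        cp = d.get("covariate_params", {})
        cov = CovariateParams(**{**cp, "wave_probs": tuple(cp.get("wave_probs", (0.45, 0.35, 0.20)))})
        init = InitiationModel(**d.get("initiation", {}))
        hazards = {}
        for key, hz in d.get("hazards", {k: asdict(v) for k, v in default_hazards().items()}).items():
            if isinstance(key, str):
                l, m = (int(x) for x in key.split("->"))
            else:
                l, m = key
            hazards[(l, m)] = TransitionHazard(**hz) if isinstance(hz, Mapping) else hz
        return cls(
            n_patients=d.get("n_patients", 500),
            seed=d.get("seed", 0),
            covariate_params=cov,
            initiation=init,
            hazards=hazards,
            admin_censor_day=d.get("admin_censor_day", 45),
            ineligible_fractions=dict(
                d.get(
                    "ineligible_fractions",
                    {"hospital_acquired": 0.03, "readmission": 0.03,
                     "pre_treatment": 0.02, "outcome_day0": 0.01},
                )
            ),
        )


# ---------------------------------------------------------------------------
# design matrix helpers


def design_matrix(df: pd.DataFrame) -> np.ndarray:
    """Analysis design matrix (n x 9): raw covariates with wave dummies."""
    from .errors import SchemaError

    for col in COVARIATE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"cohort table is missing required column {col!r}")
    wave = df["wave"].to_numpy()
    cols = [df[c].to_numpy(dtype=float) for c in COVARIATE_COLUMNS[:-1]]
    cols.append((wave == 2).astype(float))
    cols.append((wave == 3).astype(float))
    return np.column_stack(cols)


def _standardize(Z: np.ndarray, params: CovariateParams) -> np.ndarray:
    mu, sd = params.design_moments()
    return (Z - mu) / sd


#: standardized covariate effects on hazards saturate beyond this many SD
HAZARD_Z_CLIP = 4.0


def _hazard_design(df: pd.DataFrame, params: CovariateParams) -> np.ndarray:
    """Standardized design for the transition-hazard models.

    The log-normal biomarkers (CRP, LDH, D-dimer, lymphocytes) enter on the
    log scale so their standardized values are light-tailed; each column is
    additionally clipped at +-HAZARD_Z_CLIP SD (risk saturation) so that
    multiplicative hazard modification stays bounded.  This only concerns the
    data-generating mechanism: the analysis estimators are nonparametric in
    the outcome model and only the treatment-initiation mechanism (which is
    linear in the raw analysis covariates) enters the censoring model.
    """
    Z = design_matrix(df).copy()
    for col in ("crp", "ldh", "lymphocytes"):
        j = DESIGN_COLUMNS.index(col)
        Z[:, j] = np.log(np.maximum(Z[:, j], 1e-12))
    mu, sd = params.hazard_design_moments()
    return np.clip((Z - mu) / sd, -HAZARD_Z_CLIP, HAZARD_Z_CLIP)


# ---------------------------------------------------------------------------
# core path simulation


def _daily_probs(
    Zs: np.ndarray, config: SimulationConfig
) -> tuple[dict[tuple[int, int], np.ndarray], dict[tuple[int, int], float]]:
    """Per-patient untreated daily transition probabilities and the
    (scalar) treatment multipliers."""
    q = {}
    tmult = {}
    for (l, m), hz in config.hazards.items():
        lp = Zs @ _coef_vector(hz.log_hr, "hazard_spec")
        q[(l, m)] = hz.base_daily_prob * np.exp(lp)
        tmult[(l, m)] = math.exp(hz.treatment_log_hr)
    # positivity of the per-day stay probability under either treatment status
    for l in config.structure.transient:
        for mult_on in (False, True):
            total = np.zeros(Zs.shape[0])
            for (a, m), probs in q.items():
                if a == l:
                    total = total + probs * (tmult[(a, m)] if mult_on else 1.0)
            if total.size and float(total.max()) >= 1.0:
                raise SimulationError(
                    f"total daily exit probability from state {l} reaches "
                    f"{float(total.max()):.3f} >= 1 after covariate modification; "
                    "rescale hazard_spec baseline probabilities or log hazard ratios"
                )
    return q, tmult


def _simulate_paths(
    Zs_init: np.ndarray,
    Zs_haz: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    treatment_day: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate trajectories day by day.

    ``Zs_init`` is the standardized analysis design driving treatment
    initiation; ``Zs_haz`` is the clipped log-scale hazard design driving the
    transition probabilities (see :func:`_hazard_design`).

    If ``treatment_day`` is None, treatment initiation is drawn each day from
    the confounded initiation model (first success wins; no initiation after
    an absorbing event).  Otherwise the given (possibly NaN) initiation days
    are used as a fixed policy.

    Returns ``(tau, icu_day, event_day, event_state)`` where ``event_state``
    is 0 while no absorbing event occurred.
    """
    n = Zs_haz.shape[0]
    admin = config.admin_censor_day
    q, tmult = _daily_probs(Zs_haz, config)
    struct = config.structure

    draw_init = treatment_day is None
    if draw_init:
        init_lp = Zs_init @ config.initiation.coef_vector()
        tau = np.full(n, np.nan)
        u0 = rng.random(n)
        tau[u0 < config.initiation.daily_probability(init_lp, 0)] = 0.0
    else:
        tau = np.asarray(treatment_day, dtype=float).copy()

    state = np.full(n, WARD, dtype=int)
    icu_day = np.full(n, np.nan)
    event_day = np.full(n, np.nan)
    event_state = np.zeros(n, dtype=int)

    for t in range(1, admin + 1):
        state_start = state.copy()
        transient = (state_start == WARD) | (state_start == ICU)
        if not transient.any():
            if not draw_init:
                break
        if draw_init:
            u = rng.random(n)
            cand = transient & np.isnan(tau)
            p = config.initiation.daily_probability(init_lp, t)
            tau[cand & (u < p)] = float(t)
        treated_now = ~np.isnan(tau) & (tau <= t)
        u = rng.random(n)
        for l in struct.transient:
            # one transition draw per day, from the start-of-day state
            mask = transient & (state_start == l)
            if not mask.any():
                continue
            acc = np.zeros(n)
            chosen = np.zeros(n, dtype=int)
            for m in struct.destinations(l):
                p_m = q[(l, m)] * np.where(treated_now, tmult[(l, m)], 1.0)
                hit = mask & (chosen == 0) & (u >= acc) & (u < acc + p_m)
                chosen[hit] = m
                acc = acc + p_m
            moved = chosen > 0
            to_icu = moved & (chosen == ICU)
            icu_day[to_icu] = float(t)
            state[to_icu] = ICU
            to_abs = moved & (chosen != ICU)
            event_day[to_abs] = float(t)
            event_state[to_abs] = chosen[to_abs]
            state[to_abs] = chosen[to_abs]
    return tau, icu_day, event_day, event_state


# ---------------------------------------------------------------------------
# public operations


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a synthetic cohort: one row per patient.

    Columns: patient_id, the raw covariates, treatment_day / icu_day /
    event_day (NaN when absent), event_state (0 when no absorbing event by
    the administrative horizon), and the three exclusion flags.  Patients
    flagged as having their outcome on the admission day carry
    ``event_day == 0``.  Identical config + seed reproduce identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    cp = config.covariate_params

    age = rng.normal(cp.age_mean, cp.age_sd, n)
    sex = (rng.random(n) < cp.male_p).astype(int)
    charlson = (rng.random(n) < cp.charlson_ge2_p).astype(int)
    crp = rng.lognormal(cp.crp_log_mean, cp.crp_log_sd, n)
    ldh = rng.lognormal(cp.ldh_log_mean, cp.ldh_log_sd, n)
    log_ddimer = rng.normal(cp.ddimer_log_mean, cp.ddimer_log_sd, n)
    lymph = rng.lognormal(cp.lymph_log_mean, cp.lymph_log_sd, n)
    wave = rng.choice([1, 2, 3], size=n, p=list(cp.wave_probs))

    fr = config.ineligible_fractions
    flags = {
        name: rng.random(n) < fr.get(name, 0.0) for name in FLAG_COLUMNS
    }
    outcome0 = rng.random(n) < fr.get("outcome_day0", 0.0)

    df = pd.DataFrame(
        {
            "patient_id": np.arange(n, dtype=int),
            "age": age,
            "sex": sex,
            "charlson_ge2": charlson,
            "crp": crp,
            "ldh": ldh,
            "log_ddimer": log_ddimer,
            "lymphocytes": lymph,
            "wave": wave,
        }
    )
    if n == 0:
        for col in ("treatment_day", "icu_day", "event_day"):
            df[col] = np.array([], dtype=float)
        df["event_state"] = np.array([], dtype=int)
        for col in FLAG_COLUMNS:
            df[col] = np.array([], dtype=bool)
        return df

    Zs_init = _standardize(design_matrix(df), cp)
    Zs_haz = _hazard_design(df, cp)
    tau, icu_day, event_day, event_state = _simulate_paths(Zs_init, Zs_haz, config, rng)

    # outcome-on-admission-day records: absorbing event at day 0, destination
    # drawn proportionally to the baseline ward exit rates to absorbing states
    if outcome0.any():
        abs_states = np.array([DEATH, HOME, HCF])
        base = np.array([config.hazards[(WARD, s)].base_daily_prob for s in abs_states])
        probs = base / base.sum()
        k = int(outcome0.sum())
        draws = rng.choice(abs_states, size=k, p=probs)
        tau[outcome0] = np.nan
        icu_day[outcome0] = np.nan
        event_day[outcome0] = 0.0
        event_state[outcome0] = draws

    df["treatment_day"] = tau
    df["icu_day"] = icu_day
    df["event_day"] = event_day
    df["event_state"] = event_state
    for name in FLAG_COLUMNS:
        df[name] = flags[name]
    return df


def simulate_treatment_initiation(
    covariates: Mapping[str, float] | pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator,
    max_day: int | None = None,
) -> int | None:
    """Draw a treatment-initiation day for one covariate vector.

    Initiation is attempted daily from day 0 up to ``max_day`` (default: the
    administrative horizon); the first success is returned, or None.  Within
    :func:`generate_cohort` the same daily model is drawn jointly with the
    trajectory so that initiation cannot occur after an absorbing event.
    """
    row = pd.DataFrame([dict(covariates)])
    z = _standardize(design_matrix(row), config.covariate_params)[0]
    lp = float(z @ config.initiation.coef_vector())
    horizon = config.admin_censor_day if max_day is None else max_day
    for d in range(0, horizon + 1):
        if rng.random() < float(config.initiation.daily_probability(lp, d)):
            return d
    return None


def simulate_trajectory(
    covariates: Mapping[str, float] | pd.Series,
    treatment_day: int | None,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Simulate one multi-state history as an ordered (day, state) list.

    The history starts at (0, ward); a transition to the ICU and at most one
    absorbing transition may follow.  Trajectories still transient at the
    administrative horizon are truncated there (no terminal entry added).
    """
    row = pd.DataFrame([dict(covariates)])
    Zs_init = _standardize(design_matrix(row), config.covariate_params)
    Zs_haz = _hazard_design(row, config.covariate_params)
    tau = np.array([np.nan if treatment_day is None else float(treatment_day)])
    _, icu_day, event_day, event_state = _simulate_paths(
        Zs_init, Zs_haz, config, rng, treatment_day=tau
    )
    history: list[tuple[int, int]] = [(0, WARD)]
    if not np.isnan(icu_day[0]):
        history.append((int(icu_day[0]), ICU))
    if event_state[0] != 0:
        history.append((int(event_day[0]), int(event_state[0])))
    return history


def state_at_day(
    icu_day: np.ndarray, event_day: np.ndarray, event_state: np.ndarray, t: float
) -> np.ndarray:
    """State occupied at the end of day ``t`` (vectorized over patients)."""
    state = np.full(len(event_state), WARD, dtype=int)
    in_icu = ~np.isnan(icu_day) & (icu_day <= t)
    state[in_icu] = ICU
    done = ~np.isnan(event_day) & (event_day <= t)
    state[done] = event_state[done]
    return state


def occupation_oracle(
    config: SimulationConfig,
    policy: str | int,
    n_mc: int,
    seed: int,
) -> pd.DataFrame:
    """Monte-Carlo ground-truth state-occupation probabilities under a fixed
    treatment policy.

    ``policy`` is ``"never"`` (never treat) or an integer day d (treat every
    patient at day d, overriding the confounded initiation model).  Returns a
    DataFrame indexed by day 0..admin_censor_day with one column per state id;
    each row sums to 1.
    """
    config.validate()
    if n_mc < 1:
        raise ConfigurationError(f"n_mc must be >= 1, got {n_mc!r}")
    rng = np.random.default_rng(seed)
    cp = config.covariate_params
    n = n_mc
    df = pd.DataFrame(
        {
            "age": rng.normal(cp.age_mean, cp.age_sd, n),
            "sex": (rng.random(n) < cp.male_p).astype(int),
            "charlson_ge2": (rng.random(n) < cp.charlson_ge2_p).astype(int),
            "crp": rng.lognormal(cp.crp_log_mean, cp.crp_log_sd, n),
            "ldh": rng.lognormal(cp.ldh_log_mean, cp.ldh_log_sd, n),
            "log_ddimer": rng.normal(cp.ddimer_log_mean, cp.ddimer_log_sd, n),
            "lymphocytes": rng.lognormal(cp.lymph_log_mean, cp.lymph_log_sd, n),
            "wave": rng.choice([1, 2, 3], size=n, p=list(cp.wave_probs)),
        }
    )
    Zs_init = _standardize(design_matrix(df), cp)
    Zs_haz = _hazard_design(df, cp)
    if policy == "never":
        tau = np.full(n, np.nan)
    else:
        tau = np.full(n, float(policy))
    _, icu_day, event_day, event_state = _simulate_paths(
        Zs_init, Zs_haz, config, rng, treatment_day=tau
    )
    days = np.arange(config.admin_censor_day + 1)
    out = np.zeros((len(days), 5))
    for i, t in enumerate(days):
        s = state_at_day(icu_day, event_day, event_state, t)
        counts = np.bincount(s, minlength=6)[1:6]
        out[i] = counts / n
    return pd.DataFrame(out, index=pd.Index(days, name="day"), columns=[1, 2, 3, 4, 5])
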