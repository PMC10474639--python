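"""Inverse probability of artificial-censoring weights.

The clone-censor design censors clones when they deviate from their arm's
protocol during the grace period; that censoring is informative whenever
treatment initiation depends on covariates.  Each arm gets its own Cox
censoring model (time to artificial censoring, Breslow ties and baseline),
fitted on the clones of that arm with all other follow-up ends treated as
right censoring of the *censoring* process.  The conditional probability of
remaining uncensored is

    S_C(t | Z) = exp(-Lambda_0C(min(t, grace)) * exp(beta_C . Z))

and the (unstabilized) weight is its reciprocal, W(t) = 1 / S_C(t | Z).
Weights are 1 at day 0, nondecreasing, and constant after the grace period;
in the treated arm they can only change at grace end (the only censoring
time there).

Risk-set conventions: an outcome event on day k removes the clone from the
day-k censoring risk set (events precede censoring within a day), encoded by
assigning duration k - 1/2 to within-grace outcome events.  In the outcome
analysis the weight applied to the risk interval (t-1, t] is W(t-1)
(left-continuous carry-forward).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .coxph import CoxBreslowFit, fit_cox_breslow
from .errors import (
    ConfigurationError,
    NoCensoringEventsError,
    SchemaError,
    WeightUnderflowError,
)
from .simulate import DESIGN_COLUMNS

ARMS = ("treated", "control")


def clone_design(clones: pd.DataFrame, covariate_names: tuple[str, ...]) -> np.ndarray:
    """Numeric design matrix over ``covariate_names``; ``wave_2``/``wave_3``
    are derived from a ``wave`` column when not present directly."""
    cols = []
    for name in covariate_names:
        if name in clones.columns:
            cols.append(clones[name].to_numpy(dtype=float))
        elif name in ("wave_2", "wave_3") and "wave" in clones.columns:
            level = int(name.split("_")[1])
            cols.append((clones["wave"].to_numpy() == level).astype(float))
        else:
            raise SchemaError(f"clone table is missing required covariate column {name!r}")
    return np.column_stack(cols) if cols else np.zeros((len(clones), 0))


def censoring_durations(
    clones: pd.DataFrame, grace_days: int
) -> tuple[np.ndarray, np.ndarray]:
    """Durations and event indicators for the time-to-artificial-censoring
    process of one arm.

    Artificially censored clones are events at their censoring day.  Clones
    whose follow-up ends with an outcome event within the grace period leave
    the censoring risk set just before that day (duration k - 1/2, events
    precede censoring within a day); everyone else remains at risk of
    censoring through the grace period.
    """
    fe = clones["followup_end"].to_numpy(dtype=float)
    delta = clones["censor_indicator"].to_numpy(dtype=int) == 1
    cd = clones["censor_day"].to_numpy(dtype=float)
    event_end = clones["end_reason"].to_numpy() == "event"
    g = float(grace_days)
    time = np.where(delta, cd, np.where(event_end & (fe <= g), fe - 0.5, g))
    return time, delta


@dataclass
class CensoringModel:
    """Arm-specific proportional-hazards model for artificial censoring."""

    arm: str
    covariate_names: tuple[str, ...]
    grace_days: int
    fit: CoxBreslowFit | None  # None -> degenerate (no censoring events)
    marginal_times: np.ndarray = field(default_factory=lambda: np.zeros(0))
    marginal_cumhaz: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def degenerate(self) -> bool:
        return self.fit is None

    @property
    def coefficients(self) -> np.ndarray:
        if self.fit is None:
            return np.zeros(len(self.covariate_names))
        return self.fit.coef

    @property
    def baseline_cumhaz(self) -> pd.Series:
        """Breslow baseline cumulative hazard (at covariate value zero)."""
        if self.fit is None:
            return pd.Series(dtype=float)
        return pd.Series(self.fit.baseline_cumhaz_zero, index=self.fit.baseline_times)

    def uncensored_probability(self, X: np.ndarray, t: np.ndarray | float) -> np.ndarray:
        """S_C(t | Z): probability of remaining artificially uncensored
        through day t; constant for t beyond the grace period; 1 at t = 0."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.covariate_names):
            raise SchemaError(
                f"expected {len(self.covariate_names)} covariates, got {X.shape[1]}"
            )
        t = np.minimum(np.asarray(t, dtype=float), float(self.grace_days))
        if self.fit is None:
            return np.ones(np.broadcast_shapes(X.shape[:1], np.shape(t)))
        return self.fit.survival(X, t)

    def marginal_uncensored_probability(self, t: np.ndarray | float) -> np.ndarray:
        """Covariate-free uncensored probability (stabilization numerator)."""
        t = np.minimum(np.asarray(t, dtype=float), float(self.grace_days))
        if self.marginal_times.size == 0:
            return np.ones(np.shape(t) or ())
        idx = np.searchsorted(self.marginal_times, t, side="right")
        cum = np.concatenate([[0.0], self.marginal_cumhaz])[idx]
        return np.exp(-cum)


def fit_censoring_model(
    clones: pd.DataFrame,
    covariate_names: tuple[str, ...] = DESIGN_COLUMNS,
    grace_days: int = 5,
    on_no_events: str = "raise",
) -> CensoringModel:
    """Fit the Cox censoring model for one arm's clones.

    With ``on_no_events="raise"`` an arm without any artificial censoring
    raises :class:`NoCensoringEventsError`; ``"degenerate"`` instead returns a
    degenerate model whose weights are identically 1.
    """
    arms = set(clones["arm"].unique())
    if len(arms) != 1:
        raise SchemaError(f"fit_censoring_model expects clones of a single arm, got {arms}")
    arm = arms.pop()
    time, delta = censoring_durations(clones, grace_days)
    # marginal (covariate-free) Nelson-Aalen of the censoring process
    uniq = np.unique(time[delta])
    at_risk = np.array([float(np.sum(time >= u)) for u in uniq])
    d = np.array([float(np.sum(delta & (time == u))) for u in uniq])
    marg_times, marg_cumhaz = uniq, np.cumsum(d / at_risk) if uniq.size else np.zeros(0)

    if not delta.any():
        if on_no_events == "degenerate":
            return CensoringModel(arm, tuple(covariate_names), grace_days, None)
        raise NoCensoringEventsError(
            f"arm {arm!r} has no artificial censoring events; the censoring "
            "model is degenerate and all weights equal 1 (refit with "
            "on_no_events='degenerate' to accept this)"
        )
    X = clone_design(clones, tuple(covariate_names))
    fit = fit_cox_breslow(time, delta, X)
    return CensoringModel(
        arm, tuple(covariate_names), grace_days, fit, marg_times, marg_cumhaz
    )


def uncensored_probability(
    model: CensoringModel, Z: np.ndarray, t: np.ndarray | float
) -> np.ndarray:
    """Module-level convenience wrapper over the model method."""
    return model.uncensored_probability(Z, t)


def _survival_grid(
    models: dict[str, CensoringModel],
    clones: pd.DataFrame,
    grace_days: int,
    stabilize: bool,
    min_survival: float,
) -> np.ndarray:
    """(n_clones, grace+1) matrix of S_C(t | Z) for t = 0..grace (or the
    stabilized ratio denominator/numerator arrangement)."""
    n = len(clones)
    S = np.ones((n, grace_days + 1))
    arm_col = clones["arm"].to_numpy()
    for arm, model in models.items():
        mask = arm_col == arm
        if not mask.any():
            continue
        X = clone_design(clones.loc[mask], model.covariate_names)
        for t in range(1, grace_days + 1):
            S[mask, t] = model.uncensored_probability(X, float(t))
    bad = S[:, grace_days] < min_survival
    if bad.any():
        ids = clones.loc[bad, "patient_id"].tolist()[:20]
        raise WeightUnderflowError(
            f"uncensored probability below {min_survival} for {int(bad.sum())} "
            f"clone(s) (patient ids {ids}); consider truncating weights"
        )
    W = 1.0 / S
    if stabilize:
        for arm, model in models.items():
            mask = arm_col == arm
            for t in range(1, grace_days + 1):
                W[mask, t] *= float(model.marginal_uncensored_probability(float(t)))
    return W


def compute_weights(
    models: dict[str, CensoringModel],
    clones: pd.DataFrame,
    admin_censor_day: int = 45,
    grace_days: int = 5,
    stabilize: bool = False,
    min_survival: float = 1e-8,
) -> pd.DataFrame:
    """Per-clone, per-day weight table.

    One row per clone per day the clone is at risk (day 0 through its
    follow-up end): columns ``patient_id, arm, day, weight`` where
    ``weight = 1 / S_C(min(day, grace) | Z)`` under the clone's own arm's
    model (times the marginal uncensored probability when stabilized).
    """
    for arm in set(clones["arm"].unique()):
        if arm not in models:
            raise SchemaError(f"no censoring model supplied for arm {arm!r}")
    Wgrid = _survival_grid(models, clones, grace_days, stabilize, min_survival)
    fe = clones["followup_end"].to_numpy(dtype=int)
    fe = np.minimum(fe, admin_censor_day)
    n_days = fe + 1
    idx = np.repeat(np.arange(len(clones)), n_days)
    day = np.concatenate([np.arange(k) for k in n_days]) if len(clones) else np.zeros(0, int)
    wcol = Wgrid[idx, np.minimum(day, grace_days)]
    return pd.DataFrame(
        {
            "patient_id": clones["patient_id"].to_numpy()[idx],
            "arm": clones["arm"].to_numpy()[idx],
            "day": day.astype(int),
            "weight": wcol,
        }
    )


def weights_at(
    models: dict[str, CensoringModel],
    clones: pd.DataFrame,
    day: float,
    grace_days: int = 5,
    stabilize: bool = False,
    min_survival: float = 1e-8,
) -> np.ndarray:
    """Per-clone weight evaluated at a single day (vectorized)."""
    Wgrid = _survival_grid(models, clones, grace_days, stabilize, min_survival)
    t = int(min(day, grace_days))
    return Wgrid[:, t]


def truncate_weights(table: pd.DataFrame, upper_quantile: float) -> pd.DataFrame:
    """Cap weights above the per-arm empirical ``upper_quantile``.

    ``upper_quantile`` must lie in (0.5, 1]; 1 is the identity.
    """
    if not (0.5 < upper_quantile <= 1.0):
        raise ConfigurationError(
            f"upper_quantile must be in (0.5, 1], got {upper_quantile!r}"
        )
    if upper_quantile == 1.0:
        return table.copy()
    out = table.copy()
    for arm, group in out.groupby("arm"):
        cap = float(np.quantile(group["weight"].to_numpy(), upper_quantile))
        out.loc[out["arm"] == arm, "weight"] = np.minimum(
            out.loc[out["arm"] == arm, "weight"].to_numpy(), cap
        )
    return out


def balance_smd(
    clones: pd.DataFrame,
    weights: np.ndarray,
    covariate_names: tuple[str, ...] = DESIGN_COLUMNS,
    at_day: int = 5,
    grace_days: int = 5,
) -> pd.DataFrame:
    """Standardized mean differences between arms, unweighted and weighted.

    Compares the clones still artificially uncensored at ``at_day``
    (requires ``at_day >= grace_days`` so censoring status is settled);
    ``weights`` is the per-clone weight evaluated at ``at_day``.
    SMD = |mean_T - mean_C| / sqrt((var_T + var_C) / 2), with p(1-p)
    variance for binary covariates.  A covariate with zero pooled variance
    gets SMD 0 when the means agree and NaN otherwise.
    """
    if at_day < grace_days:
        raise ConfigurationError("at_day must be at or after the end of the grace period")
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(clones):
        raise SchemaError("weights must align with the clone table rows")
    keep = clones["censor_indicator"].to_numpy(dtype=int) == 0
    sub = clones.loc[keep]
    w = weights[keep]
    X = clone_design(sub, tuple(covariate_names))
    arm = (sub["arm"].to_numpy() == "treated")

    def moments(x, mask, wts):
        ww = wts[mask]
        xx = x[mask]
        m = float(np.average(xx, weights=ww))
        v = float(np.average((xx - m) ** 2, weights=ww))
        return m, v

    rows = []
    ones = np.ones(len(sub))
    for j, name in enumerate(covariate_names):
        x = X[:, j]
        binary = set(np.unique(x)) <= {0.0, 1.0}
        entry = {"covariate": name}
        for label, wts in (("smd_unweighted", ones), ("smd_weighted", w)):
            mt, vt = moments(x, arm, wts)
            mc, vc = moments(x, ~arm, wts)
            if binary:
                vt, vc = mt * (1 - mt), mc * (1 - mc)
            pooled = (vt + vc) / 2.0
            if pooled <= 0:
                smd = 0.0 if np.isclose(mt, mc) else float("nan")
                if np.isnan(smd):
                    warnings.warn(
                        f"covariate {name!r}: zero pooled variance with unequal "
                        "means; SMD undefined"
                    )
            else:
                smd = abs(mt - mc) / np.sqrt(pooled)
            entry[label] = smd
        rows.append(entry)
    return pd.DataFrame(rows, columns=["covariate", "smd_unweighted", "smd_weighted"])


class CensoringWeightModel(BaseEstimator):
    """Arm-specific inverse-probability-of-artificial-censoring weights.

    A scikit-learn style estimator: ``fit`` takes the clone table produced by
    :func:`cloneweight.emulate.clone_and_censor` and fits one Cox censoring
    model per arm; ``transform`` returns the per-clone-day weight table and
    ``weight_at`` evaluates per-clone weights at a single day.

    Parameters
    ----------
    covariates : tuple of column names entering the censoring models.
    grace_days, admin_censor_day : emulation timing (days).
    stabilize : multiply weights by the arm's marginal uncensored probability.
    truncation_quantile : per-arm cap applied by ``transform`` (1 = none).
    on_no_events : "degenerate" (weights 1) or "raise" for arms without
        censoring events.
    """

    def __init__(
        self,
        covariates: tuple[str, ...] = DESIGN_COLUMNS,
        grace_days: int = 5,
        admin_censor_day: int = 45,
        stabilize: bool = False,
        truncation_quantile: float = 1.0,
        min_survival: float = 1e-8,
        on_no_events: str = "degenerate",
    ):
        self.covariates = covariates
        self.grace_days = grace_days
        self.admin_censor_day = admin_censor_day
        self.stabilize = stabilize
        self.truncation_quantile = truncation_quantile
        self.min_survival = min_survival
        self.on_no_events = on_no_events

    def fit(self, clones: pd.DataFrame, y=None) -> "CensoringWeightModel":
        self.models_ = {}
        for arm in ARMS:
            sub = clones.loc[clones["arm"] == arm]
            if len(sub) == 0:
                continue
            self.models_[arm] = fit_censoring_model(
                sub, tuple(self.covariates), self.grace_days, self.on_no_events
            )
        self.covariate_names_ = tuple(self.covariates)
        return self

    def transform(self, clones: pd.DataFrame) -> pd.DataFrame:
        table = compute_weights(
            self.models_,
            clones,
            admin_censor_day=self.admin_censor_day,
            grace_days=self.grace_days,
            stabilize=self.stabilize,
            min_survival=self.min_survival,
        )
        return truncate_weights(table, self.truncation_quantile)

    def fit_transform(self, clones: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(clones).transform(clones)

    def weight_at(self, clones: pd.DataFrame, day: float) -> np.ndarray:
        return weights_at(
            self.models_,
            clones,
            day,
            grace_days=self.grace_days,
            stabilize=self.stabilize,
            min_survival=self.min_survival,
        )

    def balance(self, clones: pd.DataFrame, at_day: int | None = None) -> pd.DataFrame:
        at_day = self.grace_days if at_day is None else at_day
        w = self.weight_at(clones, at_day)
        return balance_smd(
            clones, w, tuple(self.covariates), at_day=at_day, grace_days=self.grace_days
        )
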