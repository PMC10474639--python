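"""Treatment-effect summary: weighted proportional odds on the ordinal
clinical-severity scale, with a nonparametric bootstrap over the whole
clone-censor-weight pipeline.

The clinical severity at a fixed evaluation day is graded on an ordered
5-point scale from best to worst: 1 discharged home, 2 normal ward, 3
discharged to another healthcare facility, 4 ICU, 5 in-hospital death
(absorbing states keep their category forever).  The cumulative-logit model

    logit P(Y <= j | arm) = theta_j - beta * arm

is maximized with each clone's log-likelihood contribution multiplied by its
inverse-probability-of-censoring weight at the evaluation day; the reported
odds ratio exp(beta) is oriented so that values above 1 mean the treated
arm's severity distribution is shifted toward the worse categories.

Confidence intervals resample the original patients (before cloning) with
replacement and rerun the entire pipeline -- eligibility, cloning, censoring
models, weights, ordinal fit -- per replicate, so the interval reflects the
uncertainty of the weight estimation as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from . import emulate, ipcw
from .errors import (
    ConfigurationError,
    ConvergenceError,
    EstimationError,
    FittingError,
    SchemaError,
    SeparationError,
)
from .simulate import DESIGN_COLUMNS
from .states import DEATH, HCF, HOME, ICU, WARD

#: clinical-severity category for each multi-state state, best (1) to worst (5)
STATE_TO_CATEGORY = {HOME: 1, WARD: 2, HCF: 3, ICU: 4, DEATH: 5}
CATEGORY_LABELS = {1: "home", 2: "ward", 3: "hcf", 4: "icu", 5: "death"}


def ordinal_status_at(
    clones: pd.DataFrame,
    day: int,
    weights: np.ndarray | None = None,
    variant: str = "five_level",
    horizon: int = 45,
) -> pd.DataFrame:
    """Ordinal severity outcomes at the end of ``day`` for all clones still
    artificially uncensored by then.

    Clones censored artificially before (or at) the evaluation day are
    excluded; their probability mass is carried by the weights of the
    uncensored clones.  ``variant="four_level"`` (the end-of-follow-up
    analysis) drops the normal-ward category and raises if any clone still
    occupies the ward at ``day``.
    """
    if day > horizon:
        raise ConfigurationError(f"evaluation day {day} exceeds the horizon {horizon}")
    if variant not in ("five_level", "four_level"):
        raise ConfigurationError(f"unknown variant {variant!r}")
    censored = clones["censor_indicator"].to_numpy(dtype=int) == 1
    cd = clones["censor_day"].to_numpy(dtype=float)
    keep = ~(censored & (cd <= day))
    sub = clones.loc[keep]
    w = np.ones(len(sub)) if weights is None else np.asarray(weights, dtype=float)[keep]

    event_day = sub["event_day"].to_numpy(dtype=float)
    event_state = sub["event_state"].to_numpy(dtype=int)
    icu_day = sub["icu_day"].to_numpy(dtype=float)
    has_event = (sub["end_reason"].to_numpy() == "event") & (event_day <= day)
    state = np.where(
        has_event,
        event_state,
        np.where(~np.isnan(icu_day) & (icu_day <= day), ICU, WARD),
    )
    category = np.vectorize(STATE_TO_CATEGORY.get)(state) if len(sub) else np.zeros(0, int)

    if variant == "four_level":
        if np.any(category == 2):
            raise EstimationError(
                f"{int((category == 2).sum())} clone(s) still occupy the normal "
                f"ward at day {day}; the four-level scale is undefined for ward "
                "occupants -- use variant='five_level'"
            )
        # re-rank {home, hcf, icu, death} onto 1..4 preserving the order
        category = np.searchsorted(np.array([1, 3, 4, 5]), category) + 1
    return pd.DataFrame(
        {
            "patient_id": sub["patient_id"].to_numpy(),
            "arm": sub["arm"].to_numpy(),
            "evaluation_day": int(day),
            "category": category.astype(int),
            "weight": w,
        }
    )


# ---------------------------------------------------------------------------
# weighted cumulative-logit fit on aggregated (arm x category) counts


def _po_nll_grad(par: np.ndarray, counts: np.ndarray) -> tuple[float, np.ndarray]:
    K = counts.shape[1]
    t1 = par[0]
    gaps = np.exp(par[1 : K - 1])
    theta = t1 + np.concatenate([[0.0], np.cumsum(gaps)])
    beta = par[-1]
    nll = 0.0
    g_theta = np.zeros(K - 1)
    g_beta = 0.0
    for x in (0.0, 1.0):
        c = counts[int(x)]
        a = theta - beta * x
        F = expit(a)
        p = np.diff(np.concatenate([[0.0], F, [1.0]]))
        p = np.maximum(p, 1e-300)
        nll -= float(c @ np.log(p))
        fprime = F * (1.0 - F)
        dll_da = (c[:-1] / p[:-1] - c[1:] / p[1:]) * fprime
        g_theta -= dll_da
        g_beta -= float((-x) * dll_da.sum())
    grad = np.zeros_like(par)
    grad[0] = g_theta.sum()
    for m in range(1, K - 1):
        grad[m] = gaps[m - 1] * g_theta[m:].sum()
    grad[-1] = g_beta
    return nll, grad


def _merge_boundary_categories(
    counts: np.ndarray, labels: list[int]
) -> tuple[np.ndarray, list[int]]:
    """Drop categories empty in both arms; merge boundary categories empty in
    one arm into their neighbor (with a warning)."""
    keep = counts.sum(axis=0) > 0
    if not keep.all():
        counts = counts[:, keep]
        labels = [lab for lab, k in zip(labels, keep) if k]
    changed = True
    while changed and counts.shape[1] > 2:
        changed = False
        if (counts[:, 0] == 0).any():
            warnings.warn(
                f"boundary category {labels[0]} empty in one arm; merging into "
                f"category {labels[1]}"
            )
            counts = np.column_stack([counts[:, 0] + counts[:, 1], counts[:, 2:]])
            labels = labels[1:]
            changed = True
        elif (counts[:, -1] == 0).any():
            warnings.warn(
                f"boundary category {labels[-1]} empty in one arm; merging into "
                f"category {labels[-2]}"
            )
            counts = np.column_stack([counts[:, :-2], counts[:, -2] + counts[:, -1]])
            labels = labels[:-1]
            changed = True
    return counts, labels


class ProportionalOddsModel(BaseEstimator):
    """Weighted cumulative-logit (proportional odds) model with a binary arm
    covariate, scikit-learn style.

    ``fit(X, y, sample_weight)`` takes the treated indicator (0/1) and ordered
    category labels; per-observation weights multiply the log-likelihood
    contributions.  Fitted attributes: ``coef_`` (the arm log odds ratio,
    oriented toward severity), ``odds_ratio_``, ``cutpoints_``,
    ``categories_``, ``converged_``, ``n_iter_``.
    """

    def __init__(self, max_iter: int = 200, tol: float = 1e-10):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y, sample_weight=None) -> "ProportionalOddsModel":
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y)
        w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)
        if set(np.unique(x)) - {0.0, 1.0}:
            raise SchemaError("X must be a binary treated indicator (0/1)")
        labels = sorted(np.unique(y).tolist())
        if len(labels) < 2:
            raise EstimationError("need at least 2 outcome categories to fit")
        if len(np.unique(x)) < 2:
            raise EstimationError("both arms must be represented")
        counts = np.zeros((2, len(labels)))
        for i, lab in enumerate(labels):
            sel = y == lab
            counts[0, i] = w[sel & (x == 0)].sum()
            counts[1, i] = w[sel & (x == 1)].sum()
        counts, labels = _merge_boundary_categories(counts, labels)
        if counts.shape[1] < 2:
            raise EstimationError("fewer than 2 categories remain after merging")

        K = counts.shape[1]
        tot = counts.sum(axis=0)
        cum = np.clip(np.cumsum(tot)[:-1] / tot.sum(), 1e-4, 1 - 1e-4)
        theta0 = logit(cum)
        gaps0 = np.maximum(np.diff(theta0), 1e-3)
        x0 = np.concatenate([[theta0[0]], np.log(gaps0), [0.0]])
        res = minimize(
            _po_nll_grad,
            x0,
            args=(counts,),
            jac=True,
            method="BFGS",
            options={"maxiter": self.max_iter, "gtol": 1e-8},
        )
        beta = float(res.x[-1])
        if abs(beta) > 10.0:
            raise SeparationError(
                "arm coefficient diverged in the proportional odds fit "
                "(complete separation of the severity distribution)"
            )
        if not res.success and float(np.max(np.abs(res.jac))) > 1e-3:
            raise ConvergenceError(
                f"proportional odds fit did not converge: {res.message}"
            )
        t1 = res.x[0]
        self.cutpoints_ = t1 + np.concatenate([[0.0], np.cumsum(np.exp(res.x[1 : K - 1]))])
        self.coef_ = beta
        self.odds_ratio_ = float(np.exp(beta))
        self.categories_ = tuple(labels)
        self.converged_ = bool(res.success or float(np.max(np.abs(res.jac))) <= 1e-3)
        self.n_iter_ = int(res.nit)
        self.loglik_ = -float(res.fun)
        return self


def weighted_proportional_odds(outcomes: pd.DataFrame) -> float:
    """Point estimate of the severity odds ratio from an outcome table
    produced by :func:`ordinal_status_at` (treated vs control; > 1 means the
    treated arm is shifted toward severity)."""
    x = (outcomes["arm"].to_numpy() == "treated").astype(float)
    model = ProportionalOddsModel().fit(
        x, outcomes["category"].to_numpy(), outcomes["weight"].to_numpy()
    )
    return model.odds_ratio_


# ---------------------------------------------------------------------------
# full-pipeline bootstrap


@dataclass
class EffectEstimate:
    """Proportional-odds effect with a percentile bootstrap interval."""

    evaluation_day: int
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    n_bootstrap: int
    n_failed: int
    seed: int
    variant: str = "five_level"
    interval_type: str = "percentile"
    replicates: np.ndarray = field(default_factory=lambda: np.zeros(0), repr=False)


def estimate_effect_once(
    patients: pd.DataFrame,
    evaluation_day: int = 30,
    variant: str = "five_level",
    emulation: emulate.EmulationConfig | None = None,
    covariates: tuple[str, ...] = DESIGN_COLUMNS,
    stabilize: bool = False,
) -> float:
    """One pass of the pipeline: eligibility -> clone -> censoring models ->
    weights at the evaluation day -> weighted proportional odds."""
    emu = emulation or emulate.EmulationConfig()
    eligible, _ = emulate.apply_eligibility(patients)
    clones = emulate.clone_and_censor(eligible, emu)
    wm = ipcw.CensoringWeightModel(
        covariates=covariates,
        grace_days=emu.grace_days,
        admin_censor_day=emu.admin_censor_day,
        stabilize=stabilize,
        on_no_events="degenerate",
    ).fit(clones)
    w = wm.weight_at(clones, evaluation_day)
    outcomes = ordinal_status_at(
        clones, evaluation_day, weights=w, variant=variant, horizon=emu.admin_censor_day
    )
    return weighted_proportional_odds(outcomes)


def bootstrap_pipeline(
    patients: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    evaluation_day: int = 30,
    variant: str = "five_level",
    emulation: emulate.EmulationConfig | None = None,
    covariates: tuple[str, ...] = DESIGN_COLUMNS,
    stabilize: bool = False,
    max_failure_fraction: float = 0.10,
) -> EffectEstimate:
    """Nonparametric bootstrap of the whole pipeline.

    Original patients (pre-cloning) are resampled with replacement so every
    replicate re-estimates the censoring models and weights; the 95% interval
    is the percentile interval of the replicate odds ratios.  Replicates whose
    fits fail are dropped and counted; more than ``max_failure_fraction``
    failures raise an error.
    """
    if B < 1:
        raise ConfigurationError(f"B must be >= 1, got {B!r}")
    point = estimate_effect_once(
        patients, evaluation_day, variant, emulation, covariates, stabilize
    )
    rng = np.random.default_rng(seed)
    n = len(patients)
    reps = []
    failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        sample = patients.iloc[idx].reset_index(drop=True)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reps.append(
                    estimate_effect_once(
                        sample, evaluation_day, variant, emulation, covariates, stabilize
                    )
                )
        except FittingError:
            failed += 1
        except EstimationError:
            failed += 1
    if failed > max_failure_fraction * B:
        raise FittingError(
            f"{failed} of {B} bootstrap replicates failed to converge "
            f"(> {max_failure_fraction:.0%} allowed)"
        )
    reps_arr = np.array(reps)
    lo, hi = np.percentile(reps_arr, [2.5, 97.5])
    return EffectEstimate(
        evaluation_day=evaluation_day,
        odds_ratio=point,
        ci_lower=float(lo),
        ci_upper=float(hi),
        n_bootstrap=B,
        n_failed=failed,
        seed=seed,
        variant=variant,
        replicates=reps_arr,
    )
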