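"""Cox proportional-hazards fitting with Breslow tie handling.

A small Newton-Raphson maximizer of the Breslow partial likelihood with the
Breslow estimator of the baseline cumulative hazard.  Written in-package
because the censoring models of the clone-censor-weight design involve at
most ``grace_days`` distinct event times and are refitted thousands of times
inside the pipeline bootstrap, so the fit is a handful of vectorized
risk-set reductions.

Covariates are standardized internally for conditioning; coefficients and
the baseline hazard are reported on the raw covariate scale.  The baseline
cumulative hazard is anchored at the covariate mean (``Lambda_mean``); the
conventional Breslow baseline at covariate value zero is
``Lambda_mean * exp(-beta . mean)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError, SeparationError


@dataclass
class CoxBreslowFit:
    """Fitted proportional-hazards model (Breslow ties and baseline)."""

    coef: np.ndarray  # raw-scale coefficients
    mean: np.ndarray  # covariate means used for centering
    baseline_times: np.ndarray  # distinct event times, ascending
    baseline_cumhaz_mean: np.ndarray  # Breslow cumulative hazard at X = mean
    loglik: float
    n_iter: int
    converged: bool

    @property
    def baseline_cumhaz_zero(self) -> np.ndarray:
        """Breslow baseline cumulative hazard at covariate value 0."""
        return self.baseline_cumhaz_mean * np.exp(-float(self.coef @ self.mean))

    def cumulative_hazard(self, X: np.ndarray, t: np.ndarray | float) -> np.ndarray:
        """Cumulative hazard at time(s) t for covariate rows X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.baseline_times, t, side="right")
        base = np.concatenate([[0.0], self.baseline_cumhaz_mean])[idx]
        rel = np.exp((X - self.mean) @ self.coef)
        return base * rel

    def survival(self, X: np.ndarray, t: np.ndarray | float) -> np.ndarray:
        return np.exp(-self.cumulative_hazard(X, t))


def fit_cox_breslow(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> CoxBreslowFit:
    """Maximize the Breslow partial likelihood by Newton-Raphson.

    ``time`` are (possibly tied) nonnegative durations, ``event`` the event
    indicator, ``X`` the covariate matrix.  Constant covariate columns get a
    zero coefficient (the model degenerates to the Nelson-Aalen estimator of
    the censoring hazard when every column is constant).  Raises
    SeparationError when a standardized coefficient diverges and
    ConvergenceError when the iteration budget is exhausted.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != time.shape[0]:
        raise ValueError("X and time must have the same number of rows")
    n, p = X.shape
    if event.sum() == 0:
        raise ValueError("no events; the partial likelihood is constant")

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    active = sd > 0

    order = np.argsort(time, kind="stable")
    ts, es = time[order], event[order]
    Xo = ((X - mean) / np.where(active, sd, 1.0))[order][:, active]
    pa = Xo.shape[1]

    uniq_event_times = np.unique(ts[es])
    # risk set for event time t: all rows with ts >= t -> suffix sums
    start = np.searchsorted(ts, uniq_event_times, side="left")
    d = np.array([float(np.sum(es[ts == t])) for t in uniq_event_times])
    sum_x_events = Xo[es].sum(axis=0) if pa else np.zeros(0)

    def loglik(b: np.ndarray) -> float:
        eta = Xo @ b if pa else np.zeros(n)
        w = np.exp(eta)
        s0 = np.cumsum(w[::-1])[::-1][start]
        return float(eta[es].sum() - (d * np.log(s0)).sum())

    beta = np.zeros(pa)
    ll = loglik(beta)
    n_iter = 0
    converged = pa == 0
    improved = 0.0

    while not converged and n_iter < max_iter:
        n_iter += 1
        eta = Xo @ beta
        w = np.exp(eta)
        s0 = np.cumsum(w[::-1])[::-1][start]
        s1 = np.cumsum((Xo * w[:, None])[::-1], axis=0)[::-1][start]
        xx = np.einsum("ni,nj->nij", Xo, Xo) * w[:, None, None]
        s2 = np.cumsum(xx[::-1], axis=0)[::-1][start]
        mu = s1 / s0[:, None]
        grad = sum_x_events - (d[:, None] * mu).sum(axis=0)
        hess = -(
            d[:, None, None] * (s2 / s0[:, None, None] - np.einsum("ki,kj->kij", mu, mu))
        ).sum(axis=0)
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
        # a vanishing Newton step bounds the distance to the optimum on the
        # standardized scale far below any reported precision
        if float(np.max(np.abs(step))) < 1e-7:
            converged = True
            break
        # step-halving line search on the partial likelihood
        alpha = 1.0
        new_beta, new_ll = beta + step, loglik(beta + step)
        for _ in range(30):
            if np.isfinite(new_ll) and new_ll >= ll - 1e-12:
                break
            alpha /= 2.0
            new_beta = beta + alpha * step
            new_ll = loglik(new_beta)
        improved = new_ll - ll
        beta, ll = new_beta, new_ll
        if np.any(np.abs(beta) > 15.0):
            worst = int(np.flatnonzero(active)[int(np.argmax(np.abs(beta)))])
            raise SeparationError(
                f"coefficient for covariate index {worst} diverged "
                "(quasi-complete separation of the censoring event)"
            )
        # gradient tolerance relative to the log-likelihood scale: absolute
        # comparisons below the float spacing of the log-likelihood stall
        if abs(improved) < tol and float(np.max(np.abs(grad))) < 1e-9 * max(1.0, abs(ll)):
            converged = True
    if not converged:
        raise ConvergenceError(
            f"Cox-Breslow fit did not converge in {max_iter} iterations "
            f"(last log-likelihood change {improved:.3e})"
        )

    eta = Xo @ beta if pa else np.zeros(n)
    s0 = np.cumsum(np.exp(eta)[::-1])[::-1][start]
    cumhaz_mean = np.cumsum(d / s0)

    coef = np.zeros(p)
    coef[active] = beta / sd[active]
    return CoxBreslowFit(
        coef=coef,
        mean=mean,
        baseline_times=uniq_event_times,
        baseline_cumhaz_mean=cumhaz_mean,
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
    )
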