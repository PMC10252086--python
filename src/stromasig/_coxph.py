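"""Cox proportional-hazards partial-likelihood engine.

Implements Newton–Raphson maximization of the Cox partial likelihood with
Efron (default) or Breslow handling of tied event times, a vectorised
univariate screen (one independent scalar fit per gene, all genes advanced
simultaneously), and the Wald test per coefficient.

Conventions: covariates enter untransformed; hazard ratios are per unit of
the covariate (per log-expression unit for log-scale expression).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

MAX_ITER = 50
LOGLIK_TOL = 1e-9
MAX_HALVINGS = 20


@dataclass
class RiskSetIndex:
    """Precomputed tie-group structure over descending-sorted times."""

    order: np.ndarray        # permutation sorting times descending
    group_ends: np.ndarray   # exclusive end index of each tie group
    n_events: np.ndarray     # events per tie group
    events_sorted: np.ndarray


def build_risk_sets(times: np.ndarray, events: np.ndarray) -> RiskSetIndex:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.ndim != 1 or times.shape != events.shape:
        raise ValueError("times and events must be 1-D and equal length")
    if np.any(times <= 0):
        raise ValueError("survival times must be > 0")
    if not np.isin(events, (0.0, 1.0)).all():
        raise ValueError("event indicators must be 0/1")
    order = np.argsort(-times, kind="stable")
    t = times[order]
    e = events[order]
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    ends = np.r_[starts[1:], len(t)]
    d = np.add.reduceat(e, starts)
    return RiskSetIndex(order=order, group_ends=ends, n_events=d, events_sorted=e)


def _univariate_pass(beta, xs, rs, ties):
    """Log-likelihood, gradient, Hessian for per-gene scalar Cox models.

    ``xs``: covariates sorted descending by time, shape (n, g);
    ``beta``: shape (g,). Returns three (g,) arrays.
    """
    eta = xs * beta  # (n, g)
    eta = np.clip(eta, -500, 500)
    theta = np.exp(eta)
    c0 = np.cumsum(theta, axis=0)
    c1 = np.cumsum(xs * theta, axis=0)
    c2 = np.cumsum(xs * xs * theta, axis=0)
    ev = rs.events_sorted[:, None]
    ll = np.sum(ev * eta, axis=0)
    grad = np.sum(ev * xs, axis=0)
    hess = np.zeros_like(ll)
    start = 0
    for k, end in enumerate(rs.group_ends):
        d = rs.n_events[k]
        if d == 0:
            start = end
            continue
        S0 = c0[end - 1]
        S1 = c1[end - 1]
        S2 = c2[end - 1]
        if ties == "efron" and d > 1:
            sl = slice(start, end)
            w = rs.events_sorted[sl][:, None]
            D0 = np.sum(w * theta[sl], axis=0)
            D1 = np.sum(w * xs[sl] * theta[sl], axis=0)
            D2 = np.sum(w * xs[sl] * xs[sl] * theta[sl], axis=0)
            for j in range(int(d)):
                f = j / d
                den = S0 - f * D0
                num1 = S1 - f * D1
                num2 = S2 - f * D2
                ll -= np.log(den)
                r1 = num1 / den
                grad -= r1
                hess -= num2 / den - r1 * r1
        else:  # breslow, or single event
            den = S0
            r1 = S1 / den
            ll -= d * np.log(den)
            grad -= d * r1
            hess -= d * (S2 / den - r1 * r1)
        start = end
    return ll, grad, hess


def cox_univariate_screen(
    X: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    ties: str = "efron",
) -> dict[str, np.ndarray]:
    """Fit an independent univariate Cox model per column of ``X``.

    Returns arrays ``coef``, ``se``, ``p`` (two-sided Wald), ``converged``.
    Columns that fail to converge or have a degenerate information are
    flagged ``converged=False`` with NaN statistics; constant columns must
    be removed by the caller.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    rs = build_risk_sets(times, events)
    if rs.n_events.sum() < 1:
        raise ValueError("need at least one event")
    xs = X[rs.order]
    g = X.shape[1]
    beta = np.zeros(g)
    ll, grad, hess = _univariate_pass(beta, xs, rs, ties)
    active = np.ones(g, dtype=bool)
    for _ in range(MAX_ITER):
        info = -hess
        bad = info <= 1e-12
        step = np.where(bad, 0.0, grad / np.where(bad, 1.0, info))
        step = np.clip(step, -5.0, 5.0)
        step[~active] = 0.0
        cand = beta + step
        for _ in range(MAX_HALVINGS):
            ll_new, grad_new, hess_new = _univariate_pass(cand, xs, rs, ties)
            worse = active & (ll_new < ll - 1e-12)
            if not worse.any():
                break
            cand = np.where(worse, (beta + cand) / 2.0, cand)
        moved = np.abs(ll_new - ll)
        newly_done = active & (moved < LOGLIK_TOL)
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        active = active & ~newly_done
        if not active.any():
            break
    converged = (~active & np.isfinite(beta) & (-hess > 1e-12)
                 & (np.abs(beta) <= 15))
    se = np.full(g, np.nan)
    se[converged] = 1.0 / np.sqrt(-hess[converged])
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(np.isfinite(p), np.maximum(p, np.finfo(float).tiny), np.nan)
    coef = np.where(converged, beta, np.nan)
    return {"coef": coef, "se": se, "p": p, "converged": converged,
            "loglik": ll}


def _multivariate_pass(beta, Xs, rs, ties):
    """Log-likelihood, gradient (p,), Hessian (p, p) for one Cox model."""
    eta = np.clip(Xs @ beta, -500, 500)
    theta = np.exp(eta)
    c0 = np.cumsum(theta)
    c1 = np.cumsum(Xs * theta[:, None], axis=0)
    outer = Xs[:, :, None] * Xs[:, None, :] * theta[:, None, None]
    c2 = np.cumsum(outer, axis=0)
    ev = rs.events_sorted
    ll = float(np.sum(ev * eta))
    grad = np.sum(ev[:, None] * Xs, axis=0)
    p = Xs.shape[1]
    hess = np.zeros((p, p))
    start = 0
    for k, end in enumerate(rs.group_ends):
        d = rs.n_events[k]
        if d == 0:
            start = end
            continue
        S0 = c0[end - 1]
        S1 = c1[end - 1]
        S2 = c2[end - 1]
        if ties == "efron" and d > 1:
            sl = slice(start, end)
            w = rs.events_sorted[sl]
            D0 = float(np.sum(w * theta[sl]))
            D1 = np.sum(w[:, None] * Xs[sl] * theta[sl][:, None], axis=0)
            D2 = np.sum(w[:, None, None] * outer[sl], axis=0)
            for j in range(int(d)):
                f = j / d
                den = S0 - f * D0
                num1 = S1 - f * D1
                num2 = S2 - f * D2
                ll -= np.log(den)
                r1 = num1 / den
                grad -= r1
                hess -= num2 / den - np.outer(r1, r1)
        else:
            r1 = S1 / S0
            ll -= d * np.log(S0)
            grad -= d * r1
            hess -= d * (S2 / S0 - np.outer(r1, r1))
        start = end
    return ll, grad, hess


@dataclass
class CoxModel:
    """Fitted Cox model: coefficients on the log-hazard scale."""

    coef: np.ndarray
    se: np.ndarray
    p: np.ndarray
    loglik: float
    n_iter: int
    names: list[str] = field(default_factory=list)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)


def cox_newton(
    X: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    ties: str = "efron",
    names: list[str] | None = None,
) -> CoxModel:
    """Maximize the partial likelihood for a (possibly multivariate) model.

    Raises ``np.linalg.LinAlgError`` via its caller for rank-deficient
    designs (checked upstream) and ``RuntimeError`` on non-convergence or
    separation (diverging coefficients).
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    rs = build_risk_sets(times, events)
    if rs.n_events.sum() < 1:
        raise ValueError("need at least one event")
    Xs = X[rs.order]
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _multivariate_pass(beta, Xs, rs, ties)
    n_iter = 0
    for n_iter in range(1, MAX_ITER + 1):
        info = -hess
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(
                "singular information matrix (separation or collinearity)"
            ) from exc
        cand = beta + step
        for _ in range(MAX_HALVINGS):
            ll_new, grad_new, hess_new = _multivariate_pass(cand, Xs, rs, ties)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            cand = (beta + cand) / 2.0
        else:
            raise RuntimeError("step-halving failed; likelihood not improving")
        done = abs(ll_new - ll) < LOGLIK_TOL
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if done:
            break
    else:
        raise RuntimeError(f"no convergence in {MAX_ITER} Newton iterations")
    if np.any(np.abs(beta) > 15):
        raise RuntimeError(
            "diverging coefficient (likely complete separation): "
            f"max |beta| = {np.max(np.abs(beta)):.1f}"
        )
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.maximum(pvals, np.finfo(float).tiny)
    return CoxModel(coef=beta, se=se, p=pvals, loglik=ll, n_iter=n_iter,
                    names=list(names) if names is not None else [])


def cox_score_test(
    x: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    ties: str = "breslow",
) -> float:
    """Score (Rao) chi-square statistic at beta = 0 for one covariate.

    With Breslow ties on a two-group indicator this equals the two-group
    log-rank chi-square statistic.
    """
    x = np.asarray(x, dtype=float)
    rs = build_risk_sets(times, events)
    _, grad, hess = _multivariate_pass(np.zeros(1), x[rs.order, None], rs, ties)
    return float(grad[0] ** 2 / -hess[0, 0])
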