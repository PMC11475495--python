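"""Cox proportional-hazards machinery: Breslow partial likelihood and ridge fits.

The hazard model is ``h(t | x) = h0(t) exp(x beta)``.  The baseline hazard is
never estimated; coefficients (or, for the network, per-node risk scores)
enter through the negative log partial likelihood with Breslow handling of
tied event times.  Risk sets include subjects censored exactly at the event
time.  The same loss/gradient code serves both the ridge-penalized Newton fit
and the graph-network training loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, ConvergenceError


def _breslow_terms(time: np.ndarray, event: np.ndarray, eta: np.ndarray):
    """Sorted views plus per-sample risk-set denominators and d/S cumulants.

    Returns (order, w, denom_per_sample, cum_dS_per_sample, n_events) where
    arrays are in original sample order, ``denom_per_sample[k]`` is the
    Breslow denominator of sample k's event time group, and
    ``cum_dS_per_sample[k] = sum over event times t_g <= t_k of d_g / S_g``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    eta = np.asarray(eta, dtype=float)
    n = len(time)
    order = np.argsort(time, kind="stable")
    t_s = time[order]
    e_s = event[order]
    w_s = np.exp(eta[order] - eta.max())  # shift-invariant; guards overflow

    # suffix sums of w over samples with t >= t_i, constant within tied groups
    suffix = np.cumsum(w_s[::-1])[::-1]
    new_group = np.empty(n, dtype=bool)
    new_group[0] = True
    new_group[1:] = t_s[1:] != t_s[:-1]
    group_id = np.cumsum(new_group) - 1
    group_start = np.nonzero(new_group)[0]
    S_group = suffix[group_start]  # denominator per distinct time
    denom_s = S_group[group_id]

    # events per distinct time, then cumulative d/S over times <= t
    d_group = np.bincount(group_id, weights=e_s)
    with np.errstate(divide="ignore"):
        dS = np.where(d_group > 0, d_group / S_group, 0.0)
    cum_dS_s = np.cumsum(dS)[group_id]

    denom = np.empty(n)
    denom[order] = denom_s
    cum_dS = np.empty(n)
    cum_dS[order] = cum_dS_s
    w = np.exp(eta - eta.max())
    return w, denom, cum_dS, int(event.sum())


def cox_partial_likelihood_loss(
    risk: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Negative log Breslow partial likelihood, normalized by the event count.

    ``mask`` restricts both the events and the risk sets to a subset of
    samples (e.g. the training fold).  A mask with zero events returns 0 with
    a warning (degenerate fold).  The loss is invariant to adding a constant
    to all risks.
    """
    loss, _ = cox_loss_and_grad(risk, time, event, mask)
    return loss


def cox_loss_and_grad(
    risk: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    mask: np.ndarray | None = None,
):
    """Loss and its gradient with respect to every sample's risk score.

    Samples outside ``mask`` receive zero gradient and contribute nothing to
    events or risk sets.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    grad = np.zeros_like(risk)
    if mask is None:
        mask = np.ones(len(risk), dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
    t_m, e_m, r_m = time[mask], event[mask], risk[mask]
    if e_m.sum() == 0:
        warnings.warn("no events in mask; Cox loss defined as 0 (degenerate fold)")
        return 0.0, grad
    w, denom, cum_dS, n_events = _breslow_terms(t_m, e_m, r_m)
    shift = r_m.max()
    loss = -float(np.sum(e_m * ((r_m - shift) - np.log(denom)))) / n_events
    grad_m = -(e_m - w * cum_dS) / n_events
    grad[mask] = grad_m
    return loss, grad


@dataclass(frozen=True)
class RidgeCoxResult:
    """Fitted ridge Cox model: coefficients plus convergence diagnostics."""

    beta: np.ndarray
    l2_penalty: float
    n_iter: int
    converged: bool
    grad_norm: float
    log_partial_likelihood: float
    feature_means: np.ndarray
    feature_sds: np.ndarray

    def risk_score(self, X: np.ndarray) -> np.ndarray:
        """Linear predictor X beta on the fit's standardization scale."""
        Xz = (np.asarray(X, dtype=float) - self.feature_means) / self.feature_sds
        return Xz @ self.beta


def _neg_loglik_grad_hess(X, time, event, beta, want_hess=True):
    eta = X @ beta
    w, denom, cum_dS, n_events = _breslow_terms(time, event, eta)
    shift = eta.max()
    neg_ll = -float(np.sum(event * ((eta - shift) - np.log(denom))))
    grad_eta = -(event - w * cum_dS)
    grad = X.T @ grad_eta
    if not want_hess:
        return neg_ll, grad, None

    # reverse pass over distinct times accumulating weighted moments
    order = np.argsort(time, kind="stable")
    t_s, e_s, w_s, X_s = time[order], event[order], w[order], X[order]
    p = X.shape[1]
    H = np.zeros((p, p))
    Sw = 0.0
    Swx = np.zeros(p)
    Swxx = np.zeros((p, p))
    i = len(t_s) - 1
    while i >= 0:
        j = i
        while j >= 0 and t_s[j] == t_s[i]:
            j -= 1
        rows = slice(j + 1, i + 1)
        Wb = w_s[rows]
        Xb = X_s[rows]
        Sw += Wb.sum()
        Swx += Wb @ Xb
        Swxx += (Xb * Wb[:, None]).T @ Xb
        d = e_s[rows].sum()
        if d > 0:
            mu = Swx / Sw
            H += d * (Swxx / Sw - np.outer(mu, mu))
        i = j
    return neg_ll, grad, H


def ridge_cox_fit(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    l2_penalty: float = 0.1,
    tol: float = 1e-8,
    max_iter: int = 100,
    standardize: bool = True,
) -> RidgeCoxResult:
    """Maximize the Breslow partial likelihood minus (lambda/2) ||beta||^2.

    Newton iteration with step halving; converges when the infinity norm of
    the penalized gradient falls below ``tol``.  Features are z-scored by
    default; the returned model carries the standardization so that
    :meth:`RidgeCoxResult.risk_score` applies it transparently.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if X.ndim != 2 or X.shape[0] != len(time):
        raise ConfigurationError("X must be 2-d with one row per subject")
    if event.sum() < 2:
        raise ConfigurationError("ridge Cox fit needs at least 2 events")
    mu = X.mean(axis=0) if standardize else np.zeros(X.shape[1])
    sd = X.std(axis=0) if standardize else np.ones(X.shape[1])
    if np.any(sd == 0):
        bad = int(np.nonzero(sd == 0)[0][0])
        raise ConfigurationError(f"constant column {bad} after z-scoring")
    Xz = (X - mu) / sd

    beta = np.zeros(X.shape[1])
    neg_ll, grad, H = _neg_loglik_grad_hess(Xz, time, event, beta)
    obj = neg_ll + 0.5 * l2_penalty * beta @ beta
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        g_pen = grad + l2_penalty * beta
        if np.max(np.abs(g_pen)) < tol:
            break
        H_pen = H + l2_penalty * np.eye(len(beta))
        try:
            step = np.linalg.solve(H_pen, g_pen)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H_pen + 1e-8 * np.eye(len(beta)), g_pen)
        alpha = 1.0
        for _ in range(40):
            cand = beta - alpha * step
            neg_ll_c, grad_c, H_c = _neg_loglik_grad_hess(Xz, time, event, cand)
            obj_c = neg_ll_c + 0.5 * l2_penalty * cand @ cand
            if obj_c <= obj + 1e-12:
                beta, neg_ll, grad, H, obj = cand, neg_ll_c, grad_c, H_c, obj_c
                break
            alpha *= 0.5
        else:
            raise ConvergenceError("ridge Cox line search failed to decrease the objective")
    g_pen = grad + l2_penalty * beta
    grad_norm = float(np.max(np.abs(g_pen)))
    converged = grad_norm < tol
    if not converged:
        raise ConvergenceError(
            f"ridge Cox fit did not converge in {max_iter} iterations "
            f"(|grad|_inf = {grad_norm:.3e})"
        )
    return RidgeCoxResult(
        beta=beta,
        l2_penalty=l2_penalty,
        n_iter=n_iter,
        converged=converged,
        grad_norm=grad_norm,
        log_partial_likelihood=-neg_ll,
        feature_means=mu,
        feature_sds=sd,
    )


def cox_risk_score(model: RidgeCoxResult, X: np.ndarray) -> np.ndarray:
    """Convenience alias for :meth:`RidgeCoxResult.risk_score`."""
    return model.risk_score(X)
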