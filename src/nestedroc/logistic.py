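"""Maximum-likelihood logistic regression, single and batched.

The batched fitter runs Newton-Raphson on a whole stack of replicate
datasets at once (shape ``(R, n, p)``), which is what makes a 2000-replicate
Monte-Carlo cell cheap.  Replicates are frozen as soon as they converge, so
each replicate's iterate sequence is identical whether it is fitted alone
or inside a batch — the single-dataset entry point is literally a batch of
one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit

__all__ = ["LogisticFit", "fit_logistic", "fit_logistic_batch", "lrt_pvalue", "wald_pvalue"]

#: convergence: infinity-norm of the score vector after the accepted step
GRAD_TOL = 1e-8
MAX_ITER = 100
#: |beta_j| beyond this is treated as (quasi-)separation: the MLE is
#: diverging and the Wald statistic is meaningless
BETA_BOUND = 40.0


class DegenerateDataError(ValueError):
    """Outcome vector has a single class: no interior MLE exists."""


@dataclass(frozen=True)
class LogisticFit:
    """MLE of a logistic regression.

    ``cov_params`` is the inverse observed information at the optimum;
    ``converged`` is False under non-convergence or detected separation.
    """

    params: np.ndarray
    loglik: float
    cov_params: np.ndarray
    converged: bool
    n_iter: int


def _loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    # sum over observations of y*eta - log(1 + exp(eta)), stable form
    return np.sum(y * eta - np.logaddexp(0.0, eta), axis=-1)


def fit_logistic_batch(
    X: np.ndarray, y: np.ndarray, max_iter: int = MAX_ITER
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit R logistic regressions sharing a design shape.

    Parameters
    ----------
    X : ndarray, shape (R, n, p)
    y : ndarray, shape (R, n)

    Returns
    -------
    params : (R, p), loglik : (R,), cov : (R, p, p), converged : (R,) bool,
    n_iter : (R,) int
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    R, n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    ones = y.sum(axis=1)
    if np.any(ones == 0) or np.any(ones == n):
        raise DegenerateDataError("every dataset must contain both outcome classes")

    beta = np.zeros((R, p))
    eta = np.zeros((R, n))
    ll = _loglik(eta, y)
    active = np.ones(R, dtype=bool)
    failed = np.zeros(R, dtype=bool)
    n_iter = np.zeros(R, dtype=np.int64)
    eye = np.eye(p)

    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        Xa, ya, eta_a, beta_a, ll_a = X[idx], y[idx], eta[idx], beta[idx], ll[idx]

        prob = expit(eta_a)
        resid = ya - prob
        grad = np.einsum("rnp,rn->rp", Xa, resid)
        w = prob * (1.0 - prob)
        hess = np.einsum("rnp,rn,rnq->rpq", Xa, w, Xa)
        # tiny ridge guards near-singular information without moving the
        # optimum (the gradient criterion is checked on the true score)
        ridge = 1e-12 * np.trace(hess, axis1=1, axis2=2)[:, None, None] / p
        step = np.linalg.solve(hess + ridge * eye, grad[..., None])[..., 0]

        # step-halving: never accept an iterate that lowers the likelihood
        scale = np.ones(len(idx))
        beta_new = beta_a + step
        eta_new = np.einsum("rnp,rp->rn", Xa, beta_new)
        ll_new = _loglik(eta_new, ya)
        for _half in range(30):
            bad = ~(ll_new >= ll_a - 1e-13) | ~np.isfinite(ll_new)
            if not bad.any():
                break
            scale[bad] *= 0.5
            beta_new[bad] = beta_a[bad] + scale[bad, None] * step[bad]
            eta_new[bad] = np.einsum("rnp,rp->rn", Xa[bad], beta_new[bad])
            ll_new[bad] = _loglik(eta_new[bad], ya[bad])

        prob_new = expit(eta_new)
        grad_new = np.einsum("rnp,rn->rp", Xa, ya - prob_new)
        gnorm = np.abs(grad_new).max(axis=1)
        # stall guard only: Newton's quadratic rate reaches GRAD_TOL within a
        # couple of iterations of any ordinary optimum, so stopping on the
        # score keeps sum(y - p_hat) below GRAD_TOL exactly
        stalled = np.abs(ll_new - ll_a) / (np.abs(ll_a) + 1.0) < 1e-15

        beta[idx], eta[idx], ll[idx] = beta_new, eta_new, ll_new
        n_iter[idx] += 1

        diverged = (np.abs(beta_new).max(axis=1) > BETA_BOUND) | ~np.isfinite(
            ll_new
        )
        done = (gnorm < GRAD_TOL) | stalled
        failed[idx[diverged]] = True
        active[idx] = ~(done | diverged)

    failed |= active  # ran out of iterations
    converged = ~failed

    prob = expit(eta)
    w = prob * (1.0 - prob)
    hess = np.einsum("rnp,rn,rnq->rpq", X, w, X)
    cov = np.full((R, p, p), np.nan)
    ok = np.flatnonzero(converged)
    if ok.size:
        cov[ok] = np.linalg.inv(hess[ok])
    return beta, ll, cov, converged, n_iter


def fit_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = MAX_ITER) -> LogisticFit:
    """Fit one logistic regression by Newton-Raphson.

    ``X`` is the n-by-p design (include the intercept column yourself),
    ``y`` the 0/1 response.  Raises :class:`DegenerateDataError` if one
    outcome class is absent; separation or non-convergence is reported via
    ``converged=False`` rather than an exception, so callers can apply a
    redraw policy.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be a 2-d design matrix")
    params, ll, cov, conv, n_iter = fit_logistic_batch(X[None], y[None], max_iter)
    return LogisticFit(
        params=params[0],
        loglik=float(ll[0]),
        cov_params=cov[0],
        converged=bool(conv[0]),
        n_iter=int(n_iter[0]),
    )


def lrt_pvalue(loglik_restricted: float, loglik_expanded: float, tol: float = 1e-7):
    """Likelihood-ratio p-value for one extra parameter.

    G = 2 (l_expanded - l_restricted), referred to chi-square(1).  A tiny
    negative G (solver noise) is clipped to zero; a substantially negative
    one violates nesting and raises.
    """
    G = 2.0 * (np.asarray(loglik_expanded) - np.asarray(loglik_restricted))
    if np.any(G < -tol):
        raise ValueError(
            "expanded log-likelihood below restricted: models are not nested "
            "or a fit failed"
        )
    G = np.maximum(G, 0.0)
    p = np.maximum(stats.chi2.sf(G, df=1), np.finfo(float).tiny)
    return float(p) if np.ndim(p) == 0 else p


def wald_pvalue(beta_hat, se):
    """Two-sided Wald p-value, z = beta_hat / se against the standard normal."""
    beta_hat = np.asarray(beta_hat, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0) or not np.all(np.isfinite(se)):
        raise ValueError("standard error must be positive and finite")
    p = np.maximum(2.0 * stats.norm.sf(np.abs(beta_hat / se)), np.finfo(float).tiny)
    return float(p) if np.ndim(p) == 0 else p
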