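"""Robust (sandwich) standard errors for fitted regression mixtures.

The covariance is the standard A^{-1} B A^{-1} / n form, with A the average
negative Hessian of the observed-data per-observation log-likelihood and B the
average outer product of per-observation scores, both evaluated at the
estimate.  Scores are analytic (the mixture score is the responsibility-
weighted complete-data score); the Hessian is obtained by central differences
of the analytic score.  Mixing proportions enter through a multinomial-logit
chart so that differentiation happens on an unconstrained scale.
"""

from __future__ import annotations

import numpy as np

from .datagen import Dataset
from .em import MixtureParams, e_step

__all__ = ["pack_params", "unpack_params", "score_matrix", "robust_se"]


def pack_params(params: MixtureParams) -> np.ndarray:
    """Flatten to the unconstrained chart: coefficients, variance(s), logits."""
    K = params.n_classes
    rv = np.asarray(params.residual_variances, dtype=float)
    var_part = rv[:1] if params.constrained else rv
    pi = np.asarray(params.proportions, dtype=float)
    eta = np.log(pi[:-1] / pi[-1]) if K > 1 else np.empty(0)
    return np.concatenate([params.coefficients.ravel(), var_part, eta])


def unpack_params(theta: np.ndarray, template: MixtureParams) -> MixtureParams:
    """Inverse of :func:`pack_params` given a shape template."""
    K, p1 = template.coefficients.shape
    n_coef = K * p1
    coefs = theta[:n_coef].reshape(K, p1)
    n_var = 1 if template.constrained else K
    rv = theta[n_coef : n_coef + n_var]
    rv = np.full(K, rv[0]) if template.constrained else rv.copy()
    if K > 1:
        eta = theta[n_coef + n_var :]
        expo = np.exp(np.concatenate([eta, [0.0]]))
        pi = expo / expo.sum()
    else:
        pi = np.ones(1)
    return MixtureParams(
        coefficients=coefs,
        residual_variances=rv,
        proportions=pi,
        constrained=template.constrained,
    )


def score_matrix(params: MixtureParams, data: Dataset) -> np.ndarray:
    """(n, d) matrix of per-observation scores of the mixture log-likelihood.

    Uses the identity that the observed-data score equals the responsibility-
    weighted complete-data score; the proportion block is expressed in the
    multinomial-logit chart (score r_ik - pi_k).
    """
    r, _ = e_step(params, data)
    n, K = r.shape
    Xt = np.column_stack([np.ones(n), data.X])
    rv = np.asarray(params.residual_variances, dtype=float)
    resid = data.y[:, None] - Xt @ params.coefficients.T  # (n, K)

    blocks = []
    for k in range(K):
        blocks.append(r[:, k][:, None] * resid[:, k][:, None] * Xt / rv[k])
    var_scores = r * (resid**2 / (2.0 * rv[None, :] ** 2) - 1.0 / (2.0 * rv[None, :]))
    if params.constrained:
        blocks.append(var_scores.sum(axis=1, keepdims=True))
    else:
        blocks.append(var_scores)
    if K > 1:
        blocks.append(r[:, :-1] - np.asarray(params.proportions)[None, :-1])
    return np.concatenate(blocks, axis=1)


def _mean_score(theta: np.ndarray, template: MixtureParams, data: Dataset) -> np.ndarray:
    return score_matrix(unpack_params(theta, template), data).mean(axis=0)


def sandwich_covariance(params: MixtureParams, data: Dataset) -> np.ndarray | None:
    """Full sandwich covariance of the packed parameter vector, or None when
    the bread matrix is singular or the result is not finite/positive."""
    theta = pack_params(params)
    d = theta.size
    n = data.n

    S = score_matrix(params, data)
    B = (S.T @ S) / n

    # A = -mean Hessian, by central differences of the analytic mean score.
    A = np.zeros((d, d))
    for j in range(d):
        h = 6e-6 * max(abs(theta[j]), 0.1)
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        try:
            gp = _mean_score(tp, params, data)
            gm = _mean_score(tm, params, data)
        except (ValueError, FloatingPointError):
            return None
        A[:, j] = -(gp - gm) / (2.0 * h)
    A = 0.5 * (A + A.T)

    if not np.all(np.isfinite(A)) or not np.all(np.isfinite(B)):
        return None
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return None
    V = Ainv @ B @ Ainv / n
    if not np.all(np.isfinite(V)):
        return None
    return V


def robust_se(params: MixtureParams, data: Dataset) -> dict | None:
    """Sandwich standard errors for coefficients and residual variances.

    Returns ``{"coefficients": (K, p+1), "residual_variances": (K,)}`` arrays,
    or None when the covariance is not computable or any required variance is
    non-positive (the caller treats that as non-convergence).
    """
    V = sandwich_covariance(params, data)
    if V is None:
        return None
    K, p1 = params.coefficients.shape
    diag = np.diag(V)
    n_coef = K * p1
    n_var = 1 if params.constrained else K
    if np.any(diag[: n_coef + n_var] <= 0):
        return None
    se_coef = np.sqrt(diag[:n_coef]).reshape(K, p1)
    se_var = np.sqrt(diag[n_coef : n_coef + n_var])
    if params.constrained:
        se_var = np.full(K, se_var[0])
    return {"coefficients": se_coef, "residual_variances": se_var}
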