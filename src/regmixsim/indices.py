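"""Enumeration fit indices: AIC, BIC, sample-size-adjusted BIC, and entropy.

These are the indices used to choose the number of latent classes:

    AIC  = -2 ln L + 2 q
    BIC  = -2 ln L + q ln n
    ABIC = -2 ln L + q ln((n + 2) / 24)

with q free parameters and n observations.  Relative entropy summarizes
classification sharpness: 1 - sum_i sum_k (-p_ik ln p_ik) / (n ln K); it is 1
when every posterior is 0/1 and 0 when all posteriors are uniform.  For a
single class entropy is undefined and reported as None.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .em import FitResult

__all__ = ["FitIndices", "fit_indices", "relative_entropy", "information_criteria"]


@dataclass(frozen=True)
class FitIndices:
    loglik: float
    n_params: int
    n_obs: int
    aic: float
    bic: float
    abic: float
    entropy: float | None


def information_criteria(loglik: float, n_params: int, n_obs: int) -> tuple[float, float, float]:
    """(AIC, BIC, ABIC) from a log-likelihood, parameter count, and n."""
    if n_obs < 1:
        raise ValueError("n_obs must be at least 1")
    dev = -2.0 * loglik
    aic = dev + 2.0 * n_params
    bic = dev + n_params * np.log(n_obs)
    abic = dev + n_params * np.log((n_obs + 2.0) / 24.0)
    return aic, bic, abic


def relative_entropy(posteriors: np.ndarray) -> float | None:
    """Relative entropy of an (n, K) posterior matrix; None for K = 1."""
    post = np.asarray(posteriors, dtype=float)
    n, K = post.shape
    if K < 2:
        return None
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(post > 0, post * np.log(post), 0.0)
    value = 1.0 + plogp.sum() / (n * np.log(K))
    return float(min(max(value, 0.0), 1.0))


def fit_indices(fit: FitResult, n_obs: int, K: int) -> FitIndices:
    """Fit indices for a converged mixture fit."""
    if not fit.converged or fit.params is None:
        raise ValueError("fit indices require a converged fit")
    q = fit.params.n_free_parameters()
    aic, bic, abic = information_criteria(fit.loglik, q, n_obs)
    entropy = relative_entropy(fit.posteriors) if K >= 2 else None
    return FitIndices(
        loglik=fit.loglik,
        n_params=q,
        n_obs=n_obs,
        aic=aic,
        bic=bic,
        abic=abic,
        entropy=entropy,
    )
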