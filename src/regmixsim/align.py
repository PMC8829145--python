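"""Label alignment: resolve label switching against the generating classes.

Mixture class indices are arbitrary; before aggregating estimates per true
class, each fit is relabelled by the permutation that minimizes the summed
squared difference between estimated and generating (intercept, slopes)
vectors.  Ties are broken by assigning the larger first slope to Class 1,
matching the convention that Class 1 carries the larger regression weight.
"""

from __future__ import annotations

from dataclasses import replace
from itertools import permutations

import numpy as np

from .design import Condition
from .em import FitResult, MixtureParams

__all__ = ["align_labels", "align_to_reference"]


def _permute_params(params: MixtureParams, perm: tuple[int, ...]) -> MixtureParams:
    idx = list(perm)
    return replace(
        params,
        coefficients=params.coefficients[idx],
        residual_variances=np.asarray(params.residual_variances)[idx],
        proportions=np.asarray(params.proportions)[idx],
        degenerate_classes=tuple(sorted(idx.index(k) for k in params.degenerate_classes)),
    )


def align_to_reference(fit: FitResult, reference_coefficients: np.ndarray) -> FitResult:
    """Relabel a converged fit against reference (intercept, slopes) rows."""
    if not fit.converged or fit.params is None:
        return fit
    est = fit.params.coefficients
    K = est.shape[0]
    ref = np.asarray(reference_coefficients, dtype=float)

    best_perm = None
    best_cost = np.inf
    for perm in permutations(range(K)):
        cost = float(((est[list(perm)] - ref) ** 2).sum())
        if cost < best_cost - 1e-12:
            best_cost = cost
            best_perm = perm
        elif abs(cost - best_cost) <= 1e-12 and best_perm is not None:
            # tie: prefer the permutation putting the larger first slope first
            if est[perm[0], 1] > est[best_perm[0], 1]:
                best_perm = perm

    if best_perm is None or best_perm == tuple(range(K)):
        return fit
    idx = list(best_perm)
    ses = fit.standard_errors
    if ses is not None:
        ses = {
            "coefficients": ses["coefficients"][idx],
            "residual_variances": ses["residual_variances"][idx],
        }
    return FitResult(
        params=_permute_params(fit.params, best_perm),
        standard_errors=ses,
        posteriors=None if fit.posteriors is None else fit.posteriors[:, idx],
        loglik=fit.loglik,
        converged=fit.converged,
        n_iterations=fit.n_iterations,
        n_starts_converged=fit.n_starts_converged,
        loglik_paths=fit.loglik_paths,
    )


def align_labels(fit: FitResult, cond: Condition) -> FitResult:
    """Relabel a fit so estimated classes match the condition's generating classes."""
    ref = np.array([[cs.intercept, *cs.slopes] for cs in cond.class_specs])
    return align_to_reference(fit, ref)
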