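"""Maximum-likelihood estimation of mixtures of linear regressions by EM.

The model: observation i belongs to latent class k with probability pi_k, and
within class k,  y_i = b0_k + x_i' b_k + e_i  with  e_i ~ N(0, sigma_k^2).
Residual variances are either estimated freely per class or constrained equal
across classes (one pooled variance).  Estimation is multi-start EM: the
E-step computes responsibilities, the M-step solves a responsibility-weighted
least-squares problem per class, and the best converged, admissible start by
log-likelihood is returned.

Admissibility guards against the known degeneracies of normal mixtures: a
start whose solution pins a residual variance at the variance floor, or leaves
a class with fewer than two expected members, is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from .datagen import Dataset

__all__ = [
    "MixtureParams",
    "FitConfig",
    "FitResult",
    "log_likelihood",
    "e_step",
    "m_step",
    "em_fit",
    "fit_both_variants",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class MixtureParams:
    """Parameters of a K-class mixture of linear regressions.

    ``coefficients`` has shape (K, p + 1) with the intercept first; under the
    constrained model all entries of ``residual_variances`` are identical.
    """

    coefficients: np.ndarray  # (K, p + 1), column 0 = intercept
    residual_variances: np.ndarray  # (K,)
    proportions: np.ndarray  # (K,), simplex
    constrained: bool = False
    degenerate_classes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        pi = np.asarray(self.proportions, dtype=float)
        if abs(pi.sum() - 1.0) > 1e-10:
            raise ValueError("proportions must sum to 1")
        if np.any(np.asarray(self.residual_variances) <= 0):
            raise ValueError("residual variances must be positive")
        if self.constrained:
            rv = np.asarray(self.residual_variances)
            if not np.allclose(rv, rv[0], rtol=0, atol=1e-12):
                raise ValueError("constrained model requires equal residual variances")

    @property
    def n_classes(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.coefficients.shape[1] - 1

    @property
    def intercepts(self) -> np.ndarray:
        return self.coefficients[:, 0]

    @property
    def slopes(self) -> np.ndarray:
        return self.coefficients[:, 1:]

    def n_free_parameters(self) -> int:
        """Count of freely estimated parameters (enumeration penalty count)."""
        K, p = self.n_classes, self.n_predictors
        n_var = 1 if self.constrained else K
        return K * (p + 1) + n_var + (K - 1)


@dataclass(frozen=True)
class FitConfig:
    """Estimation settings for multi-start EM.

    ``n_starts`` responsibility starts draw each observation's responsibility
    row from a symmetric Dirichlet(1); ``n_hard_starts`` additional starts use
    a uniformly random hard partition refined by one M-step.  A start counts
    as converged when the relative log-likelihood change falls below ``tol``
    within ``max_iter`` iterations.
    """

    n_starts: int = 32
    n_hard_starts: int = 4
    max_iter: int = 1000
    tol: float = 1e-7
    variance_floor: float = 1e-5
    seed: int = 0
    compute_se: bool = True
    record_paths: bool = False

    def __post_init__(self) -> None:
        if self.tol <= 0 or self.variance_floor <= 0:
            raise ValueError("tol and variance_floor must be positive")


@dataclass
class FitResult:
    """Outcome of one mixture fit."""

    params: MixtureParams | None
    standard_errors: dict | None  # keys: coefficients (K, p+1), residual_variances (K,)
    posteriors: np.ndarray | None  # (n, K)
    loglik: float
    converged: bool
    n_iterations: int
    n_starts_converged: int
    loglik_paths: list[np.ndarray] = field(default_factory=list)


def _component_logdens(params: MixtureParams, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """(n, K) matrix of log pi_k + log N(y_i; mu_ik, sigma_k^2)."""
    Xt = np.column_stack([np.ones(len(y)), X])
    mu = Xt @ params.coefficients.T  # (n, K)
    rv = np.asarray(params.residual_variances, dtype=float)
    resid2 = (y[:, None] - mu) ** 2
    log_phi = -0.5 * (_LOG_2PI + np.log(rv)[None, :] + resid2 / rv[None, :])
    return np.log(params.proportions)[None, :] + log_phi


def log_likelihood(params: MixtureParams, data: Dataset) -> float:
    """Observed-data log-likelihood, computed stably in log space."""
    if data.n == 0:
        raise ValueError("empty dataset")
    return float(logsumexp(_component_logdens(params, data.X, data.y), axis=1).sum())


def e_step(params: MixtureParams, data: Dataset) -> tuple[np.ndarray, float]:
    """Responsibilities (n, K) and the current log-likelihood."""
    lse = _component_logdens(params, data.X, data.y)
    norm = logsumexp(lse, axis=1, keepdims=True)
    return np.exp(lse - norm), float(norm.sum())


def m_step(
    data: Dataset,
    responsibilities: np.ndarray,
    constrained: bool,
    variance_floor: float = 1e-5,
) -> MixtureParams:
    """Weighted-least-squares M-step.

    Per class the coefficients solve the responsibility-weighted normal
    equations; the free variance is the weighted mean squared residual, the
    constrained variance pools residuals over classes (denominator n); the
    proportions are mean responsibilities.  Classes whose effective weight
    falls below p + 2 are flagged degenerate (their parameters are not
    identifiable from the weighted data).
    """
    r = np.asarray(responsibilities, dtype=float)
    n, K = r.shape
    Xt = np.column_stack([np.ones(n), data.X])
    p1 = Xt.shape[1]

    coefs = np.zeros((K, p1))
    rvs = np.full(K, variance_floor)
    weights = r.sum(axis=0)
    degenerate: list[int] = []
    wsse = np.zeros(K)

    for k in range(K):
        if weights[k] < p1 + 1:
            degenerate.append(k)
            continue
        Xw = Xt * r[:, k][:, None]
        try:
            beta = np.linalg.solve(Xw.T @ Xt, Xw.T @ data.y)
        except np.linalg.LinAlgError:
            degenerate.append(k)
            continue
        coefs[k] = beta
        resid = data.y - Xt @ beta
        wsse[k] = float(r[:, k] @ resid**2)
        rvs[k] = max(wsse[k] / weights[k], variance_floor)

    if constrained:
        pooled = max(wsse.sum() / n, variance_floor)
        rvs = np.full(K, pooled)

    return MixtureParams(
        coefficients=coefs,
        residual_variances=rvs,
        proportions=weights / n,
        constrained=constrained,
        degenerate_classes=tuple(degenerate),
    )


def _ols_params(data: Dataset, constrained: bool, variance_floor: float) -> MixtureParams:
    """Closed-form single-class fit (used for K = 1)."""
    r = np.ones((data.n, 1))
    params = m_step(data, r, constrained=constrained, variance_floor=variance_floor)
    return replace(params, constrained=constrained)


def _run_em(
    data: Dataset,
    params: MixtureParams,
    config: FitConfig,
) -> tuple[MixtureParams, np.ndarray, float, int, bool, np.ndarray]:
    """Iterate EM from initial params; returns (params, posteriors, loglik,
    n_iter, tol_met, loglik_path)."""
    path = []
    prev = -np.inf
    r, ll = e_step(params, data)
    tol_met = False
    it = 0
    for it in range(1, config.max_iter + 1):
        params = m_step(data, r, params.constrained, config.variance_floor)
        if params.degenerate_classes:
            break
        r, ll = e_step(params, data)
        path.append(ll)
        if np.isfinite(prev) and abs(ll - prev) <= config.tol * (abs(prev) + 1e-12):
            tol_met = True
            break
        prev = ll
    return params, r, ll, it, tol_met, np.asarray(path)


def _initial_responsibilities(rng: np.random.Generator, n: int, K: int, hard: bool) -> np.ndarray:
    if hard:
        labels = rng.integers(0, K, size=n)
        r = np.zeros((n, K))
        r[np.arange(n), labels] = 1.0
        return r
    g = rng.standard_exponential((n, K))  # Dirichlet(1) rows
    return g / g.sum(axis=1, keepdims=True)


def em_fit(
    data: Dataset,
    K: int,
    constrained: bool,
    config: FitConfig | None = None,
    warm_starts: tuple[MixtureParams, ...] = (),
) -> FitResult:
    """Fit a K-class mixture of linear regressions by multi-start EM.

    Returns the best start by log-likelihood among those that met the
    convergence tolerance and the admissibility checks (no degenerate class,
    smallest mixing proportion at least 2/n, no residual variance pinned at
    the floor, and — when standard errors are requested — a computable
    sandwich covariance).  ``converged`` is False when no start qualifies;
    degenerate data never raises.

    ``warm_starts`` adds EM runs initialized at the given parameter values to
    the candidate pool (used to warm-start the free model from the nested
    constrained solution, which guarantees the free log-likelihood dominates).
    """
    from .sandwich import robust_se  # local import to avoid a cycle

    config = config or FitConfig()
    if data.n == 0:
        raise ValueError("empty dataset")
    p = data.n_predictors
    if K < 1 or data.n <= K * (p + 2):
        raise ValueError("K must satisfy 1 <= K and n > K (p + 2)")

    if K == 1:
        params = _ols_params(data, constrained, config.variance_floor)
        ll = log_likelihood(params, data)
        result = FitResult(
            params=params,
            standard_errors=None,
            posteriors=np.ones((data.n, 1)),
            loglik=ll,
            converged=True,
            n_iterations=1,
            n_starts_converged=1,
        )
        if config.compute_se:
            ses = robust_se(params, data)
            if ses is None:
                result.converged = False
            result.standard_errors = ses
        return result

    rng = np.random.default_rng(config.seed)
    best = None
    n_starts_converged = 0
    paths: list[np.ndarray] = []
    min_prop = 2.0 / data.n

    inits: list[MixtureParams] = []
    for s in range(config.n_starts + config.n_hard_starts):
        hard = s >= config.n_starts
        r0 = _initial_responsibilities(rng, data.n, K, hard)
        inits.append(m_step(data, r0, constrained, config.variance_floor))
    for w in warm_starts:
        inits.append(replace(w, constrained=constrained, degenerate_classes=()))

    for params0 in inits:
        if params0.degenerate_classes:
            continue
        params, r, ll, n_iter, tol_met, path = _run_em(data, params0, config)
        if config.record_paths:
            paths.append(path)
        if not tol_met or params.degenerate_classes:
            continue
        admissible = (
            params.proportions.min() >= min_prop
            and np.asarray(params.residual_variances).min() > config.variance_floor
        )
        if not admissible:
            continue
        n_starts_converged += 1
        if best is None or ll > best[2]:
            best = (params, r, ll, n_iter)

    if best is None:
        return FitResult(
            params=None,
            standard_errors=None,
            posteriors=None,
            loglik=-np.inf,
            converged=False,
            n_iterations=0,
            n_starts_converged=0,
            loglik_paths=paths,
        )

    params, r, ll, n_iter = best
    result = FitResult(
        params=params,
        standard_errors=None,
        posteriors=r,
        loglik=ll,
        converged=True,
        n_iterations=n_iter,
        n_starts_converged=n_starts_converged,
        loglik_paths=paths,
    )
    if config.compute_se:
        ses = robust_se(params, data)
        if ses is None:
            result.converged = False
        result.standard_errors = ses
    return result


def fit_both_variants(
    data: Dataset,
    K: int = 2,
    config_free: FitConfig | None = None,
    config_constrained: FitConfig | None = None,
) -> dict:
    """Fit the free and constrained variants to the same data.

    The constrained model is fitted first and its solution is added to the
    free model's start pool.  Because the free likelihood evaluated at the
    constrained maximizer equals the constrained maximum and EM is monotone,
    the free fit's log-likelihood then always dominates the constrained one
    (the nesting of the two models).

    Returns ``{"free": FitResult, "constrained": FitResult}``.
    """
    cons = em_fit(data, K, constrained=True, config=config_constrained)
    warm = (cons.params,) if (cons.converged and cons.params is not None) else ()
    free = em_fit(data, K, constrained=False, config=config_free, warm_starts=warm)
    return {"free": free, "constrained": cons}
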