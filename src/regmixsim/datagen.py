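"""Synthetic data generation for two-class regression mixtures.

Each observation is assigned a latent class by an i.i.d. draw with the
condition's mixing proportions; predictors are multivariate standard normal
with the condition's inter-predictor correlation; the outcome follows the
class-specific linear model with normal residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import Condition

__all__ = ["Dataset", "generate_dataset", "dataset_to_csv", "dataset_from_csv"]


@dataclass(frozen=True)
class Dataset:
    """One simulated replication: predictors, outcome, and true class labels."""

    X: np.ndarray  # (n, p)
    y: np.ndarray  # (n,)
    true_class: np.ndarray  # (n,) integer labels in {1, 2}
    seed: int

    def __post_init__(self) -> None:
        if not (self.X.shape[0] == self.y.shape[0] == self.true_class.shape[0]):
            raise ValueError("X, y and true_class must have equal row counts")
        if not np.isin(self.true_class, (1, 2)).all():
            raise ValueError("true_class labels must be 1 or 2")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.X.shape[1]


def generate_dataset(cond: Condition, seed: int) -> Dataset:
    """Draw one replication from the condition's data-generating process.

    The draw order (labels, predictors, residuals) is fixed, so identical
    ``(cond, seed)`` pairs reproduce bit-identical datasets.
    """
    if not isinstance(seed, (int, np.integer)) or seed < 0:
        raise ValueError("seed must be a non-negative integer")
    if cond.n < 1:
        raise ValueError("condition sample size must be positive")

    rng = np.random.default_rng(int(seed))
    n, p = cond.n, cond.n_predictors
    pi1 = cond.class_specs[0].proportion

    labels = np.where(rng.random(n) < pi1, 1, 2).astype(np.int64)

    rho = cond.predictor_correlation
    Z = rng.standard_normal((n, p))
    if p > 1 and rho != 0.0:
        corr = np.full((p, p), rho)
        np.fill_diagonal(corr, 1.0)
        X = Z @ np.linalg.cholesky(corr).T
    else:
        X = Z

    eps = rng.standard_normal(n)
    y = np.empty(n)
    for k, cs in enumerate(cond.class_specs, start=1):
        mask = labels == k
        y[mask] = (
            cs.intercept
            + X[mask] @ np.asarray(cs.slopes)
            + np.sqrt(cs.residual_variance) * eps[mask]
        )
    return Dataset(X=X, y=y, true_class=labels, seed=int(seed))


def dataset_to_csv(data: Dataset, path) -> None:
    """Write a dataset as CSV with columns x1[,x2],y,true_class."""
    cols = {f"x{j + 1}": data.X[:, j] for j in range(data.n_predictors)}
    cols["y"] = data.y
    cols["true_class"] = data.true_class
    pd.DataFrame(cols).to_csv(path, index=False)


def dataset_from_csv(path, seed: int = 0) -> Dataset:
    """Read a dataset written by :func:`dataset_to_csv`.

    A ``true_class`` column is optional on input (real data has none); when
    absent all labels are set to 1.
    """
    df = pd.read_csv(path)
    xcols = sorted(c for c in df.columns if c.startswith("x"))
    if not xcols or "y" not in df.columns:
        raise ValueError("CSV must contain x1[,x2,...] and y columns")
    X = df[xcols].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    if "true_class" in df.columns:
        labels = df["true_class"].to_numpy(dtype=np.int64)
    else:
        labels = np.ones(len(df), dtype=np.int64)
    return Dataset(X=X, y=y, true_class=labels, seed=seed)
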