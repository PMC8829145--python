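"""Per-condition accuracy criteria for the Monte Carlo study.

Replication-level fits are aggregated into the criteria used to judge
estimation quality: convergence rate, mean estimate, relative bias
((mean - true)/true, undefined for a true value of 0), mean squared error,
and coverage of the normal-based 95% confidence interval.  Relative bias with
absolute value above 0.1 is flagged substantial; coverage below 0.9 is flagged
unsatisfactory.  All aggregation uses converged replications only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import Condition
from .em import FitResult

__all__ = [
    "BIAS_CUTOFF",
    "COVERAGE_THRESHOLD",
    "Z_95",
    "ReplicationRecord",
    "ParamSummary",
    "ConditionSummary",
    "parameter_names",
    "true_parameter_values",
    "record_from_fit",
    "relative_bias",
    "mse",
    "ci_coverage",
    "convergence_rate",
    "summarize_condition",
    "summaries_to_tidy",
    "summaries_to_wide",
]

BIAS_CUTOFF = 0.1
COVERAGE_THRESHOLD = 0.9
Z_95 = 1.959963984540054  # normal 97.5% quantile


@dataclass(frozen=True)
class ReplicationRecord:
    """One fitted replication of one model variant, after label alignment."""

    condition_id: str
    replication: int
    variant: str  # "free" | "constrained"
    converged: bool
    estimates: dict = field(default_factory=dict)  # parameter name -> estimate
    ses: dict = field(default_factory=dict)  # parameter name -> standard error
    loglik: float = float("nan")
    n_iterations: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("free", "constrained"):
            raise ValueError("variant must be 'free' or 'constrained'")
        if self.converged and not self.estimates:
            raise ValueError("converged records must carry estimates")
        if not self.converged and self.estimates:
            raise ValueError("non-converged records must not carry estimates")


@dataclass(frozen=True)
class ParamSummary:
    parameter: str
    true_value: float
    mean_estimate: float
    relative_bias: float | None  # None when true value is 0
    substantial_bias: bool | None
    mse: float
    rmse: float
    coverage: float
    coverage_unsatisfactory: bool


@dataclass(frozen=True)
class ConditionSummary:
    condition_id: str
    variant: str
    n_replications: int
    n_converged: int
    convergence_rate: float
    parameters: dict  # parameter name -> ParamSummary (empty when nothing converged)


def parameter_names(n_predictors: int, n_classes: int = 2) -> list[str]:
    """Reported parameter names, in a stable order."""
    names = []
    for k in range(1, n_classes + 1):
        for j in range(1, n_predictors + 1):
            names.append(f"class{k}_slope_x{j}")
        names.append(f"class{k}_intercept")
        names.append(f"class{k}_resid_var")
    return names


def true_parameter_values(cond: Condition) -> dict:
    """Generating values keyed by parameter name."""
    out = {}
    for k, cs in enumerate(cond.class_specs, start=1):
        for j, b in enumerate(cs.slopes, start=1):
            out[f"class{k}_slope_x{j}"] = float(b)
        out[f"class{k}_intercept"] = float(cs.intercept)
        out[f"class{k}_resid_var"] = float(cs.residual_variance)
    return out


def record_from_fit(
    fit: FitResult,
    condition_id: str,
    replication: int,
    variant: str,
) -> ReplicationRecord:
    """Flatten an aligned fit into a replication record."""
    if not fit.converged or fit.params is None or fit.standard_errors is None:
        return ReplicationRecord(condition_id, replication, variant, converged=False)
    est, se = {}, {}
    coefs = fit.params.coefficients
    se_c = fit.standard_errors["coefficients"]
    for k in range(coefs.shape[0]):
        for j in range(1, coefs.shape[1]):
            est[f"class{k + 1}_slope_x{j}"] = float(coefs[k, j])
            se[f"class{k + 1}_slope_x{j}"] = float(se_c[k, j])
        est[f"class{k + 1}_intercept"] = float(coefs[k, 0])
        se[f"class{k + 1}_intercept"] = float(se_c[k, 0])
        est[f"class{k + 1}_resid_var"] = float(fit.params.residual_variances[k])
        se[f"class{k + 1}_resid_var"] = float(fit.standard_errors["residual_variances"][k])
    return ReplicationRecord(
        condition_id,
        replication,
        variant,
        converged=True,
        estimates=est,
        ses=se,
        loglik=fit.loglik,
        n_iterations=fit.n_iterations,
    )


def relative_bias(estimates, true_value: float):
    """(mean - true)/true, or None when the true value is 0 (undefined)."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("empty estimate vector")
    if true_value == 0:
        return None
    return float((est.mean() - true_value) / true_value)


def mse(estimates, true_value: float) -> float:
    """Mean squared error of the estimates around the true value."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("empty estimate vector")
    return float(np.mean((est - true_value) ** 2))


def ci_coverage(estimates, ses, true_value: float, z: float = Z_95) -> float:
    """Proportion of normal-based CIs (estimate +/- z*SE) covering the truth."""
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.size == 0 or est.shape != se.shape:
        raise ValueError("estimates and SEs must be matched, non-empty vectors")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    covered = np.abs(est - true_value) <= z * se
    return float(covered.mean())


def convergence_rate(records: list[ReplicationRecord]) -> float:
    """Fraction of converged replications (records share condition/variant)."""
    if not records:
        raise ValueError("empty record list")
    ids = {(r.condition_id, r.variant) for r in records}
    if len(ids) > 1:
        raise ValueError("records must share one condition and variant")
    return sum(r.converged for r in records) / len(records)


def _summarize_variant(
    records: list[ReplicationRecord], cond: Condition, variant: str
) -> ConditionSummary:
    recs = [r for r in records if r.variant == variant]
    if not recs:
        raise ValueError(f"no records for variant {variant!r}")
    conv = [r for r in recs if r.converged]
    rate = len(conv) / len(recs)
    params: dict[str, ParamSummary] = {}
    if conv:
        truths = true_parameter_values(cond)
        for name in parameter_names(cond.n_predictors):
            est = [r.estimates[name] for r in conv]
            ses = [r.ses[name] for r in conv]
            true = truths[name]
            rb = relative_bias(est, true)
            m = mse(est, true)
            cov = ci_coverage(est, ses, true)
            params[name] = ParamSummary(
                parameter=name,
                true_value=true,
                mean_estimate=float(np.mean(est)),
                relative_bias=rb,
                substantial_bias=None if rb is None else abs(rb) > BIAS_CUTOFF,
                mse=m,
                rmse=float(np.sqrt(m)),
                coverage=cov,
                coverage_unsatisfactory=cov < COVERAGE_THRESHOLD,
            )
    return ConditionSummary(
        condition_id=cond.condition_id,
        variant=variant,
        n_replications=len(recs),
        n_converged=len(conv),
        convergence_rate=rate,
        parameters=params,
    )


def summarize_condition(
    records: list[ReplicationRecord], cond: Condition
) -> list[ConditionSummary]:
    """One summary per model variant present in the records."""
    variants = sorted({r.variant for r in records})
    if not variants:
        raise ValueError("no records to summarize")
    return [_summarize_variant(records, cond, v) for v in variants]


def summaries_to_tidy(summaries: list[ConditionSummary]) -> pd.DataFrame:
    """Tidy table: one row per condition x variant x parameter."""
    rows = []
    for s in summaries:
        if not s.parameters:
            rows.append(
                {
                    "condition_id": s.condition_id,
                    "variant": s.variant,
                    "parameter": None,
                    "true_value": np.nan,
                    "mean_estimate": np.nan,
                    "relative_bias": np.nan,
                    "mse": np.nan,
                    "rmse": np.nan,
                    "coverage": np.nan,
                    "n_converged": s.n_converged,
                    "convergence_rate": s.convergence_rate,
                }
            )
            continue
        for name, ps in s.parameters.items():
            rows.append(
                {
                    "condition_id": s.condition_id,
                    "variant": s.variant,
                    "parameter": name,
                    "true_value": ps.true_value,
                    "mean_estimate": ps.mean_estimate,
                    "relative_bias": np.nan if ps.relative_bias is None else ps.relative_bias,
                    "mse": ps.mse,
                    "rmse": ps.rmse,
                    "coverage": ps.coverage,
                    "n_converged": s.n_converged,
                    "convergence_rate": s.convergence_rate,
                }
            )
    return pd.DataFrame(rows)


def summaries_to_wide(summaries: list[ConditionSummary]) -> pd.DataFrame:
    """Wide mean-estimate table: rows = parameter, columns = variant."""
    tidy = summaries_to_tidy(summaries)
    tidy = tidy.dropna(subset=["parameter"])
    return tidy.pivot_table(
        index=["condition_id", "parameter", "true_value"],
        columns="variant",
        values="mean_estimate",
    ).reset_index()
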