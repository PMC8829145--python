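"""Study orchestration: run the full factorial simulation, or any subset.

Every (condition, replication) cell derives its own data and estimation seeds
from the master seed by hashing, so any cell is regenerable in isolation and
results are byte-identical regardless of worker count or execution order.
Outputs are ``replications.csv`` (per-replication estimates, SEs and
convergence), ``summaries.csv`` (tidy accuracy metrics), and ``manifest.json``
(config, design counts, and seeds).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from . import __version__
from .align import align_labels
from .datagen import generate_dataset
from .design import Condition, enumerate_conditions
from .em import FitConfig, em_fit
from .evaluate import (
    ReplicationRecord,
    parameter_names,
    record_from_fit,
    summaries_to_tidy,
    summarize_condition,
)

__all__ = ["StudyConfig", "VARIANTS", "derive_seed", "fit_replication", "run_study", "resume_study"]

VARIANTS = ("free", "constrained")

# fixed replications.csv schema: estimates/SEs for up to two predictors,
# slope_x2 left empty in single-predictor families
_ALL_PARAMS = parameter_names(n_predictors=2)
_META_COLS = ["condition_id", "replication", "variant", "converged", "loglik", "n_iterations"]
_CSV_COLUMNS = _META_COLS + [f"est_{p}" for p in _ALL_PARAMS] + [f"se_{p}" for p in _ALL_PARAMS]
_FLOAT_FORMAT = "%.12g"


@dataclass(frozen=True)
class StudyConfig:
    """Settings for one study run."""

    master_seed: int = 0
    n_replications: int = 100
    n_starts: int = 32
    n_hard_starts: int = 4
    max_iter: int = 1000
    loglik_tolerance: float = 1e-7
    variance_floor: float = 1e-5
    condition_filter: dict = field(default_factory=dict)
    output_dir: str = "results"
    workers: int = 1

    def __post_init__(self) -> None:
        if self.n_replications < 1:
            raise ValueError("n_replications must be at least 1")
        if self.loglik_tolerance <= 0 or self.variance_floor <= 0:
            raise ValueError("tolerance and variance floor must be positive")

    def fit_config(self, seed: int) -> FitConfig:
        return FitConfig(
            n_starts=self.n_starts,
            n_hard_starts=self.n_hard_starts,
            max_iter=self.max_iter,
            tol=self.loglik_tolerance,
            variance_floor=self.variance_floor,
            seed=seed,
        )

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def derive_seed(master_seed: int, condition_id: str, replication: int, purpose: str) -> int:
    """Stable per-cell seed below 2**31, independent of execution order."""
    key = f"{master_seed}|{condition_id}|{replication}|{purpose}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def select_conditions(config: StudyConfig) -> list[Condition]:
    """Apply the config's condition filter to the full design."""
    conds = enumerate_conditions(n_replications=config.n_replications)
    f = config.condition_filter
    if not f:
        return conds
    out = []
    for c in conds:
        if "condition_id" in f and c.condition_id not in _aslist(f["condition_id"]):
            continue
        if "family" in f and c.model_family not in _aslist(f["family"]):
            continue
        if "separation" in f and c.separation not in _aslist(f["separation"]):
            continue
        if "n" in f and c.n not in [int(v) for v in _aslist(f["n"])]:
            continue
        if "proportion" in f:
            tag = "balanced" if abs(c.class_specs[0].proportion - 0.5) < 1e-12 else "unbalanced"
            if tag not in _aslist(f["proportion"]):
                continue
        out.append(c)
    return out


def _aslist(v):
    return v if isinstance(v, (list, tuple)) else [v]


def fit_replication(
    cond: Condition,
    replication: int,
    master_seed: int,
    config: StudyConfig,
    variants: tuple[str, ...] = VARIANTS,
) -> list[ReplicationRecord]:
    """Generate one replication and fit the requested model variants."""
    data_seed = derive_seed(master_seed, cond.condition_id, replication, "data")
    data = generate_dataset(cond, data_seed)
    # constrained first: its solution warm-starts the free fit so the free
    # log-likelihood always dominates (model nesting)
    warm = ()
    records = {}
    for variant in ("constrained", "free"):
        if variant not in variants:
            continue
        fit_seed = derive_seed(master_seed, cond.condition_id, replication, f"fit-{variant}")
        try:
            fit = em_fit(
                data,
                K=2,
                constrained=(variant == "constrained"),
                config=config.fit_config(fit_seed),
                warm_starts=warm if variant == "free" else (),
            )
            if variant == "constrained" and fit.converged and fit.params is not None:
                warm = (fit.params,)
            fit = align_labels(fit, cond)
            rec = record_from_fit(fit, cond.condition_id, replication, variant)
        except Exception:  # a failed replication is recorded, never fatal
            rec = ReplicationRecord(cond.condition_id, replication, variant, converged=False)
        records[variant] = rec
    return [records[v] for v in variants if v in records]


def _records_to_frame(records: list[ReplicationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "condition_id": r.condition_id,
            "replication": r.replication,
            "variant": r.variant,
            "converged": int(r.converged),
            "loglik": r.loglik,
            "n_iterations": r.n_iterations,
        }
        for p in _ALL_PARAMS:
            row[f"est_{p}"] = r.estimates.get(p, np.nan)
            row[f"se_{p}"] = r.ses.get(p, np.nan)
        rows.append(row)
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    return df.sort_values(["condition_id", "replication", "variant"]).reset_index(drop=True)


def _frame_to_records(df: pd.DataFrame) -> list[ReplicationRecord]:
    records = []
    for _, row in df.iterrows():
        converged = bool(row["converged"])
        est, ses = {}, {}
        if converged:
            for p in _ALL_PARAMS:
                v = row[f"est_{p}"]
                if pd.notna(v):
                    est[p] = float(v)
                    ses[p] = float(row[f"se_{p}"])
        records.append(
            ReplicationRecord(
                condition_id=row["condition_id"],
                replication=int(row["replication"]),
                variant=row["variant"],
                converged=converged,
                estimates=est,
                ses=ses,
                loglik=float(row["loglik"]) if pd.notna(row["loglik"]) else float("nan"),
                n_iterations=int(row["n_iterations"]),
            )
        )
    return records


def _summarize_all(df: pd.DataFrame, conditions: list[Condition]) -> pd.DataFrame:
    by_id = {c.condition_id: c for c in conditions}
    summaries = []
    for cid, group in df.groupby("condition_id", sort=True):
        summaries.extend(summarize_condition(_frame_to_records(group), by_id[cid]))
    tidy = summaries_to_tidy(summaries)
    return tidy.sort_values(["condition_id", "variant", "parameter"]).reset_index(drop=True)


def _write_outputs(
    out: Path, config: StudyConfig, conditions: list[Condition], df: pd.DataFrame
) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "replications.csv", index=False, float_format=_FLOAT_FORMAT)
    # summarize from the CSV as written, so summaries depend only on persisted
    # values and a resumed run reproduces a fresh run byte-for-byte
    df = pd.read_csv(out / "replications.csv")
    tidy = _summarize_all(df, conditions)
    tidy.to_csv(out / "summaries.csv", index=False, float_format=_FLOAT_FORMAT)
    # wide companion table: mean estimates, one column per variant
    wide = (
        tidy.dropna(subset=["parameter"])
        .pivot_table(
            index=["condition_id", "parameter", "true_value"],
            columns="variant",
            values="mean_estimate",
        )
        .reset_index()
    )
    wide.to_csv(out / "summaries_wide.csv", index=False, float_format=_FLOAT_FORMAT)
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "n_conditions": len(conditions),
        "n_datasets": len(conditions) * config.n_replications,
        "condition_ids": [c.condition_id for c in conditions],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"replications": df, "summaries": tidy, "manifest": manifest}


def run_study(config: StudyConfig) -> dict:
    """Run every selected (condition, replication) cell and write results.

    Returns ``{"replications": DataFrame, "summaries": DataFrame, "manifest": dict}``.
    Deterministic given ``master_seed``, including under parallel execution.
    """
    conditions = select_conditions(config)
    if not conditions:
        raise ValueError("condition filter selects no conditions")
    tasks = [(c, rep) for c in conditions for rep in range(config.n_replications)]
    results = Parallel(n_jobs=config.workers)(
        delayed(fit_replication)(c, rep, config.master_seed, config) for c, rep in tasks
    )
    records = [r for batch in results for r in batch]
    df = _records_to_frame(records)
    return _write_outputs(Path(config.output_dir), config, conditions, df)


def resume_study(config: StudyConfig, output_dir=None) -> dict:
    """Complete a partial run, computing only missing cells.

    The prior output's manifest must match the config (master seed,
    replication count, condition set); a missing or inconsistent manifest
    aborts.  The completed outputs equal a fresh full run with the same
    master seed.
    """
    out = Path(output_dir if output_dir is not None else config.output_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest at {manifest_path}")
    try:
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        prior = manifest["config"]
    except (json.JSONDecodeError, KeyError, TypeError) as err:
        raise ValueError(f"corrupted manifest at {manifest_path}: {err}") from err

    conditions = select_conditions(config)
    for key in ("master_seed", "n_replications", "condition_filter"):
        if prior.get(key) != getattr(config, key):
            raise ValueError(
                f"manifest/config mismatch on {key!r}: {prior.get(key)!r} vs "
                f"{getattr(config, key)!r}"
            )

    rep_path = out / "replications.csv"
    have = pd.read_csv(rep_path) if rep_path.exists() else pd.DataFrame(columns=_CSV_COLUMNS)
    done = {
        (row.condition_id, int(row.replication), row.variant)
        for row in have.itertuples(index=False)
    }
    missing = [
        (c, rep)
        for c in conditions
        for rep in range(config.n_replications)
        if any((c.condition_id, rep, v) not in done for v in VARIANTS)
    ]
    if missing:
        results = Parallel(n_jobs=config.workers)(
            delayed(fit_replication)(c, rep, config.master_seed, config) for c, rep in missing
        )
        new = _records_to_frame([r for batch in results for r in batch])
        redone = {(c.condition_id, rep) for c, rep in missing}
        keep = have[
            ~have.apply(lambda r: (r["condition_id"], int(r["replication"])) in redone, axis=1)
        ] if len(have) else have
        df = pd.concat([keep, new], ignore_index=True)
        df = df.sort_values(["condition_id", "replication", "variant"]).reset_index(drop=True)
    else:
        df = have
    return _write_outputs(out, config, conditions, df)
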