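"""Monte Carlo driver: simulate -> fit -> probe, per condition and grid-wide.

Each replication draws a fresh trial from the generative model, fits the
three-level REML model, and applies the slopes difference test.  Per
condition the engine aggregates

* power — the share of significant replications.  The default
  denominator counts non-converged or failed replications as
  non-significant out of all replications ("all"); a converged-only
  power is always reported alongside, because the two definitions can
  differ when fits fail;
* convergence and singularity rates (denominator: all replications;
  singular fits still yield a test and count toward power);
* mean fixed-effect estimates and their relative bias across converged
  fits.

Reproducibility: the random stream of replication r of condition c under
master seed s is ``SeedSequence(entropy=(s, c, r))``, so results are
independent of execution order and worker count.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .design import (
    FIXED_EFFECT_NAMES,
    DesignCondition,
    DEFAULT_BASE_PARAMS,
    PopulationParams,
    resolve_params,
    wave_times,
)
from .lmm import EstimationError, FitOptions, fit_arrays
from .probe import slopes_difference_test
from .simulate import simulate_dataset

__all__ = [
    "RunConfig",
    "ConditionSummary",
    "CheckpointError",
    "seed_stream",
    "run_condition",
    "run_grid",
]

class CheckpointError(RuntimeError):
    """A results checkpoint that cannot be resumed safely."""


@dataclass(frozen=True)
class RunConfig:
    """Everything a Monte Carlo run needs besides the conditions."""

    n_reps: int = 1000
    master_seed: int = 20230
    alpha: float = 0.05
    df_policy: str = "normal"  # or "residual"
    probe_mode: str = "as_printed"  # or "delta_method"
    denominator_policy: str = "all"  # or "converged"
    aptitude_value: float = -1.0
    n_jobs: int = 1
    audit: bool = False  # keep per-replication p-values and flags

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.df_policy not in ("normal", "residual"):
            raise ValueError("df_policy must be 'normal' or 'residual'")
        if self.probe_mode not in ("as_printed", "delta_method"):
            raise ValueError("probe_mode must be 'as_printed' or 'delta_method'")
        if self.denominator_policy not in ("all", "converged"):
            raise ValueError("denominator_policy must be 'all' or 'converged'")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ConditionSummary:
    """Aggregated Monte Carlo outcomes for one design condition."""

    condition: DesignCondition
    n_reps: int
    power: float
    power_converged: float
    convergence_rate: float
    singularity_rate: float
    mean_estimates: dict
    relative_bias: dict
    n_failed: int
    audit: pd.DataFrame | None = None

    def to_row(self) -> dict:
        row = {"condition_index": self.condition.condition_index}
        row.update(self.condition.factor_dict())
        row.update(
            {
                "n_reps": self.n_reps,
                "power": self.power,
                "power_converged": self.power_converged,
                "convergence_rate": self.convergence_rate,
                "singularity_rate": self.singularity_rate,
                "n_failed": self.n_failed,
            }
        )
        for k, v in self.mean_estimates.items():
            row[f"mean_{k}"] = v
        for k, v in self.relative_bias.items():
            row[f"bias_{k}"] = v
        return row


def seed_stream(
    master_seed: int, condition_index: int, replication_index: int
) -> np.random.Generator:
    """Independent, reproducible stream for one replication.

    Counter-based derivation: the three indices form the entropy tuple of
    a ``SeedSequence``, so distinct (condition, replication) pairs give
    statistically independent streams under any execution order.
    """
    if min(master_seed, condition_index, replication_index) < 0:
        raise ValueError("seed components must be non-negative")
    return np.random.default_rng(
        np.random.SeedSequence(
            entropy=(int(master_seed), int(condition_index), int(replication_index))
        )
    )


def _default_fit_probe(dataset, times, T, m, J, config: RunConfig, fit_options):
    """One replication's fit + probe; returns (p, converged, singular, beta)."""
    fit = fit_arrays(
        dataset.y,
        times,
        dataset.treatment[::T].astype(float),
        dataset.aptitude[::T],
        T,
        m,
        J,
        fit_options,
    )
    if not fit.converged:
        return np.nan, False, fit.singular, None
    pr = slopes_difference_test(
        fit,
        aptitude_value=config.aptitude_value,
        mode=config.probe_mode,
        df_policy=config.df_policy,
    )
    return pr.p, True, fit.singular, fit.beta_hat


def run_condition(
    condition: DesignCondition,
    config: RunConfig,
    base_params: PopulationParams = DEFAULT_BASE_PARAMS,
    fit_probe: Callable | None = None,
    fit_options: FitOptions | None = None,
) -> ConditionSummary:
    """Replicate simulate -> fit -> slopes-difference-test for one condition.

    A replication whose fit raises is recorded as failed (non-converged,
    non-significant under the "all" policy); it never aborts the
    condition.  ``fit_probe`` may be injected for testing; it receives
    the dataset and must return ``(p_value, converged, singular, beta)``.
    """
    params = resolve_params(condition, base_params)
    T, m, J = condition.n_waves, condition.class_size, condition.n_classrooms
    times = wave_times(T)
    truth = params.fixed_effects

    n_sig = n_conv = n_sing = n_failed = 0
    beta_sum = np.zeros(8)
    n_beta = 0
    audit_rows = [] if config.audit else None

    for r in range(config.n_reps):
        rng = seed_stream(config.master_seed, condition.condition_index, r)
        dataset = simulate_dataset(condition, params, rng)
        try:
            if fit_probe is not None:
                p, converged, singular, beta = fit_probe(dataset)
            else:
                p, converged, singular, beta = _default_fit_probe(
                    dataset, times, T, m, J, config, fit_options
                )
            failed = False
        except EstimationError:
            p, converged, singular, beta = np.nan, False, False, None
            failed = True
        n_failed += failed
        n_conv += converged
        n_sing += singular
        significant = bool(converged and np.isfinite(p) and p < config.alpha)
        n_sig += significant
        if converged and beta is not None:
            beta_sum += beta
            n_beta += 1
        if audit_rows is not None:
            audit_rows.append(
                {
                    "replication": r,
                    "p": p,
                    "significant": significant,
                    "converged": bool(converged),
                    "singular": bool(singular),
                    "failed": failed,
                }
            )

    power_all = n_sig / config.n_reps
    power_conv = n_sig / n_conv if n_conv else float("nan")
    mean_beta = beta_sum / n_beta if n_beta else np.full(8, np.nan)
    mean_estimates = dict(zip(FIXED_EFFECT_NAMES, mean_beta.tolist()))
    relative_bias = {
        name: (mean_beta[i] - truth[i]) / truth[i]
        for i, name in enumerate(FIXED_EFFECT_NAMES)
        if truth[i] != 0
    }
    return ConditionSummary(
        condition=condition,
        n_reps=config.n_reps,
        power=power_all if config.denominator_policy == "all" else power_conv,
        power_converged=power_conv,
        convergence_rate=n_conv / config.n_reps,
        singularity_rate=n_sing / config.n_reps,
        mean_estimates=mean_estimates,
        relative_bias=relative_bias,
        n_failed=n_failed,
        audit=pd.DataFrame(audit_rows) if audit_rows is not None else None,
    )


def _grid_meta(config: RunConfig, conditions: Sequence[DesignCondition]) -> dict:
    cond_digest = hashlib.sha256(
        json.dumps([c.factor_dict() for c in conditions], sort_keys=True).encode()
    ).hexdigest()[:16]
    return {
        "config": asdict(config),
        "config_digest": config.digest(),
        "conditions_digest": cond_digest,
        "master_seed": config.master_seed,
        "n_conditions": len(conditions),
    }


def run_grid(
    conditions: Sequence[DesignCondition],
    config: RunConfig,
    base_params: PopulationParams = DEFAULT_BASE_PARAMS,
    checkpoint_dir: str | Path | None = None,
    fit_options: FitOptions | None = None,
    progress: Callable[[str], None] | None = None,
) -> pd.DataFrame:
    """Run every condition; one summary row per condition, in grid order.

    With ``checkpoint_dir`` the table is flushed after each batch of
    conditions and an interrupted run resumes from the completed rows
    (refusing to resume when the stored config/conditions digest does
    not match).  Parallel execution (``config.n_jobs > 1``) gives
    bitwise-identical results to a serial run because every replication
    seeds itself from (master seed, condition, replication).
    """
    meta = _grid_meta(config, conditions)
    done: dict[int, dict] = {}
    ckpt_csv = meta_path = None
    if checkpoint_dir is not None:
        checkpoint_dir = Path(checkpoint_dir)
        checkpoint_dir.mkdir(parents=True, exist_ok=True)
        ckpt_csv = checkpoint_dir / "summaries.csv"
        meta_path = checkpoint_dir / "run_meta.json"
        if meta_path.exists() or ckpt_csv.exists():
            try:
                stored = json.loads(meta_path.read_text())
            except (OSError, json.JSONDecodeError) as exc:
                raise CheckpointError(f"corrupt checkpoint metadata: {exc}") from exc
            for key in ("config_digest", "conditions_digest"):
                if stored.get(key) != meta[key]:
                    raise CheckpointError(
                        f"checkpoint {key} mismatch "
                        f"({stored.get(key)!r} != {meta[key]!r}); refusing to resume"
                    )
            if ckpt_csv.exists():
                try:
                    prev = pd.read_csv(ckpt_csv, float_precision="round_trip")
                except Exception as exc:  # malformed CSV
                    raise CheckpointError(f"corrupt checkpoint table: {exc}") from exc
                done = {int(r["condition_index"]): r.to_dict() for _, r in prev.iterrows()}
        else:
            meta_path.write_text(json.dumps(meta, indent=2))

    todo = [c for c in conditions if c.condition_index not in done]

    def one(cond: DesignCondition) -> dict:
        return run_condition(
            cond, config, base_params=base_params, fit_options=fit_options
        ).to_row()

    rows = dict(done)
    batch = max(1, config.n_jobs) * 8
    for start in range(0, len(todo), batch):
        chunk = todo[start : start + batch]
        if config.n_jobs > 1:
            results = Parallel(n_jobs=config.n_jobs)(delayed(one)(c) for c in chunk)
        else:
            results = [one(c) for c in chunk]
        for c, row in zip(chunk, results):
            rows[c.condition_index] = row
        if progress is not None:
            last = chunk[-1].condition_index
            progress(
                f"completed {min(start + batch, len(todo))}/{len(todo)} conditions "
                f"(through index {last})"
            )
        if ckpt_csv is not None:
            _write_table(rows, conditions, meta, ckpt_csv)

    table = _assemble(rows, conditions, meta)
    if ckpt_csv is not None:
        table.to_csv(ckpt_csv, index=False, float_format="%.17g")
    return table


def _assemble(rows, conditions, meta) -> pd.DataFrame:
    ordered = [rows[c.condition_index] for c in conditions if c.condition_index in rows]
    table = pd.DataFrame(ordered)
    table["master_seed"] = meta["master_seed"]
    table["config_digest"] = meta["config_digest"]
    return table


def _write_table(rows, conditions, meta, path) -> None:
    _assemble(rows, conditions, meta).to_csv(path, index=False, float_format="%.17g")
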