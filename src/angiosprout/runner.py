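"""Full simulation protocol, parameter sweeps, replicate aggregation.

One run interleaves, per MCS: a Monte Carlo step of N copy attempts, the
PDE substeps (operator splitting), and — every ``proliferation_period``
MCS — one proliferation sweep. Metrics are recorded on a fixed period
and the whole trajectory is a deterministic function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd

from . import morphometrics
from .config import SimConfig
from .cpm import LatticeState, build_initial_state, monte_carlo_step
from .fields import FieldSet, couple_fields_per_mcs, initialize_fields
from .proliferation import proliferation_sweep

METRICS_COLUMNS = ["mcs", "compactness", "height", "size", "n_cells",
                   "replicate", "seed", "param", "value"]


@dataclass
class SweepSpec:
    """One-parameter sweep: a value list with replicated runs."""

    parameter: str
    values: list
    replicates: int = 10
    base_preset: str | None = None

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.parameter not in SimConfig().to_dict():
            raise ValueError(f"unknown parameter {self.parameter!r}")


@dataclass
class SimResult:
    metrics: pd.DataFrame
    snapshots: list[tuple[int, np.ndarray]]
    state: LatticeState
    fields: FieldSet
    config: SimConfig
    seed: int


def derive_seed(base_seed: int, value_index: int, replicate: int) -> int:
    """Stable per-(value, replicate) seed, independently reproducible."""
    ss = np.random.SeedSequence([int(base_seed), int(value_index),
                                 int(replicate)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_simulation(cfg: SimConfig, seed: int | None = None,
                   collect_snapshots: bool = True,
                   progress: Callable[[int, dict], None] | None = None,
                   per_mcs_hook: Callable[[LatticeState, FieldSet], None]
                   | None = None) -> SimResult:
    """Run one full simulation; deterministic per (config, seed)."""
    cfg.validate()
    seed = cfg.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    state = build_initial_state(cfg)
    fields = initialize_fields(cfg, state)
    rows = []
    snapshots: list[tuple[int, np.ndarray]] = []

    def record(mcs: int) -> None:
        row = morphometrics.metrics_row(state, cfg)
        row["replicate"] = 0
        row["seed"] = seed
        rows.append(row)
        if progress is not None:
            progress(mcs, row)

    record(0)
    if collect_snapshots:
        snapshots.append((0, state.sigma.copy()))
    for mcs in range(1, cfg.MCS_tot + 1):
        monte_carlo_step(state, fields, cfg, rng)
        couple_fields_per_mcs(state, fields, cfg)
        if mcs % cfg.proliferation_period == 0:
            proliferation_sweep(state, cfg, rng)
        if per_mcs_hook is not None:
            per_mcs_hook(state, fields)
        if mcs % cfg.metric_period == 0:
            record(mcs)
        if collect_snapshots and mcs % cfg.snapshot_period == 0:
            snapshots.append((mcs, state.sigma.copy()))
    metrics = pd.DataFrame(rows)
    metrics["param"] = ""
    metrics["value"] = np.nan
    return SimResult(metrics[METRICS_COLUMNS], snapshots, state, fields,
                     cfg, seed)


def run_sweep(spec: SweepSpec, base_config: SimConfig | None = None,
              collect_snapshots: bool = False) -> pd.DataFrame:
    """Run every (value, replicate) cell of a sweep; long-format table.

    Each cell gets its own seed derived from the base config's seed, the
    value index and the replicate index, so any cell can be re-run in
    isolation.
    """
    from .config import preset_config

    base = base_config if base_config is not None else SimConfig()
    if spec.base_preset is not None:
        base = preset_config(spec.base_preset, base)
    frames = []
    for vi, value in enumerate(spec.values):
        for ri in range(spec.replicates):
            cfg = base.replace(**{spec.parameter: value})
            seed = derive_seed(base.seed, vi, ri)
            res = run_simulation(cfg, seed=seed,
                                 collect_snapshots=collect_snapshots)
            df = res.metrics.copy()
            df["param"] = spec.parameter
            df["value"] = value
            df["replicate"] = ri
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def aggregate_replicates(results: pd.DataFrame,
                         by: tuple[str, ...] = ("param", "value", "mcs"),
                         metrics: tuple[str, ...] = ("compactness", "height",
                                                     "size", "n_cells"),
                         ) -> pd.DataFrame:
    """Mean and sample SD (ddof=1) per (parameter value, timepoint).

    A single replicate yields a missing SD, never zero; an empty table
    is an error.
    """
    if len(results) == 0:
        raise ValueError("cannot aggregate an empty results table")
    by = [c for c in by if c in results.columns]
    agg = results.groupby(by, dropna=False)[list(metrics)].agg(
        ["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()


def save_metrics_csv(metrics: pd.DataFrame, path) -> None:
    """Write the metrics table with the canonical column order."""
    cols = [c for c in METRICS_COLUMNS if c in metrics.columns]
    metrics[cols].to_csv(path, index=False)
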