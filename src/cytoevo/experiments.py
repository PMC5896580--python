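"""Experiment grids: replicate orchestration, aggregation and presets.

A grid is a list of named simulation configurations (grid cells); running it
executes ``R`` independently seeded replicates per cell, computes a standard
bundle of per-replicate metrics, and aggregates each metric as mean plus
standard error of the mean.  Named presets assemble the package's standard
comparisons (inheritance mode x bottleneck size x engine) at configurable
replication.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .core import SimulationConfig, run_simulation
from .fitness import FitnessSpec
from .freeliving import FreeLivingConfig, run_free_living
from .metrics import (
    detect_ratchets,
    generations_per_substitution,
    hitchhiking_index,
    sweep_stats,
)
from .trajectory import Trajectory

__all__ = [
    "GridCell",
    "ExperimentGrid",
    "replicate_seed",
    "run_replicate",
    "replicate_metrics",
    "run_grid",
    "preset",
    "PRESET_NAMES",
]

#: Default parameter values of the simulated conditions.
DEFAULTS = dict(N=1000, n=50, l=20_000, mu_b=1e-8, mu_d=1e-7, gamma=5)
RELAXED_B = 25  # b = n/2
TIGHT_B = 5  # b = n/10


@dataclass(frozen=True)
class GridCell:
    label: str
    config: SimulationConfig | FreeLivingConfig


@dataclass
class ExperimentGrid:
    name: str
    cells: list[GridCell]
    replicates: int = 20
    base_seed: int = 0


def replicate_seed(base_seed: int, label: str, r: int) -> int:
    """Deterministic per-replicate seed (< 2**31), independent across labels and r."""
    mix = np.random.SeedSequence([base_seed, zlib.crc32(label.encode()), r])
    return int(mix.generate_state(1, np.uint32)[0] & 0x7FFF_FFFF)


def run_replicate(cell: GridCell, seed: int) -> Trajectory:
    config = replace(cell.config, seed=seed)
    if isinstance(config, FreeLivingConfig):
        return run_free_living(config)
    # long combined runs only feed ratchet / adaptive-ratio statistics
    level = "minimal" if (config.mu_b > 0 and config.mu_d > 0) else "full"
    return run_simulation(config, record=level)


def replicate_metrics(traj: Trajectory) -> dict[str, float | None]:
    """Standard per-replicate metric bundle; entries are None when undefined."""
    out: dict[str, float | None] = {
        "stop_generation": float(traj.generation[-1]),
        "truncated": float(traj.truncated),
        "final_mean_alpha": float(traj.mean_alpha[-1]),
        "final_mean_kappa": float(traj.mean_kappa[-1]),
        "final_min_kappa": float(traj.min_kappa[-1]),
        "mean_within_cell_variance": float(traj.within_cell_variance.mean()),
        "mean_between_cell_fitness_variance": float(
            traj.between_cell_fitness_variance.mean()
        ),
    }
    try:
        out["generations_per_substitution"] = generations_per_substitution(traj)
    except ValueError:
        out["generations_per_substitution"] = None
    if traj.alpha_class_counts is not None:
        stats = sweep_stats(traj)
        out["m_g"] = stats.m_g
        out["c_g"] = stats.c_g
    events = detect_ratchets(traj)
    hh = hitchhiking_index(events, int(traj.generation[-1])) if traj.generation[-1] >= 1 else None
    out["phi"] = hh.phi if hh else None
    out["phi_uncensored"] = hh.phi_uncensored if hh else None
    out["n_beneficial_ratchets"] = float(sum(e.kind == "beneficial" for e in events))
    out["n_deleterious_ratchets"] = float(sum(e.kind == "deleterious" for e in events))
    if out["final_mean_kappa"] and out["final_mean_kappa"] > 0:
        out["adaptive_ratio"] = out["final_mean_alpha"] / out["final_mean_kappa"]
    else:
        out["adaptive_ratio"] = None
    return out


def _aggregate(replicates: pd.DataFrame) -> pd.DataFrame:
    """Mean and SEM per (label, metric), skipping undefined replicate values."""
    rows = []
    value_cols = [c for c in replicates.columns if c not in ("label", "replicate", "seed")]
    for label, group in replicates.groupby("label", sort=False):
        for col in value_cols:
            vals = group[col].dropna().to_numpy(dtype=np.float64)
            if len(vals) == 0:
                continue
            sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
            rows.append(
                {"label": label, "metric": col, "mean": float(vals.mean()), "sem": sem, "n": len(vals)}
            )
    return pd.DataFrame(rows)


def run_grid(
    grid: ExperimentGrid, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every grid cell x replicate; return (replicate table, summary table).

    With ``out_dir`` set, writes ``replicates.csv``, ``summary.csv`` and a
    ``provenance.json`` recording configs, seeds and package version.
    """
    rows = []
    provenance: dict[str, Any] = {
        "grid": grid.name,
        "replicates": grid.replicates,
        "base_seed": grid.base_seed,
        "version": __version__,
        "cells": {},
    }
    for cell in grid.cells:
        seeds = [replicate_seed(grid.base_seed, cell.label, r) for r in range(grid.replicates)]
        cfg = dataclasses.asdict(cell.config)
        cfg["fitness"] = dataclasses.asdict(cell.config.fitness)
        provenance["cells"][cell.label] = {"config": cfg, "seeds": seeds}
        for r, seed in enumerate(seeds):
            traj = run_replicate(cell, seed)
            row: dict[str, Any] = {"label": cell.label, "replicate": r, "seed": seed}
            row.update(replicate_metrics(traj))
            rows.append(row)
    replicates = pd.DataFrame(rows)
    summary = _aggregate(replicates)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        replicates.to_csv(out / "replicates.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return replicates, summary


# ---------------------------------------------------------------------------
# presets


def _host(inheritance: str, b: int, *, fitness: FitnessSpec, **kw) -> SimulationConfig:
    base = dict(DEFAULTS)
    base.update(kw)
    return SimulationConfig(inheritance=inheritance, b=b, fitness=fitness, **base)


def _regime_cells(fitness: FitnessSpec, **kw) -> list[GridCell]:
    return [
        GridCell("UPI", _host("uniparental", RELAXED_B, fitness=fitness, **kw)),
        GridCell("UPI_bot", _host("uniparental", TIGHT_B, fitness=fitness, **kw)),
        GridCell("BPI", _host("biparental", RELAXED_B, fitness=fitness, **kw)),
        GridCell("BPI_bot", _host("biparental", TIGHT_B, fitness=fitness, **kw)),
    ]


def _beneficial_only_cells() -> list[GridCell]:
    fit = FitnessSpec(s_b=0.1, s_d=0.0, beneficial_shape="linear", deleterious_shape="linear")
    cells = _regime_cells(
        fit, mu_d=0.0, stop_rule="all_genomes_reach_gamma", max_generations=60_000
    )
    cells.append(
        GridCell(
            "free_living",
            FreeLivingConfig(
                N_FL=50_000,
                mu_b=1e-8,
                mu_d=0.0,
                fitness=FitnessSpec(
                    s_b=0.1, s_d=0.0, beneficial_shape="linear", deleterious_shape="linear"
                ),
                stop_rule="all_genomes_reach_gamma",
                max_generations=60_000,
            ),
        )
    )
    return cells


def preset(name: str, replicates: int | None = None, base_seed: int = 0) -> ExperimentGrid:
    """A named experiment grid for one of the package's standard comparisons.

    Known names: ``beneficial_accumulation``, ``interference_timeseries``,
    ``deleterious_accumulation``, ``hitchhiking``, ``adaptive_ratio``,
    ``freeliving_scan``.
    """
    if name == "beneficial_accumulation":
        cells, default_r = _beneficial_only_cells(), 20
    elif name == "interference_timeseries":
        cells, default_r = _beneficial_only_cells(), 1
    elif name == "deleterious_accumulation":
        cells = []
        for s_d in (0.1, 0.01):
            fit = FitnessSpec(s_b=0.0, s_d=s_d, deleterious_shape="concave_down")
            for cell in _regime_cells(fit, mu_b=0.0, max_generations=10_000):
                cells.append(GridCell(f"{cell.label}_sd{s_d}", cell.config))
        cells.append(
            GridCell(
                "free_living_sd0.1",
                FreeLivingConfig(
                    N_FL=50_000,
                    mu_b=0.0,
                    mu_d=1e-7,
                    fitness=FitnessSpec(s_b=0.0, s_d=0.1, deleterious_shape="linear"),
                    max_generations=10_000,
                ),
            )
        )
        default_r = 20
    elif name in ("hitchhiking", "adaptive_ratio"):
        cells = []
        for s_b, s_d in ((0.1, 0.1), (0.01, 0.01), (0.01, 0.1), (0.1, 0.01)):
            fit = FitnessSpec(
                s_b=s_b, s_d=s_d, beneficial_shape="linear", deleterious_shape="concave_down"
            )
            for cell in _regime_cells(fit, max_generations=10_000):
                cells.append(GridCell(f"{cell.label}_sb{s_b}_sd{s_d}", cell.config))
        default_r = 20
    elif name == "freeliving_scan":
        cells = []
        for N_FL in (1000, 50_000):
            for s_FL in (1, 2, 5, 10, 20, 50):
                cells.append(
                    GridCell(
                        f"FL_N{N_FL}_sFL{s_FL}",
                        FreeLivingConfig(
                            N_FL=N_FL,
                            mu_b=1e-8,
                            mu_d=0.0,
                            fitness=FitnessSpec(
                                s_b=0.1,
                                s_d=0.0,
                                beneficial_shape="linear",
                                deleterious_shape="linear",
                                s_FL=s_FL,
                            ),
                            stop_rule="all_genomes_reach_gamma",
                            max_generations=60_000,
                        ),
                    )
                )
        default_r = 20
    else:
        raise ValueError(f"unknown preset {name!r}")
    return ExperimentGrid(
        name=name,
        cells=cells,
        replicates=replicates if replicates is not None else default_r,
        base_seed=base_seed,
    )


PRESET_NAMES = (
    "beneficial_accumulation",
    "interference_timeseries",
    "deleterious_accumulation",
    "hitchhiking",
    "adaptive_ratio",
    "freeliving_scan",
)
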