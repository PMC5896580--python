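"""Per-generation trajectory records shared by both simulation engines."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "TrajectoryRecorder"]

#: Columns of the tidy per-generation table, in output order.
COLUMNS = [
    "generation",
    "mean_alpha",
    "mean_kappa",
    "min_alpha",
    "min_kappa",
    "within_cell_variance",
    "between_cell_fitness_variance",
    "n_classes",
]


@dataclass
class Trajectory:
    """One simulation run: per-generation summaries plus provenance.

    ``generation[t]`` counts completed life cycles; row 0 is the founding
    population before any cycle.  ``alpha_class_counts[t]`` is the marginal
    genome count per beneficial substitution class (index = alpha) at
    generation ``t`` — the class-frequency table used by the analysis layer.
    """

    engine: str
    config: dict[str, Any]
    seed: int
    generation: np.ndarray
    mean_alpha: np.ndarray
    mean_kappa: np.ndarray
    min_alpha: np.ndarray
    min_kappa: np.ndarray
    within_cell_variance: np.ndarray
    between_cell_fitness_variance: np.ndarray
    n_classes: np.ndarray
    alpha_class_counts: list[np.ndarray] | None
    stop_reason: str = "max_generations"
    truncated: bool = False

    @property
    def n_generations(self) -> int:
        """Index of the last recorded generation (= number of completed cycles)."""
        return int(self.generation[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in COLUMNS})

    def frequency_matrix(self) -> np.ndarray:
        """Beneficial-class frequencies as a dense (T+1, alpha_max+1) array.

        Rows sum to 1: entry ``[t, a]`` is the fraction of all genomes that
        carry exactly ``a`` beneficial substitutions at generation ``t``.
        """
        if self.alpha_class_counts is None:
            raise ValueError("run was recorded without class counts")
        width = max(len(c) for c in self.alpha_class_counts)
        out = np.zeros((len(self.alpha_class_counts), width))
        for t, counts in enumerate(self.alpha_class_counts):
            out[t, : len(counts)] = counts
        totals = out.sum(axis=1, keepdims=True)
        return out / totals

    def save(
        self,
        directory: str | Path,
        stem: str = "trajectory",
        include_class_counts: bool = True,
    ) -> Path:
        """Write the tidy CSV plus a JSON sidecar of provenance; return the CSV path."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        csv_path = directory / f"{stem}.csv"
        self.to_frame().to_csv(csv_path, index=False)
        sidecar = {
            "engine": self.engine,
            "config": self.config,
            "seed": self.seed,
            "stop_reason": self.stop_reason,
            "truncated": self.truncated,
        }
        if include_class_counts and self.alpha_class_counts is not None:
            sidecar["alpha_class_counts"] = [c.tolist() for c in self.alpha_class_counts]
        (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
        return csv_path

    @classmethod
    def load(cls, directory: str | Path, stem: str = "trajectory") -> "Trajectory":
        """Rebuild a trajectory from its CSV table and JSON sidecar."""
        directory = Path(directory)
        frame = pd.read_csv(directory / f"{stem}.csv")
        sidecar = json.loads((directory / f"{stem}.json").read_text())
        counts = sidecar.get("alpha_class_counts")
        return cls(
            engine=sidecar["engine"],
            config=sidecar["config"],
            seed=sidecar["seed"],
            generation=frame["generation"].to_numpy(np.int64),
            mean_alpha=frame["mean_alpha"].to_numpy(),
            mean_kappa=frame["mean_kappa"].to_numpy(),
            min_alpha=frame["min_alpha"].to_numpy(np.int64),
            min_kappa=frame["min_kappa"].to_numpy(np.int64),
            within_cell_variance=frame["within_cell_variance"].to_numpy(),
            between_cell_fitness_variance=frame["between_cell_fitness_variance"].to_numpy(),
            n_classes=frame["n_classes"].to_numpy(np.int64),
            alpha_class_counts=(
                [np.asarray(c, dtype=np.int64) for c in counts] if counts is not None else None
            ),
            stop_reason=sidecar["stop_reason"],
            truncated=sidecar["truncated"],
        )


class TrajectoryRecorder:
    """Accumulates per-generation rows and assembles a :class:`Trajectory`."""

    def __init__(
        self,
        engine: str,
        config: dict[str, Any],
        seed: int,
        record_class_counts: bool = True,
    ) -> None:
        self.engine = engine
        self.config = config
        self.seed = seed
        self._rows: dict[str, list] = {c: [] for c in COLUMNS}
        self._class_counts: list[np.ndarray] | None = [] if record_class_counts else None

    def record(
        self,
        generation: int,
        mean_alpha: float,
        mean_kappa: float,
        min_alpha: int,
        min_kappa: int,
        within_cell_variance: float,
        between_cell_fitness_variance: float,
        n_classes: int,
        alpha_class_counts: np.ndarray | None = None,
    ) -> None:
        r = self._rows
        r["generation"].append(generation)
        r["mean_alpha"].append(mean_alpha)
        r["mean_kappa"].append(mean_kappa)
        r["min_alpha"].append(min_alpha)
        r["min_kappa"].append(min_kappa)
        r["within_cell_variance"].append(within_cell_variance)
        r["between_cell_fitness_variance"].append(between_cell_fitness_variance)
        r["n_classes"].append(n_classes)
        if self._class_counts is not None:
            if alpha_class_counts is None:
                raise ValueError("recorder configured for class counts but none given")
            self._class_counts.append(np.asarray(alpha_class_counts, dtype=np.int64))

    def finish(self, stop_reason: str, truncated: bool) -> Trajectory:
        r = self._rows
        return Trajectory(
            engine=self.engine,
            config=self.config,
            seed=self.seed,
            generation=np.asarray(r["generation"], dtype=np.int64),
            mean_alpha=np.asarray(r["mean_alpha"]),
            mean_kappa=np.asarray(r["mean_kappa"]),
            min_alpha=np.asarray(r["min_alpha"], dtype=np.int64),
            min_kappa=np.asarray(r["min_kappa"], dtype=np.int64),
            within_cell_variance=np.asarray(r["within_cell_variance"]),
            between_cell_fitness_variance=np.asarray(r["between_cell_fitness_variance"]),
            n_classes=np.asarray(r["n_classes"], dtype=np.int64),
            alpha_class_counts=self._class_counts,
            stop_reason=stop_reason,
            truncated=truncated,
        )
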