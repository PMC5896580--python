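"""Free-living asexual null model: single-genome cells, mutation + selection.

Each free-living cell carries one asexual genome with ``l`` sites, so the
life cycle has only two stages.  Every generation each genome independently
gains beneficial / deleterious substitutions, then ``N_FL`` cells are
resampled with replacement in proportion to :func:`~cytoevo.fitness.free_living_fitness`
(linear shapes, with the ``s_FL`` fold-scaling of per-substitution effects).

Because a cell *is* its genome, the population is fully described by the
count of genomes in each ``(alpha, kappa)`` class.  The engine therefore
stores a small 2-D count matrix and each generation costs a few vectorized
draws regardless of ``N_FL``: mutation moves ``Binomial(count, p)`` genomes
per occupied class one step up an axis (``p = 1 - (1 - mu)**l``, the chance
a genome gains at least one new substitution; multiple hits of the same
genome in a single generation are ignored, an ``O((l*mu)^2)`` effect), and
Wright-Fisher selection is a single multinomial draw over occupied classes
weighted by ``count * fitness``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .core import ExtinctionError
from .fitness import FitnessSpec, free_living_fitness
from .trajectory import Trajectory, TrajectoryRecorder

__all__ = ["FreeLivingConfig", "run_free_living"]


@dataclass
class FreeLivingConfig:
    """Parameterization of one free-living run.

    For comparisons against the host model, ``N_FL`` is matched either to
    the number of hosts (``N``) or to the total number of cytoplasmic
    genomes (``N * n``); any positive size is accepted.
    """

    N_FL: int = 50_000
    l: int = 20_000
    mu_b: float = 1e-8
    mu_d: float = 0.0
    fitness: FitnessSpec = field(
        default_factory=lambda: FitnessSpec(deleterious_shape="linear")
    )
    stop_rule: str = "fixed_generations"
    max_generations: int = 10_000
    gamma: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N_FL < 1 or self.l < 1:
            raise ValueError("N_FL and l must be positive")
        if not (0.0 <= self.mu_b <= 1.0 and 0.0 <= self.mu_d <= 1.0):
            raise ValueError("mutation rates must lie in [0, 1]")
        if self.mu_b + self.mu_d > 1.0:
            raise ValueError("mu_b + mu_d must not exceed 1")
        if self.fitness.beneficial_shape != "linear" or self.fitness.deleterious_shape != "linear":
            raise ValueError("the free-living model uses linear fitness shapes only")
        if self.stop_rule not in ("all_genomes_reach_gamma", "fixed_generations"):
            raise ValueError(f"unknown stop rule {self.stop_rule!r}")
        if self.gamma < 1 or self.max_generations < 1:
            raise ValueError("gamma and max_generations must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fitness"] = asdict(self.fitness)
        return d


class _ClassCounts:
    """Genome counts over (alpha, kappa) classes, stored with headroom."""

    def __init__(self, N: int) -> None:
        self.counts = np.zeros((8, 8), dtype=np.int64)
        self.counts[0, 0] = N
        self.N = N

    def _grow(self, axis: int) -> None:
        pad = [(0, 0), (0, 0)]
        pad[axis] = (0, self.counts.shape[axis])
        self.counts = np.pad(self.counts, pad)

    def mutate_axis(self, axis: int, p: float, rng: np.random.Generator) -> None:
        """Move Binomial(count, p) genomes of every occupied class one step up."""
        if p == 0.0:
            return
        a_idx, k_idx = np.nonzero(self.counts)
        moved = rng.binomial(self.counts[a_idx, k_idx], p)
        if int(np.max(a_idx if axis == 0 else k_idx, initial=0)) + 2 >= self.counts.shape[axis]:
            self._grow(axis)
        np.subtract.at(self.counts, (a_idx, k_idx), moved)
        if axis == 0:
            np.add.at(self.counts, (a_idx + 1, k_idx), moved)
        else:
            np.add.at(self.counts, (a_idx, k_idx + 1), moved)

    def select(self, spec: FitnessSpec, rng: np.random.Generator, generation: int) -> np.ndarray:
        """Wright-Fisher resampling; returns per-class fitness for recording."""
        a_idx, k_idx = np.nonzero(self.counts)
        w = np.asarray(free_living_fitness(a_idx, k_idx, spec), dtype=np.float64)
        weights = self.counts[a_idx, k_idx] * w
        total = weights.sum()
        if total <= 0.0:
            raise ExtinctionError(generation)
        new = rng.multinomial(self.N, weights / total)
        self.counts[a_idx, k_idx] = new
        return w


def _record(rec: TrajectoryRecorder, cc: _ClassCounts, spec: FitnessSpec, gen: int, want: bool) -> None:
    counts = cc.counts
    a_idx, k_idx = np.nonzero(counts)
    c = counts[a_idx, k_idx]
    N = cc.N
    w = np.asarray(free_living_fitness(a_idx, k_idx, spec), dtype=np.float64)
    mean_w = float((c * w).sum() / N)
    rec.record(
        generation=gen,
        mean_alpha=float((c * a_idx).sum() / N),
        mean_kappa=float((c * k_idx).sum() / N),
        min_alpha=int(a_idx.min()),
        min_kappa=int(k_idx.min()),
        within_cell_variance=0.0,  # a free-living cell carries a single genome
        between_cell_fitness_variance=float((c * w**2).sum() / N - mean_w**2),
        n_classes=int(len(c)),
        alpha_class_counts=counts.sum(axis=1)[: int(a_idx.max()) + 1] if want else None,
    )


def run_free_living(config: FreeLivingConfig, record_class_counts: bool = True) -> Trajectory:
    """Run one free-living replicate to its stop rule; schema matches the host engine."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    p_b = 1.0 - (1.0 - config.mu_b) ** config.l
    p_d = 1.0 - (1.0 - config.mu_d) ** config.l
    cc = _ClassCounts(config.N_FL)
    rec = TrajectoryRecorder(
        engine="free_living",
        config=config.to_dict(),
        seed=config.seed,
        record_class_counts=record_class_counts,
    )
    _record(rec, cc, config.fitness, 0, record_class_counts)
    gen = 0
    stop_reason, truncated = "max_generations", False
    while gen < config.max_generations:
        cc.mutate_axis(0, p_b, rng)
        cc.mutate_axis(1, p_d, rng)
        cc.select(config.fitness, rng, gen)
        gen += 1
        _record(rec, cc, config.fitness, gen, record_class_counts)
        if config.stop_rule == "all_genomes_reach_gamma":
            if int(np.nonzero(cc.counts)[0].min()) >= config.gamma:
                stop_reason = "gamma_reached"
                break
    else:
        if config.stop_rule == "all_genomes_reach_gamma":
            truncated = True
    return rec.finish(stop_reason, truncated)
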