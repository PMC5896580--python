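"""Life cycle of cytoplasmic genomes inside diploid hosts.

A population of ``N`` diploid cells, each carrying ``n`` copies of an asexual
cytoplasmic genome, passes once per generation through four stages:

1. **mutation** — every genome copy independently gains new beneficial /
   deleterious substitutions at per-site rates ``mu_b`` / ``mu_d`` over ``l``
   sites;
2. **selection** — ``N`` cells are resampled with replacement, weighted by
   cell fitness computed from each cell's total substitution loads;
3. **gametogenesis** — every cell produces one gamete of each mating type
   (``A`` and ``a``), each carrying ``b`` genome copies sampled with
   replacement from the parent's ``n`` (the transmission bottleneck);
4. **mating / repopulation** — ``A`` gametes pair at random with ``a``
   gametes; offspring draw ``n`` copies with replacement from the fused pool
   (both gametes' ``2b`` copies under biparental inheritance, only the ``A``
   gamete's ``b`` under uniparental inheritance).

A genome is identified solely by its substitution counts ``(alpha, kappa)``;
sites are not tracked and there is no back mutation.  The engine stores the
population as ``(N, copies)`` integer arrays of per-copy counts, which keeps
every stage a handful of vectorized draws.  Object-level views
(:class:`CellState`, class-count mappings) are provided for inspection and
for exercising single cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Callable, Iterator, NamedTuple

import numpy as np

from .fitness import FitnessSpec, cell_fitness
from .trajectory import Trajectory, TrajectoryRecorder

__all__ = [
    "GenomeClass",
    "CellState",
    "PopulationState",
    "SimulationConfig",
    "ExtinctionError",
    "mutate_cell",
    "mutate_population",
    "select_hosts",
    "gametogenesis",
    "mate_and_repopulate",
    "advance_generation",
    "run_simulation",
    "make_cell_fitness",
]

logger = logging.getLogger(__name__)

INHERITANCE_MODES = ("uniparental", "biparental")
STOP_RULES = ("all_genomes_reach_gamma", "fixed_generations")


class ExtinctionError(RuntimeError):
    """Raised when every cell in the population has fitness zero."""

    def __init__(self, generation: int):
        super().__init__(f"all cells have zero fitness at generation {generation}")
        self.generation = generation


class GenomeClass(NamedTuple):
    """A genome type: counts of beneficial (alpha) and deleterious (kappa) substitutions."""

    alpha: int
    kappa: int


@dataclass
class CellState:
    """A cell as a multiset of genome classes.

    ``capacity`` is the expected total copy number: ``n`` for diploid hosts,
    ``b`` for gametes.
    """

    class_counts: dict[GenomeClass, int]
    capacity: int
    mating_type: str | None = None

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.class_counts.values()):
            raise ValueError("class counts must be positive")
        if sum(self.class_counts.values()) != self.capacity:
            raise ValueError("class counts must sum to the cell's capacity")

    @classmethod
    def homoplasmic(cls, cls_: GenomeClass, capacity: int, mating_type: str | None = None):
        return cls({cls_: capacity}, capacity, mating_type)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-copy (alpha, kappa) arrays, classes in sorted order."""
        alphas, kappas = [], []
        for gc in sorted(self.class_counts):
            count = self.class_counts[gc]
            alphas.extend([gc.alpha] * count)
            kappas.extend([gc.kappa] * count)
        return np.array(alphas, dtype=np.int64), np.array(kappas, dtype=np.int64)

    @classmethod
    def from_arrays(cls, alpha, kappa, mating_type: str | None = None) -> "CellState":
        counts: dict[GenomeClass, int] = {}
        for a, k in zip(np.asarray(alpha).ravel(), np.asarray(kappa).ravel()):
            gc = GenomeClass(int(a), int(k))
            counts[gc] = counts.get(gc, 0) + 1
        return cls(counts, len(np.asarray(alpha).ravel()), mating_type)

    @property
    def total_loads(self) -> tuple[int, int]:
        x = sum(gc.alpha * c for gc, c in self.class_counts.items())
        y = sum(gc.kappa * c for gc, c in self.class_counts.items())
        return x, y


@dataclass
class PopulationState:
    """Array-backed population: per-copy substitution counts for every cell.

    ``alpha`` and ``kappa`` have shape ``(N, copies)`` where ``copies`` is
    the per-cell copy number at the current life-cycle stage (``n`` for
    diploid cells, ``b`` for gamete pools).
    """

    generation: int
    alpha: np.ndarray
    kappa: np.ndarray

    def __post_init__(self) -> None:
        if self.alpha.shape != self.kappa.shape or self.alpha.ndim != 2:
            raise ValueError("alpha and kappa must be 2-D arrays of equal shape")

    @property
    def N(self) -> int:
        return self.alpha.shape[0]

    @property
    def copies(self) -> int:
        return self.alpha.shape[1]

    @classmethod
    def founding(cls, N: int, n: int) -> "PopulationState":
        """Generation-0 population: every genome substitution-free."""
        return cls(0, np.zeros((N, n), dtype=np.int16), np.zeros((N, n), dtype=np.int16))

    def cell_loads(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell total (beneficial, deleterious) substitution counts."""
        return (
            self.alpha.sum(axis=1, dtype=np.int64),
            self.kappa.sum(axis=1, dtype=np.int64),
        )

    def cells(self) -> Iterator[CellState]:
        for i in range(self.N):
            yield CellState.from_arrays(self.alpha[i], self.kappa[i])


@dataclass
class SimulationConfig:
    """Full parameterization of one cytoplasmic-genome run."""

    N: int = 1000
    n: int = 50
    b: int = 25
    l: int = 20_000
    mu_b: float = 1e-8
    mu_d: float = 1e-7
    fitness: FitnessSpec = field(default_factory=FitnessSpec)
    inheritance: str = "uniparental"
    stop_rule: str = "fixed_generations"
    max_generations: int = 10_000
    gamma: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1 or self.n < 1 or self.l < 1:
            raise ValueError("N, n and l must be positive")
        # b <= n/2; the degenerate single-copy cell (n=1, b=1) is allowed so the
        # host engine can emulate free-living genomes in cross-engine checks.
        if not (1 <= self.b <= max(1, self.n // 2)):
            raise ValueError("bottleneck must satisfy 1 <= b <= n/2")
        if not (0.0 <= self.mu_b <= 1.0 and 0.0 <= self.mu_d <= 1.0):
            raise ValueError("mutation rates must lie in [0, 1]")
        if self.mu_b + self.mu_d > 1.0:
            raise ValueError("mu_b + mu_d must not exceed 1")
        if self.inheritance not in INHERITANCE_MODES:
            raise ValueError(f"unknown inheritance mode {self.inheritance!r}")
        if self.stop_rule not in STOP_RULES:
            raise ValueError(f"unknown stop rule {self.stop_rule!r}")
        if self.gamma < 1 or self.max_generations < 1:
            raise ValueError("gamma and max_generations must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fitness"] = asdict(self.fitness)
        return d


def make_cell_fitness(spec: FitnessSpec) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Vectorized map from per-cell total loads to relative fitness."""

    def fn(x_total: np.ndarray, y_total: np.ndarray) -> np.ndarray:
        return np.asarray(cell_fitness(x_total, y_total, spec), dtype=np.float64)

    return fn


# ---------------------------------------------------------------------------
# stage 1: mutation


def mutate_cell(
    cell: CellState, l: int, mu_b: float, mu_d: float, rng: np.random.Generator
) -> CellState:
    """Mutate one cell: each genome copy gains Binomial(l, mu) new substitutions.

    Beneficial and deleterious counts are drawn independently per copy; the
    copy number is unchanged.
    """
    if mu_b + mu_d > 1.0:
        raise ValueError("mu_b + mu_d must not exceed 1")
    if mu_b == 0.0 and mu_d == 0.0:
        return cell
    alpha, kappa = cell.to_arrays()
    alpha = alpha + rng.binomial(l, mu_b, size=alpha.size)
    kappa = kappa + rng.binomial(l, mu_d, size=kappa.size)
    return CellState.from_arrays(alpha, kappa, cell.mating_type)


def mutate_population(pop: PopulationState, config: SimulationConfig, rng: np.random.Generator) -> None:
    """In-place mutation stage over the whole population.

    The total number of new substitutions of each kind across all ``G``
    genome copies is Binomial(G*l, mu) — the exact sum of the per-copy
    Binomial(l, mu) draws — and each event lands on a copy chosen uniformly
    at random.  (Allocating events to copies with replacement rather than to
    distinct sites differs only through same-site collisions, which are
    negligible at the per-genome rates considered here.)
    """
    if config.mu_b + config.mu_d > 1.0:
        raise ValueError("mu_b + mu_d must not exceed 1")
    G = pop.alpha.size
    for arr, mu in ((pop.alpha, config.mu_b), (pop.kappa, config.mu_d)):
        if mu == 0.0:
            continue
        events = rng.binomial(G * config.l, mu)
        if events:
            pos = rng.integers(0, G, size=events)
            np.add.at(arr.reshape(-1), pos, 1)


# ---------------------------------------------------------------------------
# stage 2: selection


def select_hosts(
    pop: PopulationState,
    fitness_fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
    rng: np.random.Generator,
) -> PopulationState:
    """Resample N cells with replacement, weighted by cell fitness.

    Selection is a within-generation stage; the generation index is
    unchanged.  Raises :class:`ExtinctionError` if every cell has fitness 0.
    """
    x, y = pop.cell_loads()
    w = fitness_fn(x, y)
    cdf = np.cumsum(w)
    total = cdf[-1]
    if total <= 0.0:
        raise ExtinctionError(pop.generation)
    u = rng.random(pop.N) * total
    idx = np.searchsorted(cdf, u, side="right")
    return PopulationState(pop.generation, pop.alpha[idx], pop.kappa[idx])


# ---------------------------------------------------------------------------
# stage 3: gametogenesis


def _gather_rows(
    alpha: np.ndarray, kappa: np.ndarray, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise gather: out[i, j] = arr[i, idx[i, j]], via flat int32 indexing."""
    N, copies = alpha.shape
    flat = idx + (np.arange(N, dtype=np.int32) * copies)[:, None]
    return alpha.reshape(-1)[flat], kappa.reshape(-1)[flat]


def gametogenesis(cell: CellState, b: int, rng: np.random.Generator) -> tuple[CellState, CellState]:
    """Produce the cell's two gametes (mating types A and a).

    Each gamete carries ``b`` genome copies sampled independently with
    replacement from the parent's copies.
    """
    alpha, kappa = cell.to_arrays()
    n = alpha.size
    idx_A = rng.integers(0, n, size=b)
    idx_a = rng.integers(0, n, size=b)
    gamete_A = CellState.from_arrays(alpha[idx_A], kappa[idx_A], mating_type="A")
    gamete_a = CellState.from_arrays(alpha[idx_a], kappa[idx_a], mating_type="a")
    return gamete_A, gamete_a


def _sample_gamete_pool(pop: PopulationState, b: int, rng: np.random.Generator) -> PopulationState:
    """One gamete per parent cell: (N, b) copies drawn with replacement."""
    idx = rng.integers(0, pop.copies, size=(pop.N, b), dtype=np.int32)
    return PopulationState(pop.generation, *_gather_rows(pop.alpha, pop.kappa, idx))


# ---------------------------------------------------------------------------
# stage 4: mating and repopulation


def _repopulate(pool: PopulationState, n: int, rng: np.random.Generator) -> PopulationState:
    idx = rng.integers(0, pool.copies, size=(pool.N, n), dtype=np.int32)
    return PopulationState(pool.generation, *_gather_rows(pool.alpha, pool.kappa, idx))


def mate_and_repopulate(
    gametes_A: PopulationState,
    gametes_a: PopulationState,
    inheritance: str,
    n: int,
    rng: np.random.Generator,
) -> PopulationState:
    """Pair gametes at random and restore each offspring to ``n`` genome copies.

    Under biparental inheritance the fused pool holds both gametes' ``2b``
    copies; under uniparental inheritance only the A gamete's ``b`` copies
    are transmitted (pairing then has no effect on cytoplasmic content).
    """
    if inheritance not in INHERITANCE_MODES:
        raise ValueError(f"unknown inheritance mode {inheritance!r}")
    if gametes_A.N != gametes_a.N:
        raise ValueError(
            f"gamete pools differ in size: {gametes_A.N} A-gametes vs {gametes_a.N} a-gametes"
        )
    if inheritance == "uniparental":
        pool = gametes_A
    else:
        perm = rng.permutation(gametes_a.N)
        pool = PopulationState(
            gametes_A.generation,
            np.concatenate([gametes_A.alpha, gametes_a.alpha[perm]], axis=1),
            np.concatenate([gametes_A.kappa, gametes_a.kappa[perm]], axis=1),
        )
    return _repopulate(pool, n, rng)


# ---------------------------------------------------------------------------
# one generation, and whole runs


def advance_generation(
    pop: PopulationState, config: SimulationConfig, rng: np.random.Generator
) -> PopulationState:
    """Run one complete life cycle: mutation, selection, gametogenesis, mating.

    Under uniparental inheritance the a-gamete's cytoplasmic content is
    discarded during mating, so the engine does not sample it.
    """
    return _advance_in_place(
        PopulationState(pop.generation, pop.alpha.copy(), pop.kappa.copy()), config, rng
    )


def _advance_in_place(
    pop: PopulationState, config: SimulationConfig, rng: np.random.Generator
) -> PopulationState:
    """As :func:`advance_generation`, but may mutate the input arrays."""
    mutate_population(pop, config, rng)
    pop = select_hosts(pop, make_cell_fitness(config.fitness), rng)
    gametes_A = _sample_gamete_pool(pop, config.b, rng)
    if config.inheritance == "uniparental":
        offspring = _repopulate(gametes_A, config.n, rng)
    else:
        gametes_a = _sample_gamete_pool(pop, config.b, rng)
        offspring = mate_and_repopulate(gametes_A, gametes_a, "biparental", config.n, rng)
    offspring.generation = pop.generation + 1
    return offspring


def _record_state(
    recorder: TrajectoryRecorder,
    pop: PopulationState,
    fitness_fn: Callable,
    level: str,
) -> None:
    alpha, kappa = pop.alpha, pop.kappa
    G = alpha.size
    x, y = pop.cell_loads()
    if level == "minimal":
        # means and population minima only; variance and class-level columns
        # carry NaN / 0 placeholders (long combined runs only need ratchet
        # minima and final mean loads)
        recorder.record(
            generation=pop.generation,
            mean_alpha=float(x.sum()) / G,
            mean_kappa=float(y.sum()) / G,
            min_alpha=int(alpha.min()),
            min_kappa=int(kappa.min()),
            within_cell_variance=float("nan"),
            between_cell_fitness_variance=float("nan"),
            n_classes=0,
            alpha_class_counts=None,
        )
        return
    w = fitness_fn(x, y)
    # one joint bincount over (alpha, kappa) keys yields the class table,
    # the alpha/kappa marginals and hence the population minima
    a_flat = alpha.reshape(-1)
    k_flat = kappa.reshape(-1)
    k_max = int(k_flat.max()) if y.any() else 0
    if k_max:
        joint = np.bincount(a_flat.astype(np.int32) * (k_max + 1) + k_flat)
        width = k_max + 1
        pad = (-len(joint)) % width
        marginal = np.pad(joint, (0, pad)).reshape(-1, width)
        a_counts = marginal.sum(axis=1)
        k_counts = marginal.sum(axis=0)
        min_kappa = int(np.nonzero(k_counts)[0][0])
    else:
        joint = a_counts = np.bincount(a_flat)
        min_kappa = 0
    recorder.record(
        generation=pop.generation,
        mean_alpha=float(x.sum()) / G,
        mean_kappa=float(y.sum()) / G,
        min_alpha=int(np.nonzero(a_counts)[0][0]),
        min_kappa=min_kappa,
        within_cell_variance=float(alpha.var(axis=1).mean()),
        between_cell_fitness_variance=float(w.var()),
        n_classes=int(np.count_nonzero(joint)),
        alpha_class_counts=a_counts if level == "full" else None,
    )


def run_simulation(config: SimulationConfig, record: str = "full") -> Trajectory:
    """Run one replicate to its stop rule and return the trajectory.

    The run is fully determined by ``config`` (including its seed).  Under
    ``all_genomes_reach_gamma`` the run stops once every genome in the
    population carries at least ``gamma`` beneficial substitutions; hitting
    ``max_generations`` first flags the trajectory as truncated instead of
    raising.

    ``record`` controls per-generation detail: ``"full"`` stores the class
    table, variances and class counts; ``"summary"`` drops the class table;
    ``"minimal"`` keeps only mean and minimum loads (the inputs of ratchet
    and adaptive-ratio statistics), roughly halving the cost of long runs.
    """
    if record not in ("full", "summary", "minimal"):
        raise ValueError(f"unknown record level {record!r}")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    fitness_fn = make_cell_fitness(config.fitness)
    recorder = TrajectoryRecorder(
        engine="cytoplasmic",
        config=config.to_dict(),
        seed=config.seed,
        record_class_counts=(record == "full"),
    )
    pop = PopulationState.founding(config.N, config.n)
    _record_state(recorder, pop, fitness_fn, record)
    stop_reason, truncated = "max_generations", False
    while pop.generation < config.max_generations:
        # the loop owns `pop`, so the in-place variant is safe here
        pop = _advance_in_place(pop, config, rng)
        _record_state(recorder, pop, fitness_fn, record)
        if pop.generation % 100 == 0 and logger.isEnabledFor(logging.INFO):
            r = recorder._rows
            logger.info(
                "gen %d: mean_alpha=%.3f mean_kappa=%.3f n_classes=%d",
                pop.generation, r["mean_alpha"][-1], r["mean_kappa"][-1],
                r["n_classes"][-1],
            )
        if config.stop_rule == "all_genomes_reach_gamma" and int(pop.alpha.min()) >= config.gamma:
            stop_reason = "gamma_reached"
            break
    else:
        if config.stop_rule == "all_genomes_reach_gamma":
            truncated = True
    return recorder.finish(stop_reason, truncated)
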