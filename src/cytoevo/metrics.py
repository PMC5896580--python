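"""Statistics computed from simulation trajectories.

This layer turns per-generation trajectory records into the quantities used
to compare inheritance regimes:

* **drift / selection phases** of each beneficial substitution class, with
  loss and regain probabilities during the drift phase;
* **generations per beneficial substitution** (speed of adaptation);
* **sweep statistics**: the mean wild-type decline slope ``m_g`` (percent per
  generation) and the mean number of co-existing genome classes ``c_g``
  (a proxy for clonal interference);
* **ratchet events**: losses of the least-loaded genome class (a deleterious
  ratchet is a click of Muller's ratchet; a beneficial ratchet is the same
  construct on the beneficial axis);
* the **genetic hitchhiking index** ``phi``: mean forward gap from each
  beneficial ratchet to the next deleterious ratchet, divided by the gap
  expected if deleterious ratchets were placed uniformly at random in time
  (``phi < 1`` indicates hitchhiking of deleterious substitutions on
  selective sweeps);
* the **adaptive-evolution ratio**: mean beneficial per deleterious
  substitutions per genome at a fixed horizon, averaged over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import PopulationState, make_cell_fitness
from .fitness import FitnessSpec
from .trajectory import Trajectory

__all__ = [
    "PhaseRecord",
    "RatchetEvent",
    "HitchhikingResult",
    "SweepStats",
    "AdaptiveRatioResult",
    "compute_phases",
    "mean_phase_lengths",
    "loss_regain_probabilities",
    "generations_per_substitution",
    "sweep_stats",
    "detect_ratchets",
    "hitchhiking_index",
    "pooled_hitchhiking_index",
    "adaptive_ratio",
    "variance_panels",
    "write_summary_tables",
]


# ---------------------------------------------------------------------------
# drift / selection phases


@dataclass
class PhaseRecord:
    """Phase decomposition for one beneficial substitution class ``alpha``.

    The drift phase runs from the first observation of a genome with
    ``alpha`` substitutions (``first_seen``) to the start of its final
    uninterrupted presence (``persist_start``); the selection phase runs from
    there to the first observation of the ``alpha + 1`` class
    (``next_class_seen``).  Presence is evaluated as "any genome with at
    least ``alpha`` substitutions", so onward mutation cannot spuriously
    extinguish a class.
    """

    alpha: int
    first_seen: int
    persist_start: int | None
    next_class_seen: int | None
    n_losses: int
    n_regains: int

    @property
    def drift_length(self) -> int | None:
        if self.persist_start is None:
            return None
        return self.persist_start - self.first_seen

    @property
    def selection_length(self) -> int | None:
        if self.persist_start is None or self.next_class_seen is None:
            return None
        return self.next_class_seen - self.persist_start


def _max_alpha_series(trajectory: Trajectory) -> np.ndarray:
    if trajectory.alpha_class_counts is None:
        raise ValueError("trajectory was recorded without class counts")
    return np.array(
        [int(np.nonzero(c)[0].max()) for c in trajectory.alpha_class_counts], dtype=np.int64
    )


def compute_phases(trajectory: Trajectory) -> list[PhaseRecord]:
    """One :class:`PhaseRecord` per beneficial class observed in the run.

    Classes never reached are absent.  For the highest class observed,
    ``next_class_seen`` is ``None`` and ``persist_start`` is only defined if
    the class is present at the end of the run.
    """
    amax = _max_alpha_series(trajectory)
    gens = trajectory.generation
    records: list[PhaseRecord] = []
    for a in range(1, int(amax.max()) + 1):
        present = amax >= a
        idx_first = int(np.argmax(present))
        next_idx = None
        above = amax >= a + 1
        if above.any():
            next_idx = int(np.argmax(above))
        # persist_start: start of the presence run containing next_class_seen
        # (or the end of the trajectory if alpha+1 never appears).
        anchor = next_idx if next_idx is not None else len(present) - 1
        persist_idx: int | None = None
        if present[anchor]:
            t = anchor
            while t > idx_first and present[t - 1]:
                t -= 1
            persist_idx = t
        window_end = persist_idx if persist_idx is not None else anchor
        window = present[idx_first : window_end + 1]
        flips = np.diff(window.astype(np.int8))
        records.append(
            PhaseRecord(
                alpha=a,
                first_seen=int(gens[idx_first]),
                persist_start=int(gens[persist_idx]) if persist_idx is not None else None,
                next_class_seen=int(gens[next_idx]) if next_idx is not None else None,
                n_losses=int((flips == -1).sum()),
                n_regains=int((flips == 1).sum()),
            )
        )
    return records


def mean_phase_lengths(records: list[PhaseRecord]) -> tuple[float | None, float | None]:
    """Mean (drift, selection) phase lengths, excluding ``alpha = 1``.

    The dynamics of the first class are dominated by the substitution-free
    starting conditions, so it is left out of aggregate means.  So is the
    highest class observed while its selection phase is incomplete: until
    ``alpha + 1`` appears, the drift phase's end is only provisional.
    """
    complete = [r for r in records if r.alpha != 1 and r.next_class_seen is not None]
    drift = [r.drift_length for r in complete if r.drift_length is not None]
    sel = [r.selection_length for r in complete if r.selection_length is not None]
    return (
        float(np.mean(drift)) if drift else None,
        float(np.mean(sel)) if sel else None,
    )


def loss_regain_probabilities(
    trajectory: Trajectory, alpha: int
) -> tuple[float | None, float | None]:
    """Per-generation loss and regain probabilities during the drift phase.

    ``P(lose alpha)`` is the number of loss events divided by the number of
    drift-phase generations in which the class is present; ``P(regain
    alpha)`` is the number of reappearances divided by the number of
    drift-phase generations in which it is absent (after first appearance).
    Either probability is ``None`` when it has no at-risk generations.
    """
    recs = {r.alpha: r for r in compute_phases(trajectory)}
    if alpha not in recs:
        raise ValueError(f"class alpha={alpha} never appeared in this trajectory")
    rec = recs[alpha]
    if rec.persist_start is None:
        return None, None
    amax = _max_alpha_series(trajectory)
    gens = trajectory.generation
    in_window = (gens >= rec.first_seen) & (gens < rec.persist_start)
    present = (amax >= alpha) & in_window
    absent = (~(amax >= alpha)) & in_window
    losses = rec.n_losses
    regains = rec.n_regains
    p_lose = losses / present.sum() if present.sum() > 0 else None
    p_regain = regains / absent.sum() if absent.sum() > 0 else None
    return p_lose, p_regain


# ---------------------------------------------------------------------------
# speed of adaptation and sweep statistics


def generations_per_substitution(trajectory: Trajectory) -> float:
    """Stop generation divided by population-mean substitutions per genome.

    On a truncated run the value is computed over the truncated horizon (the
    trajectory carries the flag).
    """
    mean_alpha = float(trajectory.mean_alpha[-1])
    if mean_alpha <= 0.0:
        raise ValueError("no beneficial substitutions accumulated; rate undefined")
    return float(trajectory.generation[-1]) / mean_alpha


@dataclass
class SweepStats:
    """Clonal-interference summary of one run.

    ``m_g``: mean decline slope of near-fixed ("wild type") classes, in
    percent per generation (negative; ``None`` if no class ever neared
    fixation).  ``c_g``: mean number of genome classes co-existing per
    generation.
    """

    m_g: float | None
    c_g: float
    n_sweeps: int
    durations: list[int] = field(default_factory=list)


def sweep_stats(trajectory: Trajectory, high: float = 1.0, low: float = 0.005) -> SweepStats:
    """Wild-type decline slope and co-existing class count.

    Every beneficial class whose frequency reaches ``high`` (by default full
    fixation, 100%) becomes a wild type whose decline is measured: the
    duration runs from its last generation at or above ``high`` to its first
    subsequent generation below ``low`` (0.5%), so with the defaults
    ``m_g = -99.5 / mean(durations)`` in percent per generation.  Declines
    still above ``low`` when the run ends are censored and excluded.
    ``c_g`` averages the per-generation number of classes present (distinct
    beneficial classes in beneficial-only runs; distinct ``(alpha, kappa)``
    classes otherwise).
    """
    freq = trajectory.frequency_matrix()
    gens = trajectory.generation
    durations: list[int] = []
    for a in range(freq.shape[1]):
        col = freq[:, a]
        high_idx = np.nonzero(col >= high)[0]
        if len(high_idx) == 0:
            continue
        t_high = high_idx[-1]
        low_idx = np.nonzero(col[t_high:] < low)[0]
        if len(low_idx) == 0:
            continue  # censored: run ended mid-decline
        durations.append(int(gens[t_high + low_idx[0]] - gens[t_high]))
    m_g = -100.0 * (high - low) / float(np.mean(durations)) if durations else None
    return SweepStats(
        m_g=m_g,
        c_g=float(trajectory.n_classes.mean()),
        n_sweeps=len(durations),
        durations=durations,
    )


# ---------------------------------------------------------------------------
# ratchets and the hitchhiking index


@dataclass(frozen=True)
class RatchetEvent:
    """Loss of the least-loaded genome class at ``generation``.

    ``kind`` is "beneficial" when the population-minimum beneficial count
    increased, "deleterious" when the minimum deleterious count increased (a
    click of Muller's ratchet).  A jump of the minimum by more than one in a
    single generation is still one event; ``jump`` records the step size.
    """

    kind: str
    generation: int
    jump: int = 1


def detect_ratchets(trajectory: Trajectory) -> list[RatchetEvent]:
    """All ratchet events of a run, ordered by generation."""
    events: list[RatchetEvent] = []
    gens = trajectory.generation
    for kind, series in (("beneficial", trajectory.min_alpha), ("deleterious", trajectory.min_kappa)):
        steps = np.diff(series)
        for t in np.nonzero(steps > 0)[0]:
            events.append(RatchetEvent(kind, int(gens[t + 1]), int(steps[t])))
    events.sort(key=lambda e: e.generation)
    return events


@dataclass
class HitchhikingResult:
    """Hitchhiking index of one run.

    ``pairs`` holds, per beneficial ratchet, ``(generation, gap, censored)``
    where ``gap`` is the number of generations to the first deleterious
    ratchet at or after it (same-generation pairs have gap 0).  Beneficial
    ratchets with no subsequent deleterious ratchet are censored and
    contribute their open gap ``T - generation``.  ``expected_gap = T / D``
    is the forward waiting time if the ``D`` deleterious ratchets were
    placed uniformly at random over the ``T`` generations; ``phi =
    observed_mean_gap / expected_gap``.  ``phi_uncensored`` repeats the
    calculation with censored pairs dropped.
    """

    pairs: list[tuple[int, int, bool]]
    observed_mean_gap: float | None
    expected_gap: float | None
    phi: float | None
    phi_uncensored: float | None
    n_censored: int

    @property
    def pair_indices(self) -> list[float]:
        """Per-pair index values gap / expected_gap (censored pairs included)."""
        if self.expected_gap is None or self.expected_gap == 0.0:
            return []
        return [gap / self.expected_gap for _, gap, _ in self.pairs]


def hitchhiking_index(events: list[RatchetEvent], T: int) -> HitchhikingResult:
    """Compute the hitchhiking index ``phi`` from a run's ratchet events.

    ``T`` is the total number of generations in the run.  With no
    deleterious ratchets ``phi`` is undefined (``None``); with no beneficial
    ratchets there are no pairs and ``phi`` is likewise ``None``.
    """
    if T < 1:
        raise ValueError("T must be at least 1")
    ben = np.array([e.generation for e in events if e.kind == "beneficial"], dtype=np.int64)
    dele = np.array(
        sorted(e.generation for e in events if e.kind == "deleterious"), dtype=np.int64
    )
    D = len(dele)
    pairs: list[tuple[int, int, bool]] = []
    for g in ben:
        j = np.searchsorted(dele, g, side="left")
        if j < D:
            pairs.append((int(g), int(dele[j] - g), False))
        else:
            pairs.append((int(g), int(T - g), True))
    n_censored = sum(1 for p in pairs if p[2])
    if D == 0 or not pairs:
        return HitchhikingResult(pairs, None, None, None, None, n_censored)
    expected = T / D
    observed = float(np.mean([gap for _, gap, _ in pairs]))
    open_gaps = [gap for _, gap, cens in pairs if not cens]
    phi_unc = float(np.mean(open_gaps)) / expected if open_gaps else None
    return HitchhikingResult(pairs, observed, expected, observed / expected, phi_unc, n_censored)


def pooled_hitchhiking_index(
    events_per_replicate: list[list[RatchetEvent]], T: int
) -> HitchhikingResult:
    """Regime-level ``phi`` pooled over replicate runs of ``T`` generations each.

    Gaps are measured within each replicate (a beneficial ratchet never pairs
    with a deleterious ratchet from another run, and censored pairs
    contribute their open gap as usual), but the uniform-placement
    expectation uses the pooled event density: ``expected_gap = (R * T) /
    total deleterious ratchets``.  This keeps ``phi`` defined for regimes in
    which individual replicates may see no deleterious ratchet at all.
    """
    pairs: list[tuple[int, int, bool]] = []
    D_total = 0
    for events in events_per_replicate:
        dele = np.array(
            sorted(e.generation for e in events if e.kind == "deleterious"), dtype=np.int64
        )
        D_total += len(dele)
        for e in events:
            if e.kind != "beneficial":
                continue
            j = np.searchsorted(dele, e.generation, side="left")
            if j < len(dele):
                pairs.append((e.generation, int(dele[j] - e.generation), False))
            else:
                pairs.append((e.generation, int(T - e.generation), True))
    n_censored = sum(1 for p in pairs if p[2])
    if D_total == 0 or not pairs:
        return HitchhikingResult(pairs, None, None, None, None, n_censored)
    expected = len(events_per_replicate) * T / D_total
    observed = float(np.mean([gap for _, gap, _ in pairs]))
    open_gaps = [gap for _, gap, cens in pairs if not cens]
    phi_unc = float(np.mean(open_gaps)) / expected if open_gaps else None
    return HitchhikingResult(pairs, observed, expected, observed / expected, phi_unc, n_censored)


# ---------------------------------------------------------------------------
# adaptive-evolution ratio and variance panels


@dataclass
class AdaptiveRatioResult:
    """Mean over replicates of (mean alpha per genome) / (mean kappa per genome)."""

    mean: float | None
    sem: float | None
    n_used: int
    n_excluded: int


def adaptive_ratio(final_states: list[tuple[float, float]]) -> AdaptiveRatioResult:
    """Adaptive-evolution ratio from per-replicate final mean loads.

    Each replicate contributes the ratio of its mean beneficial to mean
    deleterious substitutions per genome; replicates with zero deleterious
    load are excluded and counted.  The mean of ratios is not the ratio of
    means — aggregation order follows the per-replicate recipe.
    """
    ratios = [a / k for a, k in final_states if k > 0]
    n_excluded = len(final_states) - len(ratios)
    if not ratios:
        return AdaptiveRatioResult(None, None, 0, n_excluded)
    arr = np.asarray(ratios)
    sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return AdaptiveRatioResult(float(arr.mean()), sem, len(arr), n_excluded)


def write_summary_tables(
    runs: list[tuple[str, int, Trajectory]], out_dir
) -> dict[str, "object"]:
    """Write the per-run metric tables as tidy CSVs keyed by run and replicate.

    ``runs`` is a list of ``(run_id, replicate, trajectory)``.  Emits
    ``phases.csv`` (one row per phase record), ``ratchets.csv`` (one row per
    event), ``hitchhiking.csv`` (one row per beneficial/deleterious ratchet
    pair plus a ``phi`` footer row per run), ``sweeps.csv`` and
    ``panels.csv`` (per-generation variance time series).  Returns the
    tables as DataFrames keyed by file stem.
    """
    import pandas as pd
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    phases, ratchets, hitch, sweeps, panels = [], [], [], [], []
    for run_id, rep, traj in runs:
        key = {"run_id": run_id, "replicate": rep}
        if traj.alpha_class_counts is not None:
            for r in compute_phases(traj):
                phases.append({**key, **r.__dict__,
                               "drift_length": r.drift_length,
                               "selection_length": r.selection_length})
            s = sweep_stats(traj)
            sweeps.append({**key, "m_g": s.m_g, "c_g": s.c_g, "n_sweeps": s.n_sweeps})
        events = detect_ratchets(traj)
        for e in events:
            ratchets.append({**key, "kind": e.kind, "generation": e.generation,
                             "jump": e.jump})
        hh = hitchhiking_index(events, int(traj.generation[-1]))
        for g, gap, cens in hh.pairs:
            hitch.append({**key, "row": "pair", "generation": g, "gap": gap,
                          "censored": cens,
                          "pair_index": (gap / hh.expected_gap if hh.expected_gap else None)})
        hitch.append({**key, "row": "phi", "generation": None, "gap": None,
                      "censored": None, "pair_index": hh.phi})
        for t in range(len(traj.generation)):
            panels.append({**key, "generation": int(traj.generation[t]),
                           "within_cell_variance": float(traj.within_cell_variance[t]),
                           "between_cell_fitness_variance":
                               float(traj.between_cell_fitness_variance[t])})
    tables = {
        "phases": pd.DataFrame(phases),
        "ratchets": pd.DataFrame(ratchets),
        "hitchhiking": pd.DataFrame(hitch),
        "sweeps": pd.DataFrame(sweeps),
        "panels": pd.DataFrame(panels),
    }
    for stem, frame in tables.items():
        frame.to_csv(out / f"{stem}.csv", index=False)
    return tables


def variance_panels(
    pop_snapshot: PopulationState, fitness_spec: FitnessSpec
) -> tuple[float, float]:
    """(within-cell variance, between-cell fitness variance) of one snapshot.

    Within: the variance, across each cell's genome copies, of the per-copy
    beneficial substitution count, averaged over cells (population-variance
    convention).  Between: the variance of cell fitness across the
    population.
    """
    within = float(pop_snapshot.alpha.var(axis=1).mean())
    x, y = pop_snapshot.cell_loads()
    w = make_cell_fitness(fitness_spec)(x, y)
    return within, float(w.var())
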