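"""Host-engine tests: stage contracts, sampling oracles, whole-run invariants."""

import itertools

import numpy as np
import pytest
from scipy import stats

import cytoevo as ce
from cytoevo.core import (
    CellState,
    ExtinctionError,
    GenomeClass,
    PopulationState,
    gametogenesis,
    make_cell_fitness,
    mate_and_repopulate,
    mutate_cell,
    mutate_population,
    select_hosts,
)


def small_fitness(s_b=0.1, **kw):
    kw.setdefault("s_d", 0.0)
    kw.setdefault("beneficial_shape", "linear")
    kw.setdefault("deleterious_shape", "linear")
    kw.setdefault("n_ref", 10)
    kw.setdefault("gamma_ref", 3)
    return ce.FitnessSpec(s_b=s_b, **kw)


def small_config(**kw):
    base = dict(
        N=50, n=10, b=5, l=500, mu_b=1e-4, mu_d=0.0,
        fitness=small_fitness(), inheritance="uniparental",
        stop_rule="fixed_generations", max_generations=50, gamma=3, seed=0,
    )
    base.update(kw)
    return ce.SimulationConfig(**base)


class TestMutation:
    def test_zero_rate_identity(self, rng):
        cell = CellState({GenomeClass(1, 0): 3, GenomeClass(0, 2): 7}, 10)
        assert mutate_cell(cell, 1000, 0.0, 0.0, rng) is cell

    def test_rates_exceeding_one_rejected(self, rng):
        cell = CellState.homoplasmic(GenomeClass(0, 0), 4)
        with pytest.raises(ValueError):
            mutate_cell(cell, 100, 0.6, 0.6, rng)

    def test_per_copy_binomial_mean(self, rng):
        # per copy, new substitutions ~ Binomial(l, mu): mean l*mu
        cell = CellState.homoplasmic(GenomeClass(0, 0), 2000)
        l, mu = 1000, 1e-3
        totals = []
        for _ in range(5):
            out = mutate_cell(cell, l, mu, 0.0, rng)
            totals.append(sum(gc.alpha * c for gc, c in out.class_counts.items()))
        mean = np.mean(totals) / 2000
        se = np.sqrt(l * mu / (2000 * 5))
        assert abs(mean - l * mu) < 4 * se

    def test_population_rate_matches_binomial_tail(self, rng):
        # fraction of genomes hit by >=1 deleterious mutation ~ 1 - (1-mu)^l
        pop = PopulationState.founding(10_000, 100)  # 1e6 genomes
        config = small_config(N=10_000, n=100, l=20_000, mu_b=0.0, mu_d=1e-7, b=50)
        mutate_population(pop, config, rng)
        frac = np.count_nonzero(pop.kappa) / pop.kappa.size
        p = 1.0 - (1.0 - 1e-7) ** 20_000
        se = np.sqrt(p * (1 - p) / pop.kappa.size)
        assert abs(frac - p) < 4 * se

    def test_population_mean_matches_l_mu(self, rng):
        pop = PopulationState.founding(10_000, 100)
        config = small_config(N=10_000, n=100, l=20_000, mu_b=1e-8, mu_d=0.0, b=50)
        mutate_population(pop, config, rng)
        mean = pop.alpha.sum() / pop.alpha.size
        expect = 20_000 * 1e-8
        se = np.sqrt(expect / pop.alpha.size)
        assert abs(mean - expect) < 4 * se

    def test_copy_number_unchanged(self, rng):
        cell = CellState.homoplasmic(GenomeClass(0, 0), 50)
        out = mutate_cell(cell, 1000, 1e-3, 1e-3, rng)
        assert sum(out.class_counts.values()) == 50


class TestSelection:
    def test_identical_cells_fixed_point(self, rng):
        pop = PopulationState(3, np.full((20, 5), 2, dtype=np.int16), np.zeros((20, 5), np.int16))
        out = select_hosts(pop, make_cell_fitness(small_fitness()), rng)
        assert np.array_equal(out.alpha, pop.alpha)
        assert out.generation == 3  # within-generation stage

    def test_proportional_sampling(self, rng):
        # fitness 0.9 vs 0.45: the fitter cell takes 2/3 of slots in expectation
        alpha = np.array([[1], [0]], dtype=np.int16)
        pop = PopulationState(0, alpha, np.zeros((2, 1), np.int16))
        fn = lambda x, y: np.where(x > 0, 0.9, 0.45)
        hits = total = 0
        for _ in range(3000):
            out = select_hosts(pop, fn, rng)
            hits += int(out.alpha.sum())
            total += 2
        se = np.sqrt((2 / 3) * (1 / 3) / total)
        assert abs(hits / total - 2 / 3) < 4 * se

    def test_two_cell_composition_matches_multinomial(self, rng):
        # N=2, fitness (1.0, 0.9): offspring composition ~ Multinomial probabilities
        alpha = np.array([[1], [0]], dtype=np.int16)
        pop = PopulationState(0, alpha, np.zeros((2, 1), np.int16))
        w = np.array([1.0, 0.9])
        fn = lambda x, y: w
        p = w[0] / w.sum()
        expected = np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
        counts = np.zeros(3)
        n_draws = 20_000
        for _ in range(n_draws):
            out = select_hosts(pop, fn, rng)
            counts[2 - int(out.alpha.sum())] += 1  # index by number of fitter cells
        chi = stats.chisquare(counts, expected * n_draws)
        assert chi.pvalue > 1e-3

    def test_extinction_error(self, rng):
        spec = ce.FitnessSpec(s_b=0.6, s_d=0.6, n_ref=2, gamma_ref=1)
        alpha = np.zeros((4, 2), dtype=np.int16)
        kappa = np.full((4, 2), 1, dtype=np.int16)  # saturated deleterious load
        pop = PopulationState(7, alpha, kappa)
        with pytest.raises(ExtinctionError) as err:
            select_hosts(pop, make_cell_fitness(spec), rng)
        assert err.value.generation == 7


class TestGametogenesis:
    def test_homoplasmic_parent(self, rng):
        cell = CellState.homoplasmic(GenomeClass(2, 1), 10)
        gA, ga = gametogenesis(cell, 5, rng)
        assert gA.class_counts == {GenomeClass(2, 1): 5}
        assert ga.class_counts == {GenomeClass(2, 1): 5}
        assert (gA.mating_type, ga.mating_type) == ("A", "a")

    def test_two_copy_parent_loss_probability(self, rng):
        # n=2 with one mutant, b=2: P(gamete carries no mutant) = 1/4
        cell = CellState({GenomeClass(1, 0): 1, GenomeClass(0, 0): 1}, 2)
        misses = 0
        n_draws = 20_000
        for _ in range(n_draws):
            gA, _ = gametogenesis(cell, 2, rng)
            if GenomeClass(1, 0) not in gA.class_counts:
                misses += 1
        se = np.sqrt(0.25 * 0.75 / n_draws)
        assert abs(misses / n_draws - 0.25) < 4 * se

    def test_bottleneck_binomial_mean(self, rng):
        # 10 mutant copies of 50, b=5: mutant count ~ Binomial(5, 0.2)
        cell = CellState({GenomeClass(1, 0): 10, GenomeClass(0, 0): 40}, 50)
        counts = []
        for _ in range(5000):
            gA, _ = gametogenesis(cell, 5, rng)
            counts.append(gA.class_counts.get(GenomeClass(1, 0), 0))
        mean = np.mean(counts)
        se = np.sqrt(5 * 0.2 * 0.8 / len(counts))
        assert abs(mean - 1.0) < 4 * se


class TestMating:
    def test_uniparental_ignores_a_gamete(self, rng):
        A = PopulationState(0, np.full((30, 2), 3, np.int16), np.zeros((30, 2), np.int16))
        a = PopulationState(0, np.zeros((30, 2), np.int16), np.full((30, 2), 9, np.int16))
        out = mate_and_repopulate(A, a, "uniparental", 4, rng)
        assert np.all(out.alpha == 3) and np.all(out.kappa == 0)

    def test_biparental_same_class_homoplasmic(self, rng):
        A = PopulationState(0, np.full((30, 2), 3, np.int16), np.zeros((30, 2), np.int16))
        out = mate_and_repopulate(A, A, "biparental", 6, rng)
        assert np.all(out.alpha == 3)

    def test_biparental_mixture_binomial(self, rng):
        # A gametes all class X (alpha=1), a gametes all class Y (alpha=0):
        # offspring X-count ~ Binomial(n, 1/2)
        N, b, n = 20_000, 5, 10
        A = PopulationState(0, np.ones((N, b), np.int16), np.zeros((N, b), np.int16))
        a = PopulationState(0, np.zeros((N, b), np.int16), np.zeros((N, b), np.int16))
        out = mate_and_repopulate(A, a, "biparental", n, rng)
        counts = out.alpha.sum(axis=1)
        se_mean = np.sqrt(n * 0.25 / N)
        assert abs(counts.mean() - n / 2) < 4 * se_mean
        assert abs(counts.var() - n * 0.25) < 0.1

    def test_mismatched_pools_rejected(self, rng):
        A = PopulationState(0, np.zeros((4, 2), np.int16), np.zeros((4, 2), np.int16))
        a = PopulationState(0, np.zeros((3, 2), np.int16), np.zeros((3, 2), np.int16))
        with pytest.raises(ValueError):
            mate_and_repopulate(A, a, "biparental", 4, rng)


def enumerate_bpi_offspring_distribution(w0, w1):
    """Exact offspring-composition distribution for the 2-cell instance.

    Start: cell0 carries copies alpha=[1, 0], cell1 alpha=[0, 0]; N=2, n=2,
    b=1, no mutation, biparental inheritance.  Returns probabilities of the
    unordered pair of per-cell mutant-copy counts.
    """
    p0 = w0 / (w0 + w1)
    parent_probs = {0: p0, 1: 1 - p0}
    gamete_mutant_prob = {0: 0.5, 1: 0.0}  # P(gamete copy is the mutant)
    dist: dict[tuple[int, int], float] = {}
    for p1, p2 in itertools.product((0, 1), repeat=2):
        p_sel = parent_probs[p1] * parent_probs[p2]
        for mA1, mA2, ma1, ma2 in itertools.product((0, 1), repeat=4):
            pg = 1.0
            for parent, m in ((p1, mA1), (p2, mA2), (p1, ma1), (p2, ma2)):
                q = gamete_mutant_prob[parent]
                pg *= q if m else 1 - q
            if pg == 0.0:
                continue
            for perm_swap in (False, True):
                pools = (
                    ((mA1, ma2), (mA2, ma1)) if perm_swap else ((mA1, ma1), (mA2, ma2))
                )
                # each offspring draws 2 copies with replacement from its 2-copy pool
                per_cell = []
                for pool in pools:
                    q = sum(pool) / 2
                    per_cell.append({0: (1 - q) ** 2, 1: 2 * q * (1 - q), 2: q * q})
                for c1, c2 in itertools.product((0, 1, 2), repeat=2):
                    key = tuple(sorted((c1, c2)))
                    prob = p_sel * pg * 0.5 * per_cell[0][c1] * per_cell[1][c2]
                    dist[key] = dist.get(key, 0.0) + prob
    return dist


class TestFullGenerationOracle:
    """Exhaustive enumeration of the N=2, n=2, b=1 one-generation distribution."""

    def make_pop(self):
        alpha = np.array([[1, 0], [0, 0]], dtype=np.int16)
        return PopulationState(0, alpha, np.zeros((2, 2), np.int16))

    def config(self, inheritance):
        return small_config(
            N=2, n=2, b=1, mu_b=0.0, mu_d=0.0, inheritance=inheritance,
            fitness=ce.FitnessSpec(s_b=0.5, s_d=0.0, beneficial_shape="linear",
                                   deleterious_shape="linear", n_ref=2, gamma_ref=1),
        )

    def test_uniparental_matches_enumeration(self, rng):
        # offspring are homoplasmic copies of their A-gamete: number of
        # mutant cells ~ Binomial(2, P(parent=cell0) * 1/2)
        config = self.config("uniparental")
        w0, w1 = 0.75, 0.5  # linear fitness at loads 1 and 0 with X=2
        p = (w0 / (w0 + w1)) * 0.5
        expected = {0: (1 - p) ** 2, 1: 2 * p * (1 - p), 2: p * p}
        counts = {0: 0, 1: 0, 2: 0}
        n_runs = 20_000
        for _ in range(n_runs):
            out = ce.advance_generation(self.make_pop(), config, rng)
            mutant_cells = int((out.alpha.sum(axis=1) == 2).sum())
            counts[mutant_cells] += 1
        chi = stats.chisquare(
            [counts[k] for k in (0, 1, 2)], [expected[k] * n_runs for k in (0, 1, 2)]
        )
        assert chi.pvalue > 1e-3

    def test_biparental_matches_enumeration(self, rng):
        config = self.config("biparental")
        dist = enumerate_bpi_offspring_distribution(0.75, 0.5)
        assert sum(dist.values()) == pytest.approx(1.0)
        n_runs = 20_000
        counts = {k: 0 for k in dist}
        for _ in range(n_runs):
            out = ce.advance_generation(self.make_pop(), config, rng)
            key = tuple(sorted(out.alpha.sum(axis=1).tolist()))
            counts[key] += 1
        keys = sorted(dist)
        chi = stats.chisquare([counts[k] for k in keys], [dist[k] * n_runs for k in keys])
        assert chi.pvalue > 1e-3


class TestWholeRuns:
    def test_conservation_after_each_generation(self, rng):
        config = small_config(mu_d=1e-4)
        pop = PopulationState.founding(config.N, config.n)
        for _ in range(5):
            pop = ce.advance_generation(pop, config, rng)
            assert pop.alpha.shape == (config.N, config.n)

    def test_neutral_mean_alpha_is_martingale(self, rng):
        # mu=0, equal fitness: expected population-mean alpha is conserved
        alpha0 = np.array([[1, 0], [0, 0], [2, 0]], dtype=np.int16)
        config = small_config(N=3, n=2, b=1, mu_b=0.0, fitness=small_fitness(s_b=0.0))
        start_mean = alpha0.mean()
        outs = []
        for _ in range(4000):
            pop = PopulationState(0, alpha0.copy(), np.zeros_like(alpha0))
            outs.append(ce.advance_generation(pop, config, rng).alpha.mean())
        sem = np.std(outs, ddof=1) / np.sqrt(len(outs))
        assert abs(np.mean(outs) - start_mean) < 4 * sem

    def test_neutral_molecular_clock(self):
        # with s=0, E[mean alpha at T] = T * l * mu_b and likewise for kappa
        T, l, mu_b, mu_d = 40, 1000, 1e-4, 2e-4
        finals_a, finals_k = [], []
        for seed in range(40):
            config = small_config(
                N=40, n=8, b=4, l=l, mu_b=mu_b, mu_d=mu_d,
                fitness=ce.FitnessSpec(s_b=0.0, s_d=0.0, beneficial_shape="linear",
                                       deleterious_shape="linear", n_ref=8, gamma_ref=3),
                max_generations=T, seed=seed,
            )
            traj = ce.run_simulation(config, record="minimal")
            finals_a.append(traj.mean_alpha[-1])
            finals_k.append(traj.mean_kappa[-1])
        for finals, mu in ((finals_a, mu_b), (finals_k, mu_d)):
            sem = np.std(finals, ddof=1) / np.sqrt(len(finals))
            assert abs(np.mean(finals) - T * l * mu) < 4 * sem + 0.01 * T * l * mu

    def test_min_loads_monotone(self):
        config = small_config(mu_b=2e-4, mu_d=2e-4, max_generations=150,
                              fitness=small_fitness(s_d=0.1), seed=21)
        traj = ce.run_simulation(config)
        assert np.all(np.diff(traj.min_alpha) >= 0)
        assert np.all(np.diff(traj.min_kappa) >= 0)

    def test_determinism(self):
        config = small_config(mu_d=1e-4, max_generations=60, seed=1234)
        t1 = ce.run_simulation(config)
        t2 = ce.run_simulation(config)
        assert t1.to_frame().equals(t2.to_frame())
        assert all(np.array_equal(a, b) for a, b in zip(t1.alpha_class_counts,
                                                        t2.alpha_class_counts))

    def test_unreachable_gamma_truncates(self):
        config = small_config(mu_b=0.0, stop_rule="all_genomes_reach_gamma",
                              max_generations=20)
        traj = ce.run_simulation(config)
        assert traj.truncated and traj.stop_reason == "max_generations"
        assert traj.generation[-1] == 20

    def test_gamma_stop(self):
        config = small_config(
            N=30, mu_b=5e-4, stop_rule="all_genomes_reach_gamma",
            gamma=1, max_generations=2000, seed=6,
        )
        traj = ce.run_simulation(config)
        assert traj.stop_reason == "gamma_reached"
        assert traj.min_alpha[-1] >= 1 and not traj.truncated


def test_config_validation():
    with pytest.raises(ValueError):
        small_config(b=6)  # b > n/2
    with pytest.raises(ValueError):
        small_config(mu_b=0.7, mu_d=0.7)
    with pytest.raises(ValueError):
        small_config(inheritance="maternal")
    # degenerate single-copy cell allowed for cross-engine checks
    assert ce.SimulationConfig(N=5, n=1, b=1, mu_b=0.0, mu_d=0.0).n == 1


def test_cell_state_validation():
    with pytest.raises(ValueError):
        CellState({GenomeClass(0, 0): 3}, 4)
    with pytest.raises(ValueError):
        CellState({GenomeClass(0, 0): 0}, 0)
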