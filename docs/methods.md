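# Methods

## Model

The host model is a discrete-generation Wright–Fisher process on two nested
levels.  The unit of selection is the diploid host cell; the unit of
inheritance is the cytoplasmic genome, present in `n` copies per cell.  A
genome is a pair of substitution counts `(alpha, kappa)`; sites are
exchangeable, every substitution of a kind has the same effect, there is no
back mutation, no recombination, no paternal leakage, and no within-cell
replication advantage (replication is host-controlled).  Generations do not
overlap, and the population size `N` is strictly constant: selection
resamples `N` cells with replacement each generation, and every cell
contributes one gamete of each mating type.

Each generation applies, in order: mutation, selection on hosts,
gametogenesis (bottleneck `b` copies per gamete, sampled with replacement),
and mating/repopulation (offspring draw `n` copies with replacement from
the fused gamete pool).  Trajectory records are taken immediately after
repopulation; the founding, substitution-free population is recorded as
generation 0.  Under uniparental inheritance only the maternal (mating type
A) gamete transmits cytoplasm, so pairing cannot influence offspring genome
content and the engine does not sample the paternal gamete pool; the
single-cell operation `gametogenesis` still returns both gametes.  Gamete
pairing is a uniform random matching of the two mating-type pools; a cell's
own two gametes may pair (probability 1/N) — the alternative would impose
an arbitrary derangement constraint on an event of vanishing consequence.

## Fitness

Cell fitness depends only on total loads `x = sum(alpha)`, `y = sum(kappa)`
over the cell's genomes.  Both axes are anchored at the same endpoints:
`w_b(0) = 1 - s_b`, `w_b(X) = 1`; `w_d(0) = 1`, `w_d(X) = 1 - s_d`, with
`X = n_ref * gamma_ref` (250 at the defaults).  Between the endpoints we
use the power family `u = min(x, X)/X`, `w_b = (1-s_b) + s_b * u**theta`
with `theta` = 2 (concave up), 1 (linear), 1/2 (concave down), and
`w_d = 1 - s_d * u**theta` with `theta` = 2 (concave down: the load barely
hurts until a high proportion of genomes is mutated) or 1 (linear).  These
forms were chosen as the simplest family matching the anchored endpoints
and the stated curvatures; the exponents are parameters of the shape table
in `cytoevo.fitness` if another family is wanted.  Loads beyond `X` clamp
at the endpoint — fitness cannot exceed 1 nor drop below `1 - s_d` along
one axis.  The axes combine additively as deviations from one,
`w = w_b + w_d - 1`, floored at 0 to keep sampling weights valid; note the
combined map at `x = 0` is the deleterious curve shifted down by the
beneficial baseline deficit `s_b`.

The free-living model uses the linear forms only, with every substitution's
fitness increment multiplied by `s_FL >= 1` and the same per-axis clamps.
With `s_FL = 1` a substitution on a free-living genome moves its cell's
fitness exactly as far as one substitution on a single cytoplasmic genome
moves its host's fitness (`s / X` on the linear map).

## Default parameters (the simulated conditions)

| parameter | default | meaning |
|---|---|---|
| `N` | 1000 | host cells |
| `n` | 50 | genome copies per cell |
| `b` | 25 / 5 | relaxed (`n/2`) / tight (`n/10`) bottleneck |
| `l` | 20,000 bp | genome length (animal-mtDNA scale) |
| `mu_d` | 1e-7 /site/gen | deleterious mutation rate |
| `mu_b` | 1e-8 (or 1e-9) | beneficial mutation rate |
| `s_b`, `s_d` | 0.01–0.1 | selection coefficients (small effects) |
| `gamma` | 5 | per-genome target; beneficial-only runs stop when min alpha >= gamma |
| horizon | 10,000 gen | deleterious-only and combined runs |
| `N_FL` | `N*n` or `N` | free-living population size |
| `s_FL` | 1–50 | free-living fitness scaling |

## Numerical implementation

The host population is stored as `(N, n)` integer arrays of per-copy
counts; every stage is a handful of vectorized draws, so a default-sized
generation costs about 1.5–2.5 ms.  Mutation draws the total number of new
substitutions of each kind as Binomial(`N*n*l`, mu) — the exact sum of the
per-copy binomials — and drops each event on a copy chosen uniformly with
replacement; relative to allocating events to distinct sites this differs
only through same-site collisions, an `O((l*mu)^2)` effect (~1e-7 per
genome-generation at the defaults).  The free-living engine stores genome
counts per `(alpha, kappa)` class: mutation moves Binomial(count,
`1-(1-mu)**l`) genomes per occupied class one step (a genome gaining two
substitutions of one kind in a single generation is neglected, again
`O((l*mu)^2)`), and selection is one multinomial draw weighted by
count × fitness, making even `N_FL = 50,000` runs cheap.  A run is fully
determined by its config and seed (PCG64 via `numpy.random.SeedSequence`);
replicate seeds are derived from a base seed, a run label and the replicate
index.  Long combined runs are recorded at a "minimal" level (per-generation
mean and minimum loads, the inputs of the ratchet and adaptive-ratio
statistics); full recording adds the class table and the within-cell /
between-cell variance panels.

Cross-engine consistency: the host engine run at `n = 1, b = 1` under
uniparental inheritance reduces exactly to the free-living life cycle, and
the suite checks distributional agreement of the two engines there.  The
config validator admits that degenerate case; otherwise `1 <= b <= n/2`.

## Analysis definitions

* **Phases.** The drift phase of class `alpha` runs from its first
  observation to the start of its final uninterrupted presence; the
  selection phase from there to the first observation of `alpha + 1`.
  Presence is evaluated as "any genome with >= alpha substitutions" so that
  onward mutation cannot spuriously extinguish a class, and the persistence
  point is found by walking back from the first sighting of `alpha + 1`
  through its unbroken presence run.  Aggregate phase lengths exclude
  `alpha = 1` (dominated by the substitution-free start) and the highest
  class observed (its drift end is provisional until `alpha + 1` arises).
  Loss/regain probabilities are event counts divided by at-risk generations
  within the drift window.
* **Sweeps.** Every class that reaches full fixation (frequency 1.0)
  becomes a wild type; its decline is timed from its last generation at
  fixation to its first generation below 0.5%, and
  `m_g = -99.5 / mean(duration)` %/generation.  Declines unfinished at the
  end of a run are censored and excluded.  Both thresholds are parameters;
  starting declines at 99.5% instead of 100% systematically steepens `m_g`
  for fast sweepers.  `c_g` is the mean per-generation count of classes
  present (beneficial classes in beneficial-only runs, `(alpha, kappa)`
  classes otherwise).
* **Ratchets.** A beneficial (deleterious) ratchet occurs in any generation
  where the population minimum of `alpha` (`kappa`) increases; a multi-step
  jump is one event with its size logged.
* **Hitchhiking index.** For each beneficial ratchet at generation `g`, the
  gap is the distance to the first deleterious ratchet at or after `g`
  (same-generation pairs count as gap 0); with no later deleterious ratchet
  the pair is censored and contributes its open gap `T - g`.  The
  expectation under uniform random placement of the `D` deleterious
  ratchets over `T` generations is the Poisson forward waiting time `T/D`,
  and `phi = mean(gap) / (T/D)`; a censored-excluded variant is reported
  alongside.  For a regime summarized over `R` replicates the pooled
  estimator keeps gaps within replicates but uses the pooled density,
  `expected = R*T / sum(D_r)` — this stays defined when single replicates
  (typically uniparental with a tight bottleneck) see no deleterious
  ratchet at all.  On independent uniform event streams the index
  calibrates to 1 within ~2% (the residual bias is the finite-sample gap
  between `T/D` and the true mean forward wait).
* **Adaptive ratio.** Per replicate, mean alpha per genome divided by mean
  kappa per genome at the horizon; replicates with zero deleterious load
  are excluded and counted; the mean of ratios (not the ratio of means) is
  reported with its standard error.

## What the tests show, and at what scale

The oracle layer checks the machinery exactly: fitness endpoints to machine
precision, binomial means and tails of the mutation stage, multinomial
selection against exhaustive enumeration on an `N = 2, n = 2, b = 1`
instance, the neutral molecular clock `E[mean alpha at T] = T*l*mu_b`, and
the calibration of `phi` on synthetic streams.  The end-to-end layer
re-runs the default conditions at reduced replication — chosen to keep the
default suite within a desktop budget — and compares recomputed statistics
with reference values: 20 replicates for the uniparental speed of
adaptation (±15% of 272 generations per substitution) and for each
directional ordering, 3–5 replicates for the per-engine sweep statistics
(±20%), and 10 replicates × 4 regimes × 10,000 generations for the
combined-model hitchhiking check.  Two orderings use shortened horizons
where the contrast is already decisive: biparental speed-of-adaptation
rates are estimated on a 3,000-generation cap (the rate estimate from a
truncated run is slightly optimistic but the UPI < BPI-tight < BPI-relaxed
gaps are several-fold), and the deleterious-load ordering is tested at
generation 1,200 rather than 10,000 (the UPI < BPI-tight < BPI-relaxed
separation is many standard errors wide well before then).  The
adaptive-ratio ordering shares the combined-model pool (10 replicates per
regime) and is compared on log-ratios: per-replicate ratios inherit heavy
right skew from small mean-kappa denominators, which the log scale removes.

Passing these tests shows the engine reproduces the model's expected
behaviour under the model's own idealizations.  It does not, and cannot,
validate those idealizations against real organelle biology: equal-effect
substitutions, no site structure, no selfish replication, single-celled
hosts and strict mating-type symmetry are all assumptions of the simulated
world.

## Known limitations

* Substitution counts use 16-bit integers; runs pushing per-genome counts
  past ~3×10^4 would need a wider dtype.
* `phi` has no analytic confidence interval here; uncertainty comes from
  replicate scatter (bootstrap over replicates if needed).
* The free-living engine's per-class mutation step ignores double hits of
  one genome within a single generation (see above); at mutation rates
  orders of magnitude above the defaults this would bias the clock.
* `run_grid` executes replicates serially; full 500-replicate grids are
  better driven externally.
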