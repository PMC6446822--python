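# Methods

## Model structure

`ridlsim` simulates discrete, non-overlapping generations of a
two-locus insect population in networks of fully connected cages
("subpopulations"). The state is a `SexedCohort`: integer counts per
(genotype, sex), with 9 genotypes from the cross of a biallelic
Cry1Ac-resistance locus (R/S) and the self-limiting construct insertion
site (L/w). The loci are treated as unlinked (free recombination): the
resistance allele and the construct enter the system in different
strains, and no linkage is modelled or configurable.

Within one generation, each cage executes in order:

1. **Refuge assignment** — homogeneous (one fraction everywhere) or
   heterogeneous (a fresh uniform permutation of a fixed list of
   fractions across cages each generation).
2. **Release** (from `release_start_generation`, default 1) — LLSS
   males are added to the mating pool at `base_ratio` per local male
   ("everywhere"), or at `base_ratio × whack_multiplier` into the
   single cage with the most toxin-diet survivors in the previous
   generation ("whack-a-mole"). The multiplier (default 3, i.e. 12:1
   vs 4:1) standardizes the total budget across strategies when cage
   sizes are equal. The target is scored on pre-dispersal cage counts;
   ties, and the all-zero case, are broken uniformly at random (a
   config flag can skip the release instead, and a persistent-target
   variant pins the release to a fixed cage). Released males join
   mating but are never dispersed.
3. **Mating and laying** — each female takes one mate, drawn with
   probability proportional to male counts, and lays a
   Poisson(`eggs_per_female`) clutch; egg genotypes follow the
   Mendelian cross, egg sex is Bernoulli(`sex_ratio`). Females of one
   genotype are aggregated: fathers drawn multinomially, and eggs per
   (mother, father) class drawn as Poisson(k·mean) — exactly the law of
   k independent females. Monandry is a simplification (the diamondback
   moth is polyandrous); allele-frequency expectations under random
   mating are unchanged by it.
4. **Egg allocation** — a bioassay sample is removed first (each egg
   independently with `bioassay_fraction`), then the remainder is
   assigned egg-by-egg to refuge diet with probability
   `refuge_fraction`, else toxin diet. The three parts partition the
   input exactly.
5. **Selection and pupation** — survival on toxin diet is
   `(0, h, 1)` by R-copy count (`h = 0` by default: the strict
   high-dose/recessive case; the dose is a label, not a kinetic
   model); survival on refuge diet is `refuge_survival ×
   (1 − fitness_cost_R)^r`. Off tetracycline, surviving females
   carrying the construct die at the larval stage, before the pupal
   census — lethality repression is delivered in the larval diet, so
   cage populations (reared without tetracycline) never produce
   transgenic female pupae. Survivors above `capacity × diet_fraction`
   are thinned by uniform without-replacement subsampling
   (multivariate hypergeometric — unbiased for genotype proportions).
6. **Census** — refuge and toxin pupae, allele frequencies, releases,
   the pooled per-replicate bioassay, and the whack target are recorded
   as one tidy row per cage.
7. **Dispersal** — `round(dispersal_fraction × total)` pupae leave each
   cage, drawn uniformly without replacement, and are split as evenly
   as possible between the other cages (odd remainders to receivers
   chosen by fair coin). Outflows are computed from pre-dispersal
   states, so network totals are conserved exactly.

A replicate whose network pupal count reaches zero is recorded as
extinct and its trajectory truncated; empty cages remain in the network
and can be recolonized by dispersal.

## Parameters and defaults

| parameter | default | units / meaning |
|---|---|---|
| `founder_pupae` | 200 | pupae per cage at generation 0 |
| `founder_r_freq` | 0.075 | initial R-allele frequency (founders at Hardy–Weinberg, all ww) |
| `generations` | 4 | generations 0..3; selection starts at 0, releases at 1 |
| `bioassay_fraction` | 0.10 | eggs removed for the diagnostic assay, before the diet split |
| `bioassay_n` | 100 / 150 | larvae tested per replicate (experiment 1 / 2) |
| `dispersal_fraction` | 0.10 | pupae shared among the other cages, before mating |
| `base_ratio` | 4 | released : local wild males (everywhere) |
| `whack_multiplier` | 3 | whack ratio = 12:1; preserves the total budget |
| refuges | 0.10; 0.12 vs {0.05, 0.10, 0.20} | experiment 1; experiment 2 homogeneous vs heterogeneous |
| `toxin_survival_by_r` | (0, 0, 1) | high-dose, recessive; `h` is configurable because resistance is only *near*-recessive |
| `refuge_survival` | 1.0 | shared baseline on toxin-free diet |
| `fitness_cost_R` | 0 | per-R-allele viability discount on refuge diet; costs are believed small and are off by default |
| `eggs_per_female` | 30 | mean Poisson fecundity; egg counts per cage were never reported, so this is a free parameter and all analytic anchor points are insensitive to it |
| `capacity_refuge`, `capacity_toxin` | 2000 | max pupae per unit diet fraction |
| `sex_ratio` | 0.5 | probability an egg is female |

The capacity model makes a cage's realized ceiling
`capacity_refuge·f + capacity_toxin·(1 − f)` *conditional on phenotypic
access*: a fully susceptible cage at a 10% refuge holds ~200 pupae (the
founder scale), while a resistant cage can grow tenfold because
resistance opens the toxin diet. This reproduces the qualitative
coupling between resistance and population size with the simplest
possible mechanism (hard truncation).

## The deterministic oracle

`ridlsim.oracle` transcribes the identical event order into expected
values for a single panmictic cage: per-sex genotype-frequency vectors
are advanced through random mating (a 9×9×9 offspring tensor), the diet
split, diet survival and female lethality; a release at ratio ρ enters
as a male-frequency injection `(m + ρ·δ_LLSS)/(1 + ρ)` before mating —
the expected-value analogue of adding ρ released males per local male.
A scalar scale tracks expected population size with per-diet capacity
caps, but the frequency recursion itself is density-free. The oracle
exists for verification and fast exploration, not for spatial
replication; the network case is handled by running cages with the
appropriate ratios.

Two consequences matter when comparing engine and oracle:

* **capacity truncation** is frequency-neutral only when it binds both
  diets proportionally; if the refuge cap binds while the toxin side
  does not, realized frequencies shift in the stochastic engine. The
  agreement tests therefore run with unbounded capacity.
* **extinction** — sustained 12:1 releases into one cage crush the
  population (tens of individuals within ~5 generations from 50,000
  founders); the infinite-population oracle cannot go extinct, so
  agreement is assessed over surviving runs, with a pooled-binomial
  error term covering generations where populations are tiny.

A second, exhaustive oracle (`brute_force_generation`) enumerates every
mate assignment, egg outcome and survival outcome for cohorts of ≤ 6
individuals with a fixed egg count per female (a finite-support
stand-in for Poisson fecundity); it is used only in tests.

## Readouts

*Toxin survivors in cage* = `pupae_toxin / (pupae_toxin +
pupae_refuge)`; undefined (NaN, not 0) for an empty cage, so trend fits
drop dead cages explicitly. With equal survival on both diets its
ceiling is exactly `1 − refuge_fraction` — 0.90 at a 10% refuge and
0.88 at 12% — which the oracle attains analytically and the stochastic
engine within binomial error.

The *bioassay* rears `n` larvae drawn uniformly from the pooled egg
sample of a replicate on the diagnostic dose, using the same selection
parameters as cage selection, so a configured `h` propagates
consistently. With `h = 0` the survival proportion is an unbiased
estimator of the sample's RR proportion. Larvae are drawn from the egg
sample directly (transgenic female mortality during rearing is not
modelled here; toxin survival depends only on the R locus, so the RR
estimator is unaffected). If the sample is smaller than `n`, larvae are
drawn with replacement and the event is logged.

## Statistics layer

Proportion series are transformed with arcsin(√p) (the classical
variance-stabilizer for binomial proportions) and fitted by OLS on
(1, g, g²); fewer than three defined points fall back to a flagged
linear fit. Detrending is per subpopulation. Residual series are
screened with the circular lag-1 serial correlation about the series
mean, whose expectation for white noise is exactly −1/(n−1) — the
small-sample negative bias any analysis of 4-point series must account
for (an alternating series gives −1; a constant series is undefined).
Treatment contrasts use permutation tests on replicate-level summaries:
exhaustive enumeration when all two-group relabelings number at most
`n_perm` (exact p = extreme/total), otherwise `n_perm` random
relabelings with p = (1 + extreme)/(1 + n_perm), which is valid and
uniform under exchangeability. With two groups the statistic is the
difference in means (directional alternatives available); with more
groups, the between-group sum of squares. Mixed-effects binomial models
are deliberately out of scope: the transformed-OLS + permutation layer
is self-contained and dependency-light, and users can fit GLMMs to the
trajectory CSVs externally.

## Reproducibility

All stochastic draws flow through explicit `numpy.random.Generator`
streams. A run derives one child stream per (treatment arm × replicate)
by `SeedSequence(master_seed).spawn(...)` in a fixed arm-major order, so
any replicate is independently reproducible; the spawn keys are recorded
in the run manifest, and re-running from a manifest reproduces the
trajectory CSV byte-for-byte.

## What the synthetic experiments do and do not show

The experiment runners emulate the *design* of the mesocosm selection
experiments: founder sizes, initial allele frequency, refuge regimes,
dispersal, release ratios and timing, bioassay sizes, and both
resistance readouts. They do not emulate biological features outside
the model: polyandry, overlapping emergence, within-generation timing
(two egg collections are collapsed into one laying event — no genetic
consequence in a discrete-generation model), larval competition beyond
hard truncation, mating-competitiveness costs of the construct in
males, or maternal effects. Passing tests therefore validate the
engine's internal consistency and its agreement with the analytic
model, not quantitative fidelity to any particular wet dataset; under
the defaults, selection is stronger and resistance sweeps faster than
is typical in cage experiments, because survival probabilities are
idealized (0/1) and fitness costs are off.

## Numerical choices

* Rounding of dispersal and release counts uses round-half-to-even;
  the residual pupa of an odd dispersal batch goes to a receiver chosen
  by fair coin (unbiased in expectation).
* Frequency vectors are validated to sum to 1 within 1e-10; offspring
  distributions are exact to 1e-12.
* Degenerate inputs: a cage with no females or no males lays nothing
  and is flagged; an empty egg sample yields a (0, 0) bioassay; an
  empty cage's toxin-survivor proportion is NaN; the oracle's extinct
  state is absorbing.
* `allocate_eggs` uses independent per-egg assignment (binomial
  splits), which partitions the input exactly and makes the refuge
  count Binomial(n, f) — the natural stochastic reading of "10% of the
  eggs".
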