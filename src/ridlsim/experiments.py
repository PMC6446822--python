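"""In-silico replication of the two metapopulation selection experiments.

Experiment 1 compares three release treatments (no release, "everywhere"
at 4:1, "whack-a-mole" at 12:1 into the worst cage) in networks of three
cages founded with 200 pupae at a 7.5% resistance-allele frequency,
under a 10% refuge and 10% pre-mating pupal dispersal.  Experiment 2 is
a 2x2 factorial of release strategy (everywhere vs whack-a-mole) and
selection regime (homogeneous 12% refuge vs heterogeneous {5%, 10%,
20%} refuges re-randomized each generation).

Each generation executes, in order: refuge assignment; release of LLSS
males (from ``release_start_generation`` on, the whack target scored on
the previous generation's pre-dispersal toxin survivor counts); random
mating and egg laying; removal of the bioassay egg sample (pooled per
replicate); allocation of remaining eggs to refuge/toxin diet; viability
selection, female transgene lethality and density regulation; the pupal
census; and finally pupal dispersal, which seeds the next generation's
adults.

Output is a tidy table with one row per (replicate, cage, generation).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import SelectionParams
from .lifecycle import (
    FEMALE,
    MALE,
    DemographyParams,
    SexedCohort,
    allocate_eggs,
    mate_and_lay,
    select_and_pupate,
)
from .metapop import (
    ReleaseStrategy,
    SelectionRegime,
    SubpopState,
    apply_release,
    assign_refuges,
    disperse,
)
from .metrics import bioassay

__all__ = [
    "ExperimentConfig",
    "TRAJECTORY_COLUMNS",
    "make_founders",
    "run_generation",
    "run_replicate",
    "run_experiment1",
    "run_experiment2",
]

#: Deterministic column order of the trajectory table.
TRAJECTORY_COLUMNS = [
    "experiment",
    "treatment",
    "regime",
    "replicate",
    "subpop",
    "generation",
    "refuge_fraction",
    "pupae_refuge",
    "pupae_toxin",
    "released_males",
    "bioassay_tested",
    "bioassay_survivors",
    "freq_R",
    "freq_L",
    "whack_target",
    "extinct",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Full parameterization of one treatment arm or experiment.

    Defaults are the study conditions: 3 cages x 3 replicates, 200
    founder pupae per cage at a 7.5% R frequency, 10% of eggs to the
    bioassay, 10% pupal dispersal, 4 generations (indexed 0..3) with
    releases starting at generation 1.  ``bioassay_n`` of ``None``
    means the per-experiment default (100 larvae in experiment 1, 150
    in experiment 2).
    """

    n_subpops: int = 3
    n_replicates: int = 3
    founder_pupae: int = 200
    founder_r_freq: float = 0.075
    generations: int = 4
    bioassay_n: int | None = None
    bioassay_fraction: float = 0.10
    dispersal_fraction: float = 0.10
    release_start_generation: int = 1
    strategy: ReleaseStrategy = field(default_factory=ReleaseStrategy)
    regime: SelectionRegime = field(default_factory=SelectionRegime)
    selection: SelectionParams = field(default_factory=SelectionParams)
    demography: DemographyParams = field(default_factory=DemographyParams)
    master_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        checks = [
            ("n_subpops", self.n_subpops >= 1),
            ("n_replicates", self.n_replicates >= 1),
            ("founder_pupae", self.founder_pupae > 0),
            ("founder_r_freq", 0.0 <= self.founder_r_freq <= 1.0),
            ("generations", self.generations >= 1),
            ("bioassay_n", self.bioassay_n is None or self.bioassay_n >= 0),
            ("bioassay_fraction", 0.0 <= self.bioassay_fraction <= 1.0),
            ("dispersal_fraction", 0.0 <= self.dispersal_fraction <= 1.0),
            ("release_start_generation", self.release_start_generation >= 0),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(
                    f"invalid value for {name}: {getattr(self, name)!r}"
                )

    def resolved_bioassay_n(self, experiment: int) -> int:
        if self.bioassay_n is not None:
            return self.bioassay_n
        return 100 if experiment == 1 else 150

    def with_(self, **changes) -> "ExperimentConfig":
        return dataclasses.replace(self, **changes)


def make_founders(
    n: int, r_freq: float, rng: np.random.Generator
) -> SexedCohort:
    """Founder pupae at Hardy-Weinberg proportions for the R locus.

    All founders are non-transgenic (ww); resistance genotypes are
    multinomial at (q^2, 2q(1-q), (1-q)^2) for (RR, RS, SS) and sex is
    Binomial(n, 1/2), independent of genotype.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= r_freq <= 1.0:
        raise ValueError("r_freq must be in [0, 1]")
    q = r_freq
    hwe = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])  # SS, RS, RR
    by_r = rng.multinomial(n, hwe)
    cohort = SexedCohort.empty()
    for r_copies, count in enumerate(by_r):
        n_f = rng.binomial(count, 0.5)
        cohort.counts[r_copies, 0, FEMALE] = n_f
        cohort.counts[r_copies, 0, MALE] = count - n_f
    return cohort


def run_generation(
    subpops: list[SubpopState],
    config: ExperimentConfig,
    strategy: ReleaseStrategy,
    regime: SelectionRegime,
    generation: int,
    bioassay_n: int,
    rng: np.random.Generator,
    cohort_log: list | None = None,
) -> tuple[list[SubpopState], list[dict], bool]:
    """Advance one generation; returns (next states, records, network_extinct).

    The incoming ``subpops`` hold the adult pool (last generation's
    pupae, already dispersed, plus any previously released males were
    consumed last generation).  Releases for this generation are applied
    before mating; the whack target is scored on the incoming
    ``toxin_pupae_count`` values, which are pre-dispersal cage counts.
    """
    refuges = assign_refuges(regime, config.n_subpops, generation, rng)
    subpops = [
        dataclasses.replace(sp, refuge_fraction=float(f), released_males=0)
        for sp, f in zip(subpops, refuges)
    ]

    target: int | None = None
    if generation >= config.release_start_generation and strategy.mode != "none":
        subpops, target = apply_release(subpops, strategy, rng)

    # Mating, laying, allocation and selection per cage.
    per_cage: list[dict] = []
    pooled_bioassay = SexedCohort.empty()
    next_states: list[SubpopState] = []
    for sp in subpops:
        eggs, cage_failed = mate_and_lay(sp.pupae, config.demography, rng)
        bio, refuge_eggs, toxin_eggs = allocate_eggs(
            eggs, sp.refuge_fraction, config.bioassay_fraction, rng
        )
        pooled_bioassay = pooled_bioassay + bio
        refuge_pupae = select_and_pupate(
            refuge_eggs, "refuge", config.selection, config.demography,
            sp.refuge_fraction, rng,
        )
        toxin_pupae = select_and_pupate(
            toxin_eggs, "toxin", config.selection, config.demography,
            1.0 - sp.refuge_fraction, rng,
        )
        pupae = refuge_pupae + toxin_pupae
        per_cage.append(
            dict(
                subpop=sp.id,
                refuge_fraction=sp.refuge_fraction,
                pupae_refuge=refuge_pupae.total,
                pupae_toxin=toxin_pupae.total,
                released_males=sp.released_males,
                freq_R=pupae.allele_frequency("r"),
                freq_L=pupae.allele_frequency("l"),
                whack_target=(target is not None and sp.id == target),
            )
        )
        next_states.append(
            dataclasses.replace(
                sp, pupae=pupae, toxin_pupae_count=toxin_pupae.total
            )
        )

    if cohort_log is not None:
        cohort_log.append([st.pupae.copy() for st in next_states])
    tested, survivors = bioassay(pooled_bioassay, bioassay_n, config.selection, rng)
    network_total = sum(st.pupae.total for st in next_states)
    extinct = network_total == 0
    records = [
        dict(
            rec,
            generation=generation,
            bioassay_tested=tested,
            bioassay_survivors=survivors,
            extinct=extinct,
        )
        for rec in per_cage
    ]

    next_states = disperse(next_states, config.dispersal_fraction, rng)
    return next_states, records, extinct


def run_replicate(
    config: ExperimentConfig,
    strategy: ReleaseStrategy,
    regime: SelectionRegime,
    bioassay_n: int,
    rng: np.random.Generator,
    cohort_log: list | None = None,
) -> list[dict]:
    """One replicate network from founding to the final generation.

    Network extinction truncates the trajectory after emitting the
    flagged records of the fatal generation.  ``cohort_log``, if given,
    collects the per-cage pre-dispersal pupal cohorts of each
    generation (used for verification against the oracle).
    """
    subpops = [
        SubpopState(id=i, pupae=make_founders(config.founder_pupae,
                                              config.founder_r_freq, rng))
        for i in range(config.n_subpops)
    ]
    records: list[dict] = []
    for g in range(config.generations):
        subpops, recs, extinct = run_generation(
            subpops, config, strategy, regime, g, bioassay_n, rng,
            cohort_log=cohort_log,
        )
        records.extend(recs)
        if extinct:
            break
    return records


def _run_arms(
    config: ExperimentConfig,
    experiment: int,
    arms: list[tuple[str, str, ReleaseStrategy, SelectionRegime]],
) -> pd.DataFrame:
    """Run (arm x replicate) with per-replicate seeds spawned from the master seed."""
    bioassay_n = config.resolved_bioassay_n(experiment)
    ss = np.random.SeedSequence(config.master_seed)
    children = ss.spawn(len(arms) * config.n_replicates)
    rows: list[dict] = []
    k = 0
    for treatment, regime_label, strategy, regime in arms:
        for rep in range(config.n_replicates):
            rng = np.random.default_rng(children[k])
            k += 1
            for rec in run_replicate(config, strategy, regime, bioassay_n, rng):
                rows.append(
                    dict(
                        experiment=f"exp{experiment}",
                        treatment=treatment,
                        regime=regime_label,
                        replicate=rep,
                        **rec,
                    )
                )
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


def run_experiment1(config: ExperimentConfig | None = None) -> pd.DataFrame:
    """Experiment 1: {control, everywhere, whack-a-mole} x replicates.

    All treatments use a homogeneous refuge at the experiment-1 size
    (10% by default); the configured ``strategy`` field is ignored in
    favour of the three treatment arms.
    """
    config = config or ExperimentConfig()
    regime = SelectionRegime(
        mode="homogeneous", homogeneous_refuge=config.regime.experiment1_refuge
    )
    base = config.strategy.base_ratio
    mult = config.strategy.whack_multiplier
    arms = [
        ("control", "homogeneous", ReleaseStrategy(mode="none"), regime),
        ("everywhere", "homogeneous",
         ReleaseStrategy(mode="everywhere", base_ratio=base), regime),
        ("whack", "homogeneous",
         ReleaseStrategy(mode="whack", base_ratio=base, whack_multiplier=mult),
         regime),
    ]
    return _run_arms(config, 1, arms)


def run_experiment2(config: ExperimentConfig | None = None) -> pd.DataFrame:
    """Experiment 2: {everywhere, whack} x {homogeneous, heterogeneous} refuges."""
    config = config or ExperimentConfig()
    base = config.strategy.base_ratio
    mult = config.strategy.whack_multiplier
    hom = SelectionRegime(
        mode="homogeneous", homogeneous_refuge=config.regime.homogeneous_refuge
    )
    het = SelectionRegime(
        mode="heterogeneous",
        heterogeneous_refuges=config.regime.heterogeneous_refuges,
    )
    arms = []
    for treatment, strategy in [
        ("everywhere", ReleaseStrategy(mode="everywhere", base_ratio=base)),
        ("whack", ReleaseStrategy(mode="whack", base_ratio=base,
                                  whack_multiplier=mult)),
    ]:
        for regime_label, regime in [("homogeneous", hom), ("heterogeneous", het)]:
            arms.append((treatment, regime_label, strategy, regime))
    return _run_arms(config, 2, arms)
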