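"""Within-generation demography for one cage.

A generation inside a cage proceeds: adults mate at random and lay eggs
(:func:`mate_and_lay`); a bioassay sample is removed and the remaining
eggs are split between toxin-free refuge diet and Cry1Ac toxin diet
(:func:`allocate_eggs`); larvae undergo viability selection, transgenic
females die off-tetracycline, and survivors are truncated to the diet's
carrying capacity (:func:`select_and_pupate`).

Populations are held as integer counts per (genotype, sex) in a
:class:`SexedCohort`.  All stochastic draws take an explicit
:class:`numpy.random.Generator`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np

from .genetics import (
    GENOTYPES,
    N_GENOTYPES,
    OFFSPRING,
    Diet,
    Genotype,
    SelectionParams,
    genotype_index,
    survival_vector,
)

__all__ = [
    "FEMALE",
    "MALE",
    "SexedCohort",
    "DemographyParams",
    "mate_and_lay",
    "allocate_eggs",
    "select_and_pupate",
]

FEMALE, MALE = 0, 1
Sex = Literal[0, 1]


@dataclass
class SexedCohort:
    """Non-negative integer counts per (genotype, sex).

    ``counts`` has shape (3, 3, 2) indexed ``[r_copies, l_copies, sex]``
    with sex 0=female, 1=male.  This is the universal population
    container for eggs, larvae, pupae and adults alike.
    """

    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((3, 3, 2), dtype=np.int64)
    )

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3, 2):
            raise ValueError("counts must have shape (3, 3, 2)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    # -- constructors -------------------------------------------------
    @classmethod
    def empty(cls) -> "SexedCohort":
        return cls()

    @classmethod
    def from_dict(cls, d: dict[tuple[Genotype, int], int]) -> "SexedCohort":
        c = cls()
        for (g, sex), n in d.items():
            g.validate()
            c.counts[g.r_copies, g.l_copies, sex] += n
        return c

    @classmethod
    def single(cls, g: Genotype, sex: int, n: int = 1) -> "SexedCohort":
        c = cls()
        c.counts[g.r_copies, g.l_copies, sex] = n
        return c

    # -- census -------------------------------------------------------
    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_females(self) -> int:
        return int(self.counts[..., FEMALE].sum())

    @property
    def n_males(self) -> int:
        return int(self.counts[..., MALE].sum())

    def genotype_counts(self, sex: int | None = None) -> np.ndarray:
        """Length-9 counts in GENOTYPES order (both sexes unless given)."""
        c = self.counts if sex is None else self.counts[..., sex]
        return c.reshape(3, 3, -1).sum(axis=-1).ravel()

    def allele_frequency(self, locus: Literal["r", "l"]) -> float:
        """Frequency of the R (or L) allele; NaN for an empty cohort."""
        n = self.total
        if n == 0:
            return math.nan
        copies = np.arange(3)
        axis_counts = (
            self.counts.sum(axis=(1, 2)) if locus == "r" else self.counts.sum(axis=(0, 2))
        )
        return float((axis_counts * copies).sum() / (2 * n))

    # -- algebra ------------------------------------------------------
    def __add__(self, other: "SexedCohort") -> "SexedCohort":
        return SexedCohort(self.counts + other.counts)

    def copy(self) -> "SexedCohort":
        return SexedCohort(self.counts.copy())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SexedCohort) and bool(
            (self.counts == other.counts).all()
        )

    def items(self) -> Iterator[tuple[Genotype, int, int]]:
        """Yield (genotype, sex, count) for non-empty cells."""
        for r in range(3):
            for l in range(3):
                for sex in (FEMALE, MALE):
                    n = int(self.counts[r, l, sex])
                    if n:
                        yield Genotype(r, l), sex, n


@dataclass(frozen=True)
class DemographyParams:
    """Fecundity, carrying capacities and the primary sex ratio.

    Capacities are the maximum pupae supported *per unit diet fraction*:
    a cage with refuge fraction f supports ``capacity_refuge * f`` pupae
    on refuge diet and ``capacity_toxin * (1 - f)`` on toxin diet, so a
    cage's realized ceiling rises as resistance grants access to the
    toxin diet.  Defaults put a fully susceptible cage at a 10% refuge
    near the 200-pupae founder scale.
    """

    eggs_per_female: float = 30.0
    capacity_refuge: float = 2000.0
    capacity_toxin: float = 2000.0
    sex_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.eggs_per_female <= 0:
            raise ValueError("eggs_per_female must be positive")
        if self.capacity_refuge < 0 or self.capacity_toxin < 0:
            raise ValueError("capacities must be non-negative")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")

    def capacity(self, diet: Diet) -> float:
        return self.capacity_refuge if diet == "refuge" else self.capacity_toxin


def mate_and_lay(
    adults: SexedCohort, d: DemographyParams, rng: np.random.Generator
) -> tuple[SexedCohort, bool]:
    """Random mating and egg laying; returns (eggs, extinction_flag).

    Each female takes a single mate drawn with probability proportional
    to male counts (monandry; males mate freely) and lays a
    Poisson(``eggs_per_female``) number of eggs whose genotypes follow
    the Mendelian cross and whose sex is female with ``sex_ratio``.
    Females of one genotype are aggregated: their fathers are drawn
    multinomially and eggs per (mother, father) class are
    Poisson(k * mean), the exact law of k independent females.

    With zero females or zero males the cage cannot reproduce: an empty
    egg cohort is returned with the extinction flag set.
    """
    females = adults.genotype_counts(FEMALE)
    males = adults.genotype_counts(MALE)
    total_males = males.sum()
    eggs = SexedCohort.empty()
    if females.sum() == 0 or total_males == 0:
        return eggs, True
    male_p = males / total_males
    for i in np.flatnonzero(females):
        fathers = rng.multinomial(females[i], male_p)
        for j in np.flatnonzero(fathers):
            n_eggs = rng.poisson(d.eggs_per_female * fathers[j])
            if n_eggs == 0:
                continue
            by_geno = rng.multinomial(n_eggs, OFFSPRING[i, j])
            n_f = rng.binomial(by_geno, d.sex_ratio)
            eggs.counts[..., FEMALE] += n_f.reshape(3, 3)
            eggs.counts[..., MALE] += (by_geno - n_f).reshape(3, 3)
    return eggs, False


def allocate_eggs(
    eggs: SexedCohort,
    refuge_fraction: float,
    bioassay_fraction: float,
    rng: np.random.Generator,
) -> tuple[SexedCohort, SexedCohort, SexedCohort]:
    """Partition eggs into (bioassay_sample, refuge_eggs, toxin_eggs).

    The bioassay sample is removed first — each egg independently with
    ``bioassay_fraction`` — and the remainder is split egg-by-egg
    between refuge (probability ``refuge_fraction``) and toxin diet.
    The three parts partition the input exactly.
    """
    for name, frac in (("refuge_fraction", refuge_fraction),
                       ("bioassay_fraction", bioassay_fraction)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {frac}")
    bio = rng.binomial(eggs.counts, bioassay_fraction)
    rest = eggs.counts - bio
    refuge = rng.binomial(rest, refuge_fraction)
    toxin = rest - refuge
    return SexedCohort(bio), SexedCohort(refuge), SexedCohort(toxin)


def select_and_pupate(
    eggs_on_diet: SexedCohort,
    diet: Diet,
    s: SelectionParams,
    d: DemographyParams,
    diet_fraction: float,
    rng: np.random.Generator,
) -> SexedCohort:
    """Viability selection, female transgene lethality, density regulation.

    Each egg survives independently with its genotype's diet survival;
    off-tetracycline, surviving females carrying the construct die at
    the larval stage (before the pupal census).  If survivors exceed
    ``capacity(diet) * diet_fraction`` a uniform without-replacement
    subsample of exactly the capacity is retained (hypergeometric
    thinning, unbiased for genotype proportions).
    """
    if diet not in ("toxin", "refuge"):
        raise ValueError(f"unknown diet {diet!r}")
    surv = survival_vector(diet, s).reshape(3, 3)
    c = rng.binomial(eggs_on_diet.counts, surv[..., None])
    if not s.tetracycline:
        c[:, 1:, FEMALE] = 0  # dominant female-specific lethality
    cap = d.capacity(diet) * diet_fraction
    if np.isfinite(cap):
        cap_n = int(round(cap))
        if c.sum() > cap_n:
            kept = rng.multivariate_hypergeometric(c.ravel(), cap_n)
            c = kept.reshape(3, 3, 2)
    return SexedCohort(np.asarray(c, dtype=np.int64))
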