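"""Two-locus genetics for a Bt-resistance / self-limiting-transgene system.

Two unlinked biallelic loci are tracked per individual:

* the Cry1Ac-resistance locus, with alleles R (resistant) and S
  (susceptible); ``r_copies`` counts R alleles, so 0=SS, 1=RS, 2=RR;
* the self-limiting construct insertion site, with the construct allele L
  and wild-type absence w; ``l_copies`` counts L copies, so 0=ww, 1=Lw,
  2=LL.

The L construct is a dominant, tetracycline-repressible, female-specific
lethal: off tetracycline any female carrying at least one L copy dies
before pupation, while males are unaffected.  Released factory males are
homozygous for the construct and fully susceptible to the toxin
(``RELEASED_MALE`` = LLSS).

Toxin-diet survival depends only on the resistance locus; at a
diagnostic high dose resistance is (near-)recessive, so the default
survival schedule is (SS, RS, RR) = (0, h, 1) with h = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np

__all__ = [
    "Genotype",
    "GENOTYPES",
    "N_GENOTYPES",
    "RELEASED_MALE",
    "SelectionParams",
    "Diet",
    "genotype_index",
    "gamete_distribution",
    "offspring_distribution",
    "offspring_tensor",
    "female_is_viable",
    "diet_survival",
]

Diet = Literal["toxin", "refuge"]


class Genotype(NamedTuple):
    """An individual's two-locus genotype as allele-copy counts."""

    r_copies: int
    l_copies: int

    def validate(self) -> None:
        if self.r_copies not in (0, 1, 2) or self.l_copies not in (0, 1, 2):
            raise ValueError(f"invalid genotype {self!r}: copy counts must be in 0..2")


#: All 9 genotypes in a fixed order; index = 3 * r_copies + l_copies.
GENOTYPES: tuple[Genotype, ...] = tuple(
    Genotype(r, l) for r in range(3) for l in range(3)
)
N_GENOTYPES = len(GENOTYPES)

#: Genotype of mass-released self-limiting males: LL at the construct
#: locus, SS (fully susceptible) at the resistance locus.
RELEASED_MALE = Genotype(r_copies=0, l_copies=2)


def genotype_index(g: Genotype) -> int:
    """Position of ``g`` in :data:`GENOTYPES`."""
    return 3 * g.r_copies + g.l_copies


# Row c -> probability a gamete carries (0, 1) copies of the allele when
# the parent carries c copies (fair meiosis).
_ALLELE_TRANSMISSION = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])


@dataclass(frozen=True)
class SelectionParams:
    """Viability parameters for both diets and the transgene.

    ``toxin_survival_by_r`` maps R-copy count to survival probability on
    toxin diet; the default (0, 0, 1) is the strict high-dose/recessive
    case (h = 0).  ``refuge_survival`` is shared by all genotypes on
    toxin-free diet, discounted by ``(1 - fitness_cost_R)`` per R copy.
    ``tetracycline`` represses female lethality when true (factory
    rearing); cage populations run off tetracycline.
    """

    toxin_survival_by_r: tuple[float, float, float] = (0.0, 0.0, 1.0)
    refuge_survival: float = 1.0
    fitness_cost_R: float = 0.0
    tetracycline: bool = False

    def __post_init__(self) -> None:
        for p in (*self.toxin_survival_by_r, self.refuge_survival):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"survival probability {p} outside [0, 1]")
        if not 0.0 <= self.fitness_cost_R <= 1.0:
            raise ValueError("fitness_cost_R must be in [0, 1]")

    @classmethod
    def with_dominance(cls, h: float, **kwargs) -> "SelectionParams":
        """Near-recessive variant: heterozygote toxin survival h."""
        return cls(toxin_survival_by_r=(0.0, float(h), 1.0), **kwargs)


def gamete_distribution(g: Genotype) -> np.ndarray:
    """Probabilities of the 4 gamete types produced by genotype ``g``.

    Returns a (2, 2) array indexed ``[carries_R, carries_L]`` (0/1 at
    each axis).  Loci assort independently (unlinked).
    """
    g.validate()
    return np.outer(_ALLELE_TRANSMISSION[g.r_copies], _ALLELE_TRANSMISSION[g.l_copies])


def offspring_distribution(mother: Genotype, father: Genotype) -> np.ndarray:
    """Distribution over the 9 offspring genotypes of a cross.

    Returns a length-9 probability vector in :data:`GENOTYPES` order,
    the convolution of the parental gamete distributions at each locus.
    """
    mother.validate()
    father.validate()
    r_child = _locus_child_dist(mother.r_copies, father.r_copies)
    l_child = _locus_child_dist(mother.l_copies, father.l_copies)
    return np.outer(r_child, l_child).ravel()


def _locus_child_dist(mc: int, fc: int) -> np.ndarray:
    """P(child copy count = 0,1,2) at one locus from parental counts."""
    m = _ALLELE_TRANSMISSION[mc]
    f = _ALLELE_TRANSMISSION[fc]
    out = np.zeros(3)
    for a in (0, 1):
        for b in (0, 1):
            out[a + b] += m[a] * f[b]
    return out


def _build_offspring_tensor() -> np.ndarray:
    t = np.empty((N_GENOTYPES, N_GENOTYPES, N_GENOTYPES))
    for i, mom in enumerate(GENOTYPES):
        for j, dad in enumerate(GENOTYPES):
            t[i, j] = offspring_distribution(mom, dad)
    return t


#: OFFSPRING[i, j, k] = P(offspring genotype k | mother i, father j).
OFFSPRING: np.ndarray = _build_offspring_tensor()


def offspring_tensor() -> np.ndarray:
    """The full (9, 9, 9) mother x father -> offspring probability tensor."""
    return OFFSPRING.copy()


def female_is_viable(g: Genotype, tetracycline: bool) -> bool:
    """Whether a female of genotype ``g`` survives to pupation.

    The construct is dominant and female-specific: any L copy is lethal
    to females unless repressed by dietary tetracycline.
    """
    g.validate()
    return tetracycline or g.l_copies == 0


def diet_survival(g: Genotype, diet: Diet, p: SelectionParams) -> float:
    """Larval survival probability of genotype ``g`` on the given diet.

    Sex-independent; female transgene lethality is applied separately.
    """
    g.validate()
    if diet == "toxin":
        return p.toxin_survival_by_r[g.r_copies]
    if diet == "refuge":
        return p.refuge_survival * (1.0 - p.fitness_cost_R) ** g.r_copies
    raise ValueError(f"unknown diet {diet!r}")


def survival_vector(diet: Diet, p: SelectionParams) -> np.ndarray:
    """Length-9 survival probabilities in :data:`GENOTYPES` order."""
    return np.array([diet_survival(g, diet, p) for g in GENOTYPES])


def female_viability_vector(tetracycline: bool) -> np.ndarray:
    """Length-9 vector of 0/1 female viabilities in :data:`GENOTYPES` order."""
    return np.array(
        [1.0 if female_is_viable(g, tetracycline) else 0.0 for g in GENOTYPES]
    )
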