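"""Infinite-population genotype-frequency recursion.

The oracle transcribes the stochastic engine's event order into expected
values for a single panmictic cage: random-mating offspring frequencies,
the refuge/toxin egg split, diet survival, female transgene lethality,
and male release as a frequency injection.  It has no sampling noise, so
it serves both as a verification oracle for the simulator (large-
population mean trajectories must track it) and as a fast explorer of
expected dynamics.

A small exhaustive-enumeration engine (:func:`brute_force_generation`)
computes the exact next-generation distribution for tiny cohorts and is
used only in tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetics import (
    GENOTYPES,
    N_GENOTYPES,
    OFFSPRING,
    RELEASED_MALE,
    Genotype,
    SelectionParams,
    diet_survival,
    female_is_viable,
    female_viability_vector,
    genotype_index,
    survival_vector,
)
from .lifecycle import FEMALE, MALE, DemographyParams, SexedCohort

__all__ = [
    "FreqState",
    "GenerationDiagnostics",
    "deterministic_generation",
    "oracle_trajectory",
    "max_toxin_survivor_proportion",
    "brute_force_generation",
]

_FREQ_TOL = 1e-10


@dataclass
class FreqState:
    """Per-sex genotype-frequency vectors plus a population-scale multiplier.

    ``female`` and ``male`` are length-9 probability vectors in
    GENOTYPES order; ``scale`` is the expected population size.  An
    extinct (absorbing) state has ``extinct`` set and zero scale.
    """

    female: np.ndarray
    male: np.ndarray
    scale: float = 1.0
    extinct: bool = False

    def __post_init__(self) -> None:
        self.female = np.asarray(self.female, dtype=float)
        self.male = np.asarray(self.male, dtype=float)
        if self.extinct:
            return
        for name, v in (("female", self.female), ("male", self.male)):
            if v.shape != (N_GENOTYPES,):
                raise ValueError(f"{name} frequency vector must have length 9")
            if (v < -_FREQ_TOL).any():
                raise ValueError(f"{name} frequencies must be non-negative")
            if abs(v.sum() - 1.0) > _FREQ_TOL:
                raise ValueError(f"{name} frequencies must sum to 1")

    @classmethod
    def from_allele_freqs(
        cls, r_freq: float, l_freq: float = 0.0, scale: float = 1.0
    ) -> "FreqState":
        """Hardy-Weinberg state at the given allele frequencies, both sexes."""
        def hwe(q: float) -> np.ndarray:
            return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])

        v = np.outer(hwe(r_freq), hwe(l_freq)).ravel()
        return cls(female=v.copy(), male=v.copy(), scale=scale)

    @classmethod
    def fixed(cls, g: Genotype, scale: float = 1.0) -> "FreqState":
        v = np.zeros(N_GENOTYPES)
        v[genotype_index(g)] = 1.0
        return cls(female=v.copy(), male=v.copy(), scale=scale)

    @classmethod
    def extinct_state(cls) -> "FreqState":
        z = np.zeros(N_GENOTYPES)
        return cls(female=z, male=z.copy(), scale=0.0, extinct=True)

    def combined(self) -> np.ndarray:
        """Sex-averaged genotype frequencies."""
        return 0.5 * (self.female + self.male)

    def allele_frequency(self, locus: str) -> float:
        copies = np.array([getattr(g, f"{locus}_copies") for g in GENOTYPES])
        return float((self.combined() * copies).sum() / 2.0)


@dataclass(frozen=True)
class GenerationDiagnostics:
    """Expected readouts of one oracle generation (pre-release pupal pool)."""

    toxin_survivor_proportion: float
    pupal_freq: np.ndarray  # combined-sex genotype frequencies, length 9
    pupal_freq_R: float
    pupal_freq_L: float
    extinct: bool = False


def deterministic_generation(
    state: FreqState,
    refuge_fraction: float,
    s: SelectionParams,
    d: DemographyParams | None = None,
    release_ratio: float = 0.0,
    bioassay_fraction: float = 0.0,
) -> tuple[FreqState, GenerationDiagnostics]:
    """Expected-value transcription of one cage generation.

    Mirrors the stochastic engine's event order: release of LLSS males
    as a male-frequency injection at ``release_ratio`` transgenic per
    local male (before mating), then random mating, the bioassay
    removal and refuge/toxin egg allocation, diet survival and female
    transgene lethality.  Returns the end-of-generation pupal state and
    its diagnostics.
    """
    if not 0.0 <= refuge_fraction <= 1.0:
        raise ValueError("refuge_fraction must be in [0, 1]")
    if release_ratio < 0:
        raise ValueError("release_ratio must be non-negative")
    d = d or DemographyParams()
    nan_diag = GenerationDiagnostics(
        toxin_survivor_proportion=float("nan"),
        pupal_freq=np.full(N_GENOTYPES, np.nan),
        pupal_freq_R=float("nan"),
        pupal_freq_L=float("nan"),
        extinct=True,
    )
    if state.extinct or state.female.sum() == 0 or state.male.sum() == 0:
        return FreqState.extinct_state(), nan_diag

    male = state.male
    if release_ratio > 0:
        inject = np.zeros(N_GENOTYPES)
        inject[genotype_index(RELEASED_MALE)] = 1.0
        male = (male + release_ratio * inject) / (1.0 + release_ratio)

    egg = np.einsum("i,j,ijk->k", state.female, male, OFFSPRING)
    f = refuge_fraction
    surv_refuge = survival_vector("refuge", s)
    surv_toxin = survival_vector("toxin", s)
    viable_f = female_viability_vector(s.tetracycline)

    # Per-egg survivor mass by genotype on each diet (bioassay removed first).
    kept = 1.0 - bioassay_fraction
    refuge_mass = kept * f * egg * surv_refuge
    toxin_mass = kept * (1.0 - f) * egg * surv_toxin

    sex_f = d.sex_ratio
    pup_f = sex_f * (refuge_mass + toxin_mass) * viable_f
    pup_m = (1.0 - sex_f) * (refuge_mass + toxin_mass)
    refuge_pupal = (sex_f * viable_f + (1.0 - sex_f)) * refuge_mass
    toxin_pupal = (sex_f * viable_f + (1.0 - sex_f)) * toxin_mass
    total_pupal = refuge_pupal.sum() + toxin_pupal.sum()
    if total_pupal <= 0.0:
        return FreqState.extinct_state(), nan_diag

    pupal = pup_f + pup_m
    pupal_freq = pupal / pupal.sum()
    r_copies = np.array([g.r_copies for g in GENOTYPES])
    l_copies = np.array([g.l_copies for g in GENOTYPES])
    diag = GenerationDiagnostics(
        toxin_survivor_proportion=float(toxin_pupal.sum() / total_pupal),
        pupal_freq=pupal_freq,
        pupal_freq_R=float((pupal_freq * r_copies).sum() / 2.0),
        pupal_freq_L=float((pupal_freq * l_copies).sum() / 2.0),
    )

    # Expected population size, with per-diet capacity truncation.
    adult_females = state.scale * 0.5
    n_eggs = adult_females * d.eggs_per_female
    exp_refuge = min(n_eggs * refuge_pupal.sum(), d.capacity_refuge * f)
    exp_toxin = min(n_eggs * toxin_pupal.sum(), d.capacity_toxin * (1.0 - f))
    new_scale = exp_refuge + exp_toxin

    if pup_f.sum() == 0 or pup_m.sum() == 0:
        return FreqState.extinct_state(), diag
    return FreqState(
        female=pup_f / pup_f.sum(), male=pup_m / pup_m.sum(), scale=new_scale
    ), diag


def oracle_trajectory(
    r_freq: float = 0.075,
    refuge_fraction: float = 0.10,
    generations: int = 4,
    release_ratio: float = 0.0,
    release_start: int = 1,
    release_stop: int | None = None,
    s: SelectionParams | None = None,
    d: DemographyParams | None = None,
    bioassay_fraction: float = 0.0,
    initial: FreqState | None = None,
) -> pd.DataFrame:
    """Run the oracle for several generations; returns a tidy trajectory.

    ``release_ratio`` is injected for generations in
    [release_start, release_stop); columns report the pupal pool of each
    generation.
    """
    s = s or SelectionParams()
    state = initial or FreqState.from_allele_freqs(r_freq)
    rows = []
    for g in range(generations):
        releasing = (
            release_ratio > 0
            and g >= release_start
            and (release_stop is None or g < release_stop)
        )
        state, diag = deterministic_generation(
            state,
            refuge_fraction,
            s,
            d,
            release_ratio=release_ratio if releasing else 0.0,
            bioassay_fraction=bioassay_fraction,
        )
        rows.append(
            dict(
                generation=g,
                refuge_fraction=refuge_fraction,
                release_ratio=release_ratio if releasing else 0.0,
                toxin_survivor_proportion=diag.toxin_survivor_proportion,
                freq_R=diag.pupal_freq_R,
                freq_L=diag.pupal_freq_L,
                scale=state.scale,
                extinct=diag.extinct,
            )
        )
        if state.extinct:
            break
    return pd.DataFrame(rows)


def max_toxin_survivor_proportion(refuge_fraction: float) -> float:
    """Ceiling of the toxin-survivor-in-cage proportion: 1 - refuge fraction.

    Attained by a fully resistant cohort with equal survival on both
    diets (0.90 at a 10% refuge, 0.88 at 12%).
    """
    if not 0.0 <= refuge_fraction <= 1.0:
        raise ValueError("refuge_fraction must be in [0, 1]")
    return 1.0 - refuge_fraction


# ---------------------------------------------------------------------------
# Exhaustive small-cohort enumeration (test oracle)
# ---------------------------------------------------------------------------

CohortKey = tuple[int, ...]  # flattened (3,3,2) counts


def _cohort_key(counts: np.ndarray) -> CohortKey:
    return tuple(int(x) for x in counts.ravel())


def brute_force_generation(
    cohort: SexedCohort,
    s: SelectionParams,
    eggs_per_female: int = 2,
    diet: str = "refuge",
    sex_ratio: float = 0.5,
) -> dict[CohortKey, float]:
    """Exact next-generation cohort distribution for a tiny cage.

    Enumerates all mate assignments (each female one mate, uniform over
    males), all per-egg genotype/sex outcomes and all survival outcomes,
    with a fixed egg count per female to keep the support finite.
    Returns a map from flattened (3,3,2) count tuples to probabilities.
    Intended only for tests; requires at most 6 individuals.
    """
    if cohort.total > 6:
        raise ValueError("brute-force enumeration limited to 6 individuals")
    females = [g for g, sex, n in cohort.items() if sex == FEMALE for _ in range(n)]
    males = [g for g, sex, n in cohort.items() if sex == MALE for _ in range(n)]
    empty = _cohort_key(np.zeros((3, 3, 2), dtype=np.int64))
    if not females or not males:
        return {empty: 1.0}

    # Per-egg outcome distribution for a given cross: 18 live cells + death.
    def egg_outcomes(mother: Genotype, father: Genotype) -> list[tuple[int, float]]:
        probs = OFFSPRING[genotype_index(mother), genotype_index(father)]
        out: list[tuple[int, float]] = []
        p_dead = 0.0
        for k, g in enumerate(GENOTYPES):
            surv = diet_survival(g, diet, s)
            for sex, p_sex in ((FEMALE, sex_ratio), (MALE, 1 - sex_ratio)):
                p_live = probs[k] * p_sex * surv
                if sex == FEMALE and not female_is_viable(g, s.tetracycline):
                    p_live = 0.0
                cell = (g.r_copies * 3 + g.l_copies) * 2 + sex
                if p_live > 0:
                    out.append((cell, p_live))
                p_dead += probs[k] * p_sex - p_live
        out.append((-1, p_dead))
        return out

    n_males = len(males)
    result: dict[CohortKey, float] = {}
    for assignment in itertools.product(range(n_males), repeat=len(females)):
        p_assign = (1.0 / n_males) ** len(females)
        partial: dict[CohortKey, float] = {empty: 1.0}
        for fi, mi in enumerate(assignment):
            outcomes = egg_outcomes(females[fi], males[mi])
            for _ in range(eggs_per_female):
                nxt: dict[CohortKey, float] = {}
                for key, p in partial.items():
                    for cell, p_cell in outcomes:
                        if cell < 0:
                            new_key = key
                        else:
                            lst = list(key)
                            lst[cell] += 1
                            new_key = tuple(lst)
                        nxt[new_key] = nxt.get(new_key, 0.0) + p * p_cell
                partial = nxt
        for key, p in partial.items():
            result[key] = result.get(key, 0.0) + p_assign * p
    return result
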