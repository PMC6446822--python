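"""Network layer: dispersal, refuge regimes and release strategies.

Three (generically, n) cages form a fully connected metapopulation.
Each generation a fixed fraction of every cage's pupae is shared evenly
with the other cages before mating (:func:`disperse`).  Self-limiting
males are then released either into every cage at a base ratio to local
males ("everywhere") or, under the "whack-a-mole" policy, at a
multiplied ratio into the single cage that produced the most survivors
on toxin diet (:func:`choose_whack_target`, :func:`apply_release`).
Refuge sizes per cage come from a :class:`SelectionRegime`
(:func:`assign_refuges`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .genetics import RELEASED_MALE
from .lifecycle import MALE, SexedCohort

__all__ = [
    "SubpopState",
    "ReleaseStrategy",
    "SelectionRegime",
    "disperse",
    "choose_whack_target",
    "apply_release",
    "assign_refuges",
]


@dataclass
class SubpopState:
    """One cage's state within a replicate network.

    ``pupae`` is the current cohort (pupae at the end of a generation;
    adults at the start of the next).  ``toxin_pupae_count`` is the
    cage's own (pre-dispersal) count of survivors from toxin diet in the
    most recent generation, the quantity the whack-a-mole policy scores.
    """

    id: int
    pupae: SexedCohort = field(default_factory=SexedCohort.empty)
    refuge_fraction: float = float("nan")
    toxin_pupae_count: int = 0
    released_males: int = 0

    def __post_init__(self) -> None:
        if not (np.isnan(self.refuge_fraction) or 0.0 <= self.refuge_fraction <= 1.0):
            raise ValueError("refuge_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ReleaseStrategy:
    """Where and how many self-limiting males to release.

    ``base_ratio`` is the transgenic:wild ratio rho against local male
    counts.  ``whack`` mode releases only into the chosen target cage at
    ``base_ratio * whack_multiplier`` (default 12:1), so with equal cage
    sizes the total release budget matches the everywhere strategy.
    ``persistent_target`` pins the whack target to a fixed cage (the
    fixed-source variant); ``release_when_no_survivors`` keeps releasing
    at a random cage when no cage has toxin survivors.
    """

    mode: Literal["none", "everywhere", "whack"] = "none"
    base_ratio: float = 4.0
    whack_multiplier: int = 3
    persistent_target: int | None = None
    release_when_no_survivors: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("none", "everywhere", "whack"):
            raise ValueError(f"unknown release mode {self.mode!r}")
        if self.base_ratio < 0:
            raise ValueError("base_ratio must be non-negative")
        if self.whack_multiplier < 0:
            raise ValueError("whack_multiplier must be non-negative")

    @property
    def whack_ratio(self) -> float:
        return self.base_ratio * self.whack_multiplier


@dataclass(frozen=True)
class SelectionRegime:
    """Per-cage refuge fractions across the network.

    ``homogeneous`` assigns the same refuge everywhere each generation;
    ``heterogeneous`` assigns a fresh uniform-random permutation of
    ``heterogeneous_refuges`` to the cages each generation.  Defaults
    mirror the factorial design: 12% homogeneous vs {5%, 10%, 20%}
    heterogeneous (same network-mean refuge), with a 10% refuge for the
    first selection experiment.
    """

    mode: Literal["homogeneous", "heterogeneous"] = "homogeneous"
    homogeneous_refuge: float = 0.12
    heterogeneous_refuges: tuple[float, ...] = (0.05, 0.10, 0.20)
    experiment1_refuge: float = 0.10

    def __post_init__(self) -> None:
        if self.mode not in ("homogeneous", "heterogeneous"):
            raise ValueError(f"unknown regime mode {self.mode!r}")
        for f in (self.homogeneous_refuge, self.experiment1_refuge,
                  *self.heterogeneous_refuges):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"refuge fraction {f} outside [0, 1]")


def disperse(
    subpops: Sequence[SubpopState],
    dispersal_fraction: float,
    rng: np.random.Generator,
) -> list[SubpopState]:
    """Simultaneous pre-mating pupal exchange among cages.

    From each cage, round(fraction * total) pupae are drawn uniformly
    without replacement and split as evenly as possible between the
    other cages, any odd remainder going to receivers chosen by fair
    coin.  Outflows are computed from the pre-dispersal states, so total
    pupae (and every genotype's network-wide count) are conserved
    exactly.
    """
    if not 0.0 <= dispersal_fraction <= 1.0:
        raise ValueError("dispersal_fraction must be in [0, 1]")
    n = len(subpops)
    if n < 2 or dispersal_fraction == 0.0:
        return [replace(sp, pupae=sp.pupae.copy()) for sp in subpops]

    outflows = []
    for sp in subpops:
        k = int(round(dispersal_fraction * sp.pupae.total))
        if k > 0:
            moved = rng.multivariate_hypergeometric(sp.pupae.counts.ravel(), k)
        else:
            moved = np.zeros(18, dtype=np.int64)
        outflows.append(moved.reshape(3, 3, 2))

    new_counts = [sp.pupae.counts - out for sp, out in zip(subpops, outflows)]
    for i, out in enumerate(outflows):
        receivers = [j for j in range(n) if j != i]
        k = int(out.sum())
        base, rem = divmod(k, len(receivers))
        sizes = np.full(len(receivers), base, dtype=np.int64)
        if rem:
            lucky = rng.choice(len(receivers), size=rem, replace=False)
            sizes[lucky] += 1
        remaining = out.ravel().copy()
        for j, size in zip(receivers, sizes):
            if size > 0:
                take = rng.multivariate_hypergeometric(remaining, int(size))
                new_counts[j] = new_counts[j] + take.reshape(3, 3, 2)
                remaining -= take
    return [
        replace(sp, pupae=SexedCohort(c)) for sp, c in zip(subpops, new_counts)
    ]


def choose_whack_target(
    subpops: Sequence[SubpopState], rng: np.random.Generator
) -> int:
    """Cage with the most survivors on toxin diet; ties broken uniformly.

    Uses the cages' own (post-selection, pre-dispersal) toxin survivor
    counts from the current generation.  When every count is zero, a
    uniformly random cage is returned so the release budget can still be
    deployed.
    """
    counts = np.array([sp.toxin_pupae_count for sp in subpops])
    best = np.flatnonzero(counts == counts.max())
    return int(subpops[int(rng.choice(best))].id) if len(best) > 1 else int(
        subpops[int(best[0])].id
    )


def apply_release(
    subpops: Sequence[SubpopState],
    strategy: ReleaseStrategy,
    rng: np.random.Generator,
) -> tuple[list[SubpopState], int | None]:
    """Add released LLSS males; returns (new states, whack target or None).

    Called after dispersal and before mating.  ``everywhere`` releases
    round(rho * local males) into every cage; ``whack`` releases
    round(rho * multiplier * local males) into the target cage only.
    Released males join the mating pool but are never dispersed.
    """
    out: list[SubpopState] = []
    target: int | None = None
    if strategy.mode == "whack":
        if strategy.persistent_target is not None:
            target = strategy.persistent_target
        else:
            all_zero = all(sp.toxin_pupae_count == 0 for sp in subpops)
            if all_zero and not strategy.release_when_no_survivors:
                target = None
            else:
                target = choose_whack_target(subpops, rng)
    for sp in subpops:
        local_males = sp.pupae.n_males
        if strategy.mode == "everywhere":
            n_rel = int(round(strategy.base_ratio * local_males))
        elif strategy.mode == "whack" and sp.id == target:
            n_rel = int(round(strategy.whack_ratio * local_males))
        else:
            n_rel = 0
        pupae = sp.pupae.copy()
        if n_rel > 0:
            pupae = pupae + SexedCohort.single(RELEASED_MALE, MALE, n_rel)
        out.append(replace(sp, pupae=pupae, released_males=n_rel))
    return out, target


def assign_refuges(
    regime: SelectionRegime,
    n_subpops: int,
    generation: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Refuge fraction per cage for one generation.

    Homogeneous: a constant vector.  Heterogeneous: a fresh uniform
    random permutation of the configured refuge list each generation.
    """
    if regime.mode == "homogeneous":
        return np.full(n_subpops, regime.homogeneous_refuge)
    if len(regime.heterogeneous_refuges) != n_subpops:
        raise ValueError(
            "heterogeneous_refuges length must equal the number of subpopulations"
        )
    return rng.permutation(np.array(regime.heterogeneous_refuges))
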