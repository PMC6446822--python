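"""Resistance readouts and population summaries.

Two readouts track phenotypic resistance.  "Toxin survivors in cage" is
the proportion of a cage's pupae that emerged from the toxin diet; with
equal survival on both diets it runs from 0 (fully susceptible) to
1 - refuge_fraction (fully resistant).  The egg bioassay rears a fixed
number of larvae from eggs sampled before the diet split (pooled per
replicate) on a diagnostic toxin dose; with recessive resistance the
survival proportion estimates the RR genotype frequency.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .genetics import SelectionParams
from .lifecycle import SexedCohort

__all__ = [
    "toxin_survivor_proportion",
    "bioassay",
    "network_population_size",
    "summarize_trajectories",
]

log = logging.getLogger(__name__)


def toxin_survivor_proportion(pupae_toxin: int, pupae_refuge: int) -> float:
    """Pupae from toxin diet over all pupae in the cage; NaN if the cage is empty.

    An empty cage is undefined (not zero): a dead cage cannot be scored,
    and downstream trend fits drop the missing value explicitly.
    """
    if pupae_toxin < 0 or pupae_refuge < 0:
        raise ValueError("pupal counts must be non-negative")
    total = pupae_toxin + pupae_refuge
    if total == 0:
        return math.nan
    return pupae_toxin / total


def bioassay(
    sample_eggs: SexedCohort,
    n: int,
    s: SelectionParams,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Diagnostic-dose assay of ``n`` larvae; returns (tested, survivors).

    Larvae are drawn uniformly without replacement from the sampled eggs
    (with replacement, logged, if the sample is smaller than ``n``) and
    each survives with its genotype's toxin-diet survival — the same
    dose and parameters as cage selection.  An empty sample yields
    (0, 0).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return 0, 0
    colors = sample_eggs.counts.reshape(9, 2).sum(axis=1)  # by genotype
    total = int(colors.sum())
    if total == 0:
        log.warning("bioassay on empty egg sample: returning (0, 0)")
        return 0, 0
    if total >= n:
        drawn = rng.multivariate_hypergeometric(colors, n)
    else:
        log.warning(
            "bioassay sample (%d eggs) smaller than n=%d: drawing with replacement",
            total,
            n,
        )
        drawn = rng.multinomial(n, colors / total)
    by_r = drawn.reshape(3, 3).sum(axis=1)
    surv = np.array(s.toxin_survival_by_r)
    survivors = int(rng.binomial(by_r, surv).sum())
    return n, survivors


def network_population_size(records: pd.DataFrame) -> int:
    """Total pupae across the cages of one replicate-generation.

    ``records`` must hold exactly the subpopulation rows of a single
    (replicate, generation); an extinct replicate sums to 0.
    """
    required = {"pupae_refuge", "pupae_toxin", "subpop"}
    if not required.issubset(records.columns):
        raise ValueError(f"records missing columns {required - set(records.columns)}")
    if records["subpop"].duplicated().any():
        raise ValueError("duplicate subpopulation rows")
    return int((records["pupae_refuge"] + records["pupae_toxin"]).sum())


def summarize_trajectories(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Replicate-level summary: one row per (treatment, regime, replicate, generation).

    Columns: network population size, mean toxin-survivor proportion
    across cages (NaN cages dropped), and the pooled bioassay
    proportion.
    """
    df = trajectories.copy()
    df["toxin_survivor_proportion"] = [
        toxin_survivor_proportion(int(t), int(r))
        for t, r in zip(df["pupae_toxin"], df["pupae_refuge"])
    ]
    keys = ["experiment", "treatment", "regime", "replicate", "generation"]
    rows = []
    for key, grp in df.groupby(keys, sort=True):
        tested = int(grp["bioassay_tested"].iloc[0])
        survivors = int(grp["bioassay_survivors"].iloc[0])
        rows.append(
            dict(
                zip(keys, key),
                network_size=int((grp["pupae_refuge"] + grp["pupae_toxin"]).sum()),
                mean_toxin_survivor_proportion=float(
                    grp["toxin_survivor_proportion"].mean()
                ),
                bioassay_tested=tested,
                bioassay_survivors=survivors,
                bioassay_proportion=(survivors / tested if tested else math.nan),
                extinct=bool(grp["extinct"].any()) if "extinct" in grp else False,
            )
        )
    return pd.DataFrame(rows)
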