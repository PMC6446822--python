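"""Mating, egg allocation, selection and density regulation in one cage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ridlsim.genetics import Genotype, SelectionParams
from ridlsim.lifecycle import (
    FEMALE,
    MALE,
    DemographyParams,
    SexedCohort,
    allocate_eggs,
    mate_and_lay,
    select_and_pupate,
)

from helpers import cohort_of


class TestMateAndLay:
    def test_fixed_line_breeds_true(self, rng):
        adults = cohort_of((2, 0, FEMALE, 10), (2, 0, MALE, 10))
        eggs, extinct = mate_and_lay(adults, DemographyParams(), rng)
        assert not extinct
        assert eggs.total > 0
        assert eggs.counts[2, 0].sum() == eggs.total  # every egg RR/ww

    def test_transgenic_paternity_share_at_4_to_1(self, rng):
        """With 4 LLSS males per wild male, ~80% of eggs carry the construct."""
        adults = cohort_of(
            (0, 0, FEMALE, 400), (0, 2, MALE, 1600), (0, 0, MALE, 400)
        )
        eggs, _ = mate_and_lay(adults, DemographyParams(), rng)
        lw = eggs.counts[:, 1, :].sum()
        frac = lw / eggs.total
        # paternity is clustered by female; 4 SD of the 400-female binomial
        tol = 4 * np.sqrt(0.8 * 0.2 / 400)
        assert frac == pytest.approx(0.8, abs=tol)

    def test_single_heterozygote_cross_rr_fraction(self, rng):
        adults = cohort_of((1, 0, FEMALE, 1), (1, 0, MALE, 1))
        d = DemographyParams(eggs_per_female=4000.0)
        eggs, _ = mate_and_lay(adults, d, rng)
        rr = eggs.counts[2, 0].sum() / eggs.total
        assert rr == pytest.approx(0.25, abs=4 * np.sqrt(0.25 * 0.75 / eggs.total))

    @pytest.mark.parametrize("missing_sex", [FEMALE, MALE])
    def test_missing_sex_flags_extinction(self, rng, missing_sex):
        adults = cohort_of((0, 0, 1 - missing_sex, 5))
        eggs, extinct = mate_and_lay(adults, DemographyParams(), rng)
        assert extinct
        assert eggs.total == 0


class TestAllocateEggs:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.integers(0, 40), min_size=18, max_size=18),
        refuge=st.floats(0, 1),
        bio=st.floats(0, 1),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_exact_partition(self, counts, refuge, bio, seed):
        eggs = SexedCohort(np.array(counts, dtype=np.int64).reshape(3, 3, 2))
        rng = np.random.default_rng(seed)
        b, r, t = allocate_eggs(eggs, refuge, bio, rng)
        assert ((b.counts + r.counts + t.counts) == eggs.counts).all()

    def test_degenerate_fractions(self, rng):
        eggs = cohort_of((0, 0, FEMALE, 7), (1, 0, MALE, 3))
        b, r, t = allocate_eggs(eggs, 0.0, 0.0, rng)
        assert b.total == 0 and r.total == 0
        assert t == eggs

    def test_refuge_split_is_binomial_in_mean(self, rng):
        """10 eggs at refuge fraction 0.2: mean refuge count ~ 2 over many draws."""
        eggs = cohort_of((0, 0, MALE, 10))
        n_draws = 10_000
        sizes = np.empty(n_draws)
        for i in range(n_draws):
            _, refuge, _ = allocate_eggs(eggs, 0.2, 0.0, rng)
            sizes[i] = refuge.total
        se = np.sqrt(10 * 0.2 * 0.8 / n_draws)
        assert sizes.mean() == pytest.approx(2.0, abs=3 * se)

    def test_expected_split_sizes(self, rng):
        """1000 eggs, 10% bioassay then 10% refuge: ~ (100, 90, 810)."""
        eggs = cohort_of((0, 0, FEMALE, 500), (0, 0, MALE, 500))
        totals = np.zeros(3)
        n_draws = 2000
        for _ in range(n_draws):
            parts = allocate_eggs(eggs, 0.10, 0.10, rng)
            totals += [p.total for p in parts]
        means = totals / n_draws
        assert means[0] == pytest.approx(100, abs=1.0)
        assert means[1] == pytest.approx(90, abs=1.0)
        assert means[2] == pytest.approx(810, abs=1.5)

    def test_invalid_fraction_rejected(self, rng):
        with pytest.raises(ValueError, match="refuge_fraction"):
            allocate_eggs(SexedCohort.empty(), 1.3, 0.0, rng)


class TestSelectAndPupate:
    def test_susceptible_eggs_on_toxin_all_die(self, rng):
        eggs = cohort_of((0, 0, FEMALE, 50), (0, 0, MALE, 50))
        pupae = select_and_pupate(
            eggs, "toxin", SelectionParams(), DemographyParams(), 0.9, rng
        )
        assert pupae.total == 0

    def test_identity_without_mortality(self, rng):
        eggs = cohort_of((2, 1, FEMALE, 30), (0, 2, MALE, 20), (1, 0, FEMALE, 10))
        s = SelectionParams(toxin_survival_by_r=(1, 1, 1), tetracycline=True)
        d = DemographyParams(
            capacity_refuge=float("inf"), capacity_toxin=float("inf")
        )
        for diet in ("refuge", "toxin"):
            assert select_and_pupate(eggs, diet, s, d, 0.5, rng) == eggs

    def test_transgenic_female_larvae_removed(self, rng):
        eggs = cohort_of((0, 1, FEMALE, 40), (0, 1, MALE, 40))
        d = DemographyParams(capacity_refuge=float("inf"))
        pupae = select_and_pupate(eggs, "refuge", SelectionParams(), d, 0.1, rng)
        assert pupae.n_females == 0
        assert pupae.n_males == 40  # refuge survival 1 by default

    def test_capacity_truncation_exact_and_never_inflating(self, rng):
        eggs = cohort_of((0, 0, FEMALE, 300), (2, 0, MALE, 200))
        d = DemographyParams(capacity_refuge=1000.0)  # cap = 1000 * 0.1 = 100
        pupae = select_and_pupate(eggs, "refuge", SelectionParams(), d, 0.1, rng)
        assert pupae.total == 100
        assert (pupae.counts <= eggs.counts).all()

    def test_truncation_preserves_proportions_in_expectation(self, rng):
        eggs = cohort_of((0, 0, FEMALE, 300), (2, 0, MALE, 100))
        d = DemographyParams(capacity_refuge=400.0)  # cap 40 of 400 survivors
        fracs = []
        for _ in range(2000):
            pupae = select_and_pupate(eggs, "refuge", SelectionParams(), d, 0.1, rng)
            fracs.append(pupae.counts[2, 0, MALE] / pupae.total)
        se = np.sqrt(0.25 * 0.75 / 40 / 2000)
        assert np.mean(fracs) == pytest.approx(0.25, abs=4 * se)


class TestSexedCohort:
    def test_allele_frequencies(self):
        c = cohort_of((2, 0, FEMALE, 1), (0, 2, MALE, 1), (1, 1, MALE, 2))
        assert c.allele_frequency("r") == pytest.approx(4 / 8)
        assert c.allele_frequency("l") == pytest.approx(4 / 8)
        assert np.isnan(SexedCohort.empty().allele_frequency("r"))

    def test_negative_counts_rejected(self):
        arr = np.zeros((3, 3, 2), dtype=np.int64)
        arr[0, 0, 0] = -1
        with pytest.raises(ValueError):
            SexedCohort(arr)
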