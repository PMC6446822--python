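"""Dispersal, whack-a-mole targeting, releases and refuge regimes."""

import itertools

import numpy as np
import pytest

from helpers import cohort_of
from ridlsim.lifecycle import FEMALE, MALE, SexedCohort
from ridlsim.metapop import (
    ReleaseStrategy,
    SelectionRegime,
    SubpopState,
    apply_release,
    assign_refuges,
    choose_whack_target,
    disperse,
)


def states_with_pupae(*cohorts):
    return [SubpopState(id=i, pupae=c) for i, c in enumerate(cohorts)]


class TestDisperse:
    def test_symmetric_exchange(self, rng):
        """100 pupae per cage, distinct genotypes: each sends 5+5, keeps 90."""
        subpops = states_with_pupae(
            cohort_of((0, 0, MALE, 100)),
            cohort_of((1, 0, MALE, 100)),
            cohort_of((2, 0, MALE, 100)),
        )
        out = disperse(subpops, 0.10, rng)
        for i, sp in enumerate(out):
            assert sp.pupae.total == 100
            own = sp.pupae.counts[i, 0, MALE]
            assert own == 90
            others = [sp.pupae.counts[j, 0, MALE] for j in range(3) if j != i]
            assert sorted(others) == [5, 5]

    def test_zero_fraction_is_identity(self, rng):
        subpops = states_with_pupae(
            cohort_of((0, 0, FEMALE, 37)), cohort_of((1, 1, MALE, 11)),
            cohort_of((2, 0, MALE, 3)),
        )
        out = disperse(subpops, 0.0, rng)
        for before, after in zip(subpops, out):
            assert before.pupae == after.pupae

    def test_asymmetric_source(self, rng):
        subpops = states_with_pupae(
            cohort_of((0, 0, MALE, 200)), SexedCohort.empty(), SexedCohort.empty()
        )
        out = disperse(subpops, 0.10, rng)
        assert out[0].pupae.total == 180
        assert out[1].pupae.total == 10
        assert out[2].pupae.total == 10

    def test_conserves_every_genotype_count(self, rng_factory):
        for seed in range(10):
            rng = rng_factory(seed)
            cohorts = [
                SexedCohort(rng.integers(0, 60, size=(3, 3, 2))) for _ in range(3)
            ]
            before = sum(c.counts for c in cohorts)
            out = disperse(states_with_pupae(*cohorts), 0.10, rng)
            after = sum(sp.pupae.counts for sp in out)
            assert (before == after).all()


class TestWhackTarget:
    def make(self, counts):
        return [
            SubpopState(id=i, toxin_pupae_count=c) for i, c in enumerate(counts)
        ]

    @pytest.mark.parametrize("counts, expected", [((30, 10, 5), 0), ((0, 0, 4), 2)])
    def test_unique_maximum(self, rng, counts, expected):
        assert choose_whack_target(self.make(counts), rng) == expected

    def test_tie_break_uniform(self, rng):
        picks = np.array(
            [choose_whack_target(self.make((7, 7, 7)), rng) for _ in range(3000)]
        )
        freqs = np.bincount(picks, minlength=3) / len(picks)
        # 4 SD of a Binomial(3000, 1/3) proportion is ~0.034
        assert freqs == pytest.approx([1 / 3] * 3, abs=0.04)

    def test_matches_argmax_oracle_on_all_small_instances(self, rng):
        """Exhaustive check against brute-force argmax for counts in 0..5."""
        for counts in itertools.product(range(6), repeat=3):
            target = choose_whack_target(self.make(counts), rng)
            assert counts[target] == max(counts)


class TestApplyRelease:
    def test_everywhere_ratio(self, rng):
        subpops = states_with_pupae(cohort_of((0, 0, MALE, 50), (0, 0, FEMALE, 50)))
        out, target = apply_release(
            subpops, ReleaseStrategy(mode="everywhere", base_ratio=4), rng
        )
        assert target is None
        assert out[0].released_males == 200
        assert out[0].pupae.counts[0, 2, MALE] == 200

    def test_whack_concentrates_at_target(self, rng):
        subpops = states_with_pupae(
            cohort_of((0, 0, MALE, 50)),
            cohort_of((0, 0, MALE, 50)),
            cohort_of((0, 0, MALE, 50)),
        )
        subpops[1].toxin_pupae_count = 9
        out, target = apply_release(subpops, ReleaseStrategy(mode="whack"), rng)
        assert target == 1
        assert [sp.released_males for sp in out] == [0, 600, 0]

    def test_release_budget_standardized(self, rng):
        """Equal local males: whack (12:1 into one cage) == everywhere (4:1 x3)."""
        def fresh():
            sp = states_with_pupae(*[cohort_of((0, 0, MALE, 40)) for _ in range(3)])
            sp[2].toxin_pupae_count = 1
            return sp

        strategy = ReleaseStrategy(mode="everywhere", base_ratio=4)
        out_e, _ = apply_release(fresh(), strategy, rng)
        whack = ReleaseStrategy(mode="whack", base_ratio=4, whack_multiplier=3)
        out_w, _ = apply_release(fresh(), whack, rng)
        assert whack.whack_ratio == 12.0
        assert sum(sp.released_males for sp in out_e) == sum(
            sp.released_males for sp in out_w
        ) == 480

    def test_released_males_are_llss(self, rng):
        subpops = states_with_pupae(cohort_of((2, 0, MALE, 10)))
        out, _ = apply_release(
            subpops, ReleaseStrategy(mode="everywhere", base_ratio=4), rng
        )
        added = out[0].pupae.counts - subpops[0].pupae.counts
        assert added.sum() == added[0, 2, MALE] == 40  # all S, LL, male

    def test_none_mode_unchanged(self, rng):
        subpops = states_with_pupae(cohort_of((0, 0, MALE, 50)))
        out, target = apply_release(subpops, ReleaseStrategy(mode="none"), rng)
        assert target is None
        assert out[0].pupae == subpops[0].pupae

    def test_all_zero_counts_still_releases_at_random_cage(self, rng):
        subpops = states_with_pupae(*[cohort_of((0, 0, MALE, 10))] * 3)
        out, target = apply_release(subpops, ReleaseStrategy(mode="whack"), rng)
        assert target in (0, 1, 2)
        assert sum(sp.released_males for sp in out) == 120

    def test_skip_release_flag(self, rng):
        subpops = states_with_pupae(*[cohort_of((0, 0, MALE, 10))] * 3)
        strategy = ReleaseStrategy(mode="whack", release_when_no_survivors=False)
        out, target = apply_release(subpops, strategy, rng)
        assert target is None
        assert all(sp.released_males == 0 for sp in out)


class TestAssignRefuges:
    def test_homogeneous_constant(self, rng):
        regime = SelectionRegime(mode="homogeneous", homogeneous_refuge=0.12)
        assert list(assign_refuges(regime, 3, 0, rng)) == [0.12] * 3

    def test_experiment1_refuge(self, rng):
        regime = SelectionRegime(mode="homogeneous", homogeneous_refuge=0.10)
        assert list(assign_refuges(regime, 3, 5, rng)) == [0.10] * 3

    def test_heterogeneous_permutations_uniform(self, rng):
        regime = SelectionRegime(mode="heterogeneous")
        counts = {}
        n_draws = 6000
        for g in range(n_draws):
            perm = tuple(assign_refuges(regime, 3, g, rng))
            assert sorted(perm) == [0.05, 0.10, 0.20]
            counts[perm] = counts.get(perm, 0) + 1
        assert len(counts) == 6
        expected = n_draws / 6
        tol = 4 * np.sqrt(n_draws * (1 / 6) * (5 / 6))
        for n in counts.values():
            assert abs(n - expected) < tol
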