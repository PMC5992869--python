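"""Reward moment matrices for binary, grouped, ordinal and interval outcomes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from numpy.testing import assert_allclose

import healthlong as hl


class TestBinaryRewards:
    def test_literal_mode_half_credit_and_equal_moments(self):
        R = hl.binary_rewards(hl.PrevalenceSchedule([0.3]), alpha=1)
        assert R.R(1)[0, 0] == pytest.approx(0.3)
        assert R.R(1)[1, 0] == pytest.approx(0.15)
        assert_allclose(R.R(2), R.R(1))
        assert_allclose(R.R(3), R.R(1))

    def test_moment_consistent_death_row(self):
        R = hl.binary_rewards(
            hl.PrevalenceSchedule([0.3]), mode="moment_consistent"
        )
        # strict Bernoulli moments of the half-credit reward: v * (1/2)^k
        assert R.R(2)[1, 0] == pytest.approx(0.3 * 0.25)
        assert R.R(3)[1, 0] == pytest.approx(0.3 * 0.125)
        assert R.R(2)[0, 0] == pytest.approx(0.3)

    def test_full_health(self):
        R = hl.binary_rewards(hl.PrevalenceSchedule([1.0, 1.0]))
        living = R.R(1)[:2, :2]
        assert_allclose(living, 1.0)
        assert_allclose(R.R(1)[2, :2], 0.5)

    def test_zero_prevalence_gives_zero_matrices(self):
        R = hl.binary_rewards(hl.PrevalenceSchedule([0.0, 0.0]))
        for k in (1, 2, 3):
            assert_allclose(R.R(k), 0.0)

    def test_absorbing_origin_columns_zero(self):
        R = hl.binary_rewards(hl.PrevalenceSchedule([0.4, 0.9]), alpha=2)
        assert_allclose(R.R(1)[:, 2:], 0.0)

    @given(
        v=st.floats(0.0, 1.0),
        credit=st.floats(0.0, 1.0),
        mode=st.sampled_from(hl.rewards.MODES),
    )
    @settings(max_examples=50, deadline=None)
    def test_per_transition_variance_nonnegative(self, v, credit, mode):
        R = hl.binary_rewards(
            hl.PrevalenceSchedule([v]), mode=mode, death_credit=credit
        )
        var = R.R(2) - R.R(1) ** 2
        if mode == "moment_consistent":
            assert np.all(var >= -1e-12)
            assert var[1, 0] == pytest.approx(v * (1 - v) * credit**2)
        # living transitions are genuinely Bernoulli in both modes
        assert var[0, 0] == pytest.approx(v * (1 - v))


class TestCombinePrevalence:
    H = hl.PrevalenceSchedule([0.5])
    C = hl.PrevalenceSchedule([0.3])
    I = hl.PrevalenceSchedule([0.2])

    def test_grouping_sums_component_prevalences(self):
        free_of_institution = hl.combine_prevalence([self.H, self.C, self.I], {0, 1})
        assert_allclose(free_of_institution.values, [0.8])

    def test_singleton_subset_is_identity(self):
        out = hl.combine_prevalence([self.H, self.C, self.I], {1})
        assert_allclose(out.values, self.C.values)

    def test_full_subset_rejected(self):
        with pytest.raises(ValueError):
            hl.combine_prevalence([self.H, self.C, self.I], {0, 1, 2})

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            hl.combine_prevalence([self.H, self.C], set())

    def test_oversummed_prevalences_rejected(self):
        with pytest.raises(ValueError):
            hl.combine_prevalence(
                [hl.PrevalenceSchedule([0.7]), hl.PrevalenceSchedule([0.7])], {0}
            )

    def test_additivity_over_disjoint_subsets(self):
        parts = [self.H, self.C, self.I]
        a = hl.combine_prevalence(parts, {0})
        b = hl.combine_prevalence(parts, {1})
        both = hl.combine_prevalence(parts, {0, 1})
        assert_allclose(a.values + b.values, both.values)


class TestGroupingsAndSplits:
    @pytest.mark.parametrize("n,expected", [(2, 2), (3, 6), (5, 30)])
    def test_count_matches_subset_enumeration(self, n, expected):
        assert hl.count_groupings(n) == expected
        assert len(hl.rewards.all_groupings(n)) == expected

    def test_too_few_outcomes_rejected(self):
        with pytest.raises(ValueError):
            hl.count_groupings(1)

    def test_ordinal_splits_three_levels(self):
        splits = hl.ordinal_binary_splits(3)
        assert splits == [((0,), (1, 2)), ((0, 1), (2,))]

    @pytest.mark.parametrize("n", [2, 4, 7])
    def test_ordinal_split_count_and_order(self, n):
        splits = hl.ordinal_binary_splits(n)
        assert len(splits) == n - 1
        for low, high in splits:
            assert max(low) < min(high)
            assert sorted(low + high) == list(range(n))


class TestIntervalRewards:
    def test_two_point_sample_moments(self):
        m = hl.OutcomeMomentSchedule.from_samples([np.array([2.0, 4.0])])
        assert_allclose([m.m1, m.m2, m.m3], [[3.0], [10.0], [36.0]])
        R = hl.interval_rewards(m)
        assert R.R(1)[0, 0] == pytest.approx(3.0)
        assert R.R(2)[0, 0] == pytest.approx(10.0)
        assert R.R(3)[0, 0] == pytest.approx(36.0)

    def test_constant_outcome_scales_binary_case(self):
        c = 7.0
        m = hl.OutcomeMomentSchedule([c], [c**2], [c**3])
        R = hl.interval_rewards(m, mode="moment_consistent")
        Rb = hl.binary_rewards(
            hl.PrevalenceSchedule([1.0]), mode="moment_consistent"
        )
        for k in (1, 2, 3):
            assert_allclose(R.R(k), c**k * Rb.R(k))

    def test_negative_outcome_variance_rejected(self):
        with pytest.raises(ValueError):
            hl.OutcomeMomentSchedule([1.0], [0.5], [1.0])


class TestFixedRewards:
    def test_elementwise_powers(self):
        R = hl.binary_rewards(hl.PrevalenceSchedule([0.3]))
        F = hl.fixed_rewards(R)
        assert F.R(2)[0, 0] == pytest.approx(0.09)
        assert F.R(3)[0, 0] == pytest.approx(0.027)

    def test_first_moment_unchanged_variance_zero(self):
        R = hl.binary_rewards(hl.PrevalenceSchedule([0.2, 0.8, 0.5]))
        F = hl.fixed_rewards(R)
        assert_allclose(F.R(1), R.R(1))
        assert_allclose(F.R(2) - F.R(1) ** 2, 0.0, atol=1e-15)

    def test_all_ones_fixed_point(self):
        R1 = np.zeros((2, 2))
        R1[:, 0] = 1.0
        R = hl.RewardMomentSet((R1, R1.copy(), R1.copy()), n_transient=1)
        F = hl.fixed_rewards(R)
        for k in (1, 2, 3):
            assert_allclose(F.R(k), R1)

    def test_zero_rewards_stay_zero(self):
        Z = np.zeros((3, 3))
        F = hl.fixed_rewards(hl.RewardMomentSet((Z, Z, Z), n_transient=2))
        for k in (1, 2, 3):
            assert_allclose(F.R(k), 0.0)


class TestRewardScaling:
    def test_scaled_multiplies_kth_moment_by_c_to_k(self):
        R = hl.binary_rewards(hl.PrevalenceSchedule([0.4, 0.6]))
        S = R.scaled(3.0)
        for k in (1, 2, 3):
            assert_allclose(S.R(k), 3.0**k * R.R(k))
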