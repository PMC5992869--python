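"""Moment recursion, summary statistics, variance decomposition, Sullivan."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from numpy.testing import assert_allclose

import healthlong as hl
from healthlong.moments import InconsistentMomentsError

from conftest import random_bounded_chain


def binary_setup(p, v, mode="paper_literal", death_credit=0.5, split=None):
    sched = hl.MortalitySchedule(tuple(range(len(p))), np.asarray(p, float))
    P = hl.chain_from_schedule(sched, cause_split=split)
    R = hl.binary_rewards(
        hl.PrevalenceSchedule(v), alpha=P.n_absorbing,
        mode=mode, death_credit=death_credit,
    )
    return P, R


class TestAccumulateMoments:
    def test_half_year_credit_enumeration(self):
        # from class 1: die in year 1 (reward 1/2) or survive then die (3/2)
        P, R = binary_setup([0.5, 0.0], [1.0, 1.0], mode="moment_consistent")
        rho = hl.accumulate_moments(P, R)
        assert rho.moment(1)[0] == pytest.approx(1.0, abs=1e-14)
        assert rho.moment(2)[0] == pytest.approx(1.25, abs=1e-14)
        assert rho.moment(3)[0] == pytest.approx(1.75, abs=1e-14)

    def test_zero_rewards_give_zero_moments(self):
        P, _ = binary_setup([0.5, 0.0], [1.0, 1.0])
        Z = np.zeros((3, 3))
        rho = hl.accumulate_moments(
            P, hl.RewardMomentSet((Z, Z, Z), n_transient=2)
        )
        for k in (1, 2, 3):
            assert_allclose(rho.moment(k), 0.0)

    def test_unit_reward_reproduces_longevity_moments(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            sched, P = random_bounded_chain(rng)
            R = hl.unit_rewards(
                sched.n_classes, alpha=P.n_absorbing, death_credit=1.0
            )
            rho = hl.accumulate_moments(P, R)
            eta = hl.longevity_moments(
                hl.fundamental_matrix(hl.TransientMatrix(P.U))
            )
            for k, vec in enumerate((eta.eta1, eta.eta2, eta.eta3), 1):
                assert_allclose(rho.moment(k), vec, atol=1e-10)

    def test_transient_only_unit_reward_is_longevity_minus_one(self):
        rng = np.random.default_rng(18)
        for _ in range(10):
            sched, P = random_bounded_chain(rng)
            R = hl.unit_rewards(
                sched.n_classes, alpha=P.n_absorbing, death_credit=0.0
            )
            rho1 = hl.accumulate_moments(P, R, max_order=1).moment(1)
            eta1 = hl.longevity_moments(
                hl.fundamental_matrix(hl.TransientMatrix(P.U))
            ).eta1
            assert_allclose(rho1, eta1 - 1.0, atol=1e-10)

    def test_order_beyond_available_moments_rejected(self):
        P, R = binary_setup([0.5, 0.0], [0.5, 0.5])
        with pytest.raises(ValueError, match="max_order"):
            hl.accumulate_moments(P, R, max_order=4)

    def test_general_recursion_supports_higher_orders(self):
        # 4th moment of accumulated unit-per-step reward vs enumeration
        P, _ = binary_setup([0.5, 0.0], [1.0, 1.0])
        w = 2
        mats = []
        for k in range(1, 5):
            R = np.zeros((3, 3))
            R[:, :w] = 1.0
            mats.append(R)
        R4 = hl.RewardMomentSet(tuple(mats), n_transient=w)
        rho = hl.accumulate_moments(P, R4, max_order=4)
        ts, ps = hl.lifetime_distribution(P, 0)
        assert rho.moment(4)[0] == pytest.approx(float(np.sum(ps * ts**4)), abs=1e-12)

    @given(c=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_reward_scaling_law(self, c):
        P, R = binary_setup([0.7, 0.4, 0.0], [0.2, 0.9, 0.5])
        rho = hl.accumulate_moments(P, R)
        rho_c = hl.accumulate_moments(P, R.scaled(c))
        for k in (1, 2, 3):
            assert_allclose(rho_c.moment(k), c**k * rho.moment(k), rtol=1e-10)
        s, s_c = hl.lifetime_statistics(rho), hl.lifetime_statistics(rho_c)
        assert_allclose(s_c.mean, c * s.mean, rtol=1e-10)
        assert_allclose(s_c.variance, c**2 * s.variance, rtol=1e-9)
        assert_allclose(s_c.skewness, s.skewness, rtol=1e-7)

    @given(data=st.data())
    @settings(max_examples=30, deadline=None)
    def test_mean_monotone_in_prevalence(self, data):
        p = [0.6, 0.3, 0.0]
        v = data.draw(
            st.lists(st.floats(0.0, 0.98), min_size=3, max_size=3)
        )
        bump = data.draw(st.floats(0.0, 0.02))
        idx = data.draw(st.integers(0, 2))
        v2 = list(v)
        v2[idx] = min(v2[idx] + bump, 1.0)
        _, R = binary_setup(p, v)
        P, R2 = binary_setup(p, v2)
        r1 = hl.accumulate_moments(P, R, max_order=1).moment(1)
        r2 = hl.accumulate_moments(P, R2, max_order=1).moment(1)
        assert np.all(r2 - r1 >= -1e-12)


class TestLifetimeStatistics:
    def test_arithmetic_identities(self):
        stats = hl.lifetime_statistics(
            hl.MomentVectorSet((np.array([2.0]), np.array([6.0])))
        )
        assert stats.variance[0] == pytest.approx(2.0)
        assert stats.sd[0] == pytest.approx(np.sqrt(2.0))
        assert stats.cv[0] == pytest.approx(np.sqrt(2.0) / 2.0)
        assert np.isnan(stats.skewness[0])  # third moment absent

    def test_symmetric_case_has_zero_skewness(self):
        stats = hl.lifetime_statistics(
            hl.MomentVectorSet(
                (np.array([1.0]), np.array([2.0]), np.array([4.0]))
            )
        )
        assert stats.skewness[0] == pytest.approx(0.0)

    def test_degenerate_reward_reports_missing(self):
        # fixed lifetime, fixed reward: variance 0, cv defined, skewness NaN
        stats = hl.lifetime_statistics(
            hl.MomentVectorSet(
                (np.array([3.0, 0.0]), np.array([9.0, 0.0]), np.array([27.0, 0.0]))
            )
        )
        assert stats.variance[0] == 0.0
        assert np.isnan(stats.skewness[0])
        assert np.isnan(stats.cv[1])  # zero mean: CV missing

    def test_tiny_negative_variance_clamped_large_rejected(self):
        ok = hl.lifetime_statistics(
            hl.MomentVectorSet((np.array([1.0]), np.array([1.0 - 1e-12])))
        )
        assert ok.variance[0] == 0.0
        with pytest.raises(InconsistentMomentsError):
            hl.lifetime_statistics(
                hl.MomentVectorSet((np.array([1.0]), np.array([0.9])))
            )


class TestVarianceDecomposition:
    def test_components_sum_exactly(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            sched, P = random_bounded_chain(rng)
            v = rng.uniform(0, 1, size=sched.n_classes)
            R = hl.binary_rewards(
                hl.PrevalenceSchedule(v), alpha=P.n_absorbing
            )
            total, among, within = hl.decompose_variance(P, R)
            assert_allclose(among + within, total, atol=1e-10)
            assert np.all(within >= 0) and np.all(among >= 0)

    def test_fixed_rewards_have_no_within_component(self):
        P, R = binary_setup([0.6, 0.3, 0.0], [0.3, 0.8, 0.5])
        _, _, within = hl.decompose_variance(P, hl.fixed_rewards(R))
        assert_allclose(within, 0.0, atol=1e-12)

    def test_deterministic_per_step_reward_is_all_among(self):
        # single open-ended class, v=1, reward 1 per survival step:
        # lifetime reward = number of survivals ~ geometric, var p/(1-p)^2
        p = 0.5
        sched = hl.MortalitySchedule((0,), [p], open_ended=True)
        P = hl.chain_from_schedule(sched)
        R = hl.binary_rewards(hl.PrevalenceSchedule([1.0]), death_credit=0.0)
        total, among, within = hl.decompose_variance(P, R)
        assert_allclose(within, 0.0, atol=1e-12)
        assert_allclose(total, p / (1 - p) ** 2, rtol=1e-12)

    def test_single_trajectory_chain_is_all_within(self):
        # all survive until a forced death: exactly one path exists
        P, R = binary_setup([1.0, 1.0, 0.0], [0.5, 0.5, 0.5])
        total, among, within = hl.decompose_variance(P, R)
        assert_allclose(among, 0.0, atol=1e-12)
        assert_allclose(within, total, atol=1e-12)


class TestSullivan:
    def test_direct_partial_sums(self):
        L = np.array([1.0, 0.5])
        v = np.array([1.0, 1.0])
        assert hl.sullivan_expectancy(L, v, x=0) == pytest.approx(1.5)
        assert hl.sullivan_expectancy(L, v, x=1) == pytest.approx(0.5)
        assert hl.sullivan_expectancy(L, np.zeros(2), x=0) == 0.0

    def test_out_of_range_start_rejected(self):
        with pytest.raises(IndexError):
            hl.sullivan_expectancy(np.ones(2), np.ones(2), x=2)

    @pytest.mark.parametrize("mode", ["paper_literal", "moment_consistent"])
    def test_matches_first_moment_of_binary_rewards(self, mode):
        """Sullivan HE(x) = rho_1[x] with L_j = occupancy times the expected
        fraction of the step lived (1 surviving, death_credit dying)."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            sched, P = random_bounded_chain(rng, max_omega=3, max_alpha=1)
            v = rng.uniform(0, 1, size=sched.n_classes)
            R = hl.binary_rewards(hl.PrevalenceSchedule(v), mode=mode)
            rho1 = hl.accumulate_moments(P, R, max_order=1).moment(1)
            for x in range(sched.n_classes):
                L = hl.occupancy_person_years(P, start=x, death_credit=0.5)
                he = hl.sullivan_expectancy(L, v, x=x)
                assert he == pytest.approx(rho1[x], abs=1e-12)
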