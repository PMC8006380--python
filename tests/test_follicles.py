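"""Poisson recruitment, the follicle growth law and life-cycle rules."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import ovsim
from ovsim.config import GrowthParams, RecruitmentParams
from ovsim.follicles import (Follicle, FollicleStatus, eligible_for_ovulation,
                             follicle_rhs, growth_rates, recruit,
                             update_lifecycle)


class TestRecruit:
    def test_requires_positive_interval(self, rng):
        with pytest.raises(ValueError):
            recruit(0.0, 0.0, 5.0, rng, RecruitmentParams(), 0)

    def test_poisson_moments(self, rng):
        """Sample mean of 10,000 unit-interval draws is within 3 standard
        errors of the configured intensity."""
        p = RecruitmentParams(base_rate=0.8, elevated_rate=2.0,
                              fsh_recruit_threshold=9.0)
        counts = [len(recruit(0.0, 1.0, 5.0, rng, p, 0)) for _ in range(10_000)]
        se = np.sqrt(p.base_rate / len(counts))
        assert abs(np.mean(counts) - p.base_rate) < 3 * se

    def test_rate_switch_above_threshold(self, rng):
        p = RecruitmentParams(base_rate=0.5, elevated_rate=5.0,
                              fsh_recruit_threshold=9.0)
        low = [len(recruit(0, 1.0, 8.9, rng, p, 0)) for _ in range(3000)]
        high = [len(recruit(0, 1.0, 9.1, rng, p, 0)) for _ in range(3000)]
        assert np.mean(high) > 3 * np.mean(low)

    def test_recruit_properties(self, rng):
        p = RecruitmentParams()
        out = recruit(5.0, 2.0, 20.0, rng, p, next_id=17)
        for k, f in enumerate(out):
            assert f.id == 17 + k
            assert 5.0 <= f.t_recruited <= 7.0
            assert f.fsh_sensitivity > 0
            assert f.size == p.seed_size
            assert f.status is FollicleStatus.GROWING

    def test_sensitivity_truncated_positive(self, rng):
        """Even with a near-zero mean, drawn sensitivities stay positive."""
        p = RecruitmentParams(sens_mean=0.1, sens_sd=2.0)
        sens = [f.fsh_sensitivity
                for f in recruit(0.0, 400.0, 20.0, rng, p, 0)]
        assert len(sens) > 50
        assert min(sens) > 0


class TestGrowthLaw:
    def test_gate_below_sensitivity_blocks_growth(self):
        g = GrowthParams()
        f = Follicle(0, 0.0, fsh_sensitivity=10.0, size=5.0)
        rate = follicle_rhs(f, [f], fsh_ovary=1.0, fsh_rec_complex=20.0,
                            p4=0.0, params=g)
        assert rate <= 0.0  # no growth contribution, only regression

    def test_saturation_toward_max_size(self):
        g = GrowthParams()
        f = Follicle(0, 0.0, fsh_sensitivity=2.0, size=g.max_size * 0.999)
        rate = follicle_rhs(f, [f], fsh_ovary=30.0, fsh_rec_complex=30.0,
                            p4=0.0, params=g)
        assert abs(rate) < 0.1

    def test_single_follicle_grows(self):
        g = GrowthParams()
        f = Follicle(0, 0.0, fsh_sensitivity=3.0, size=6.0)
        rate = follicle_rhs(f, [f], fsh_ovary=20.0, fsh_rec_complex=20.0,
                            p4=0.0, params=g)
        assert rate > 0.0

    def test_non_growing_follicle_rejected(self):
        g = GrowthParams()
        f = Follicle(0, 0.0, 3.0, 6.0, status=FollicleStatus.ATRETIC)
        with pytest.raises(ValueError):
            follicle_rhs(f, [f], 20.0, 20.0, 0.0, g)

    def test_competition_off_growth_is_monotone(self):
        """With competition disabled, no P4 and saturating FSH, every
        follicle's size is non-decreasing; trajectory matches the direct
        integration of the uncoupled single-follicle equation."""
        g = GrowthParams(competition_strength=0.0)
        sens = np.array([3.0, 4.0, 5.0])
        sizes0 = np.array([2.0, 5.0, 9.0])

        def rhs(t, s):
            return growth_rates(s, sens, fsh_ovary=40.0, fsh_rec_complex=40.0,
                                p4=0.0, params=g)

        sol = solve_ivp(rhs, (0, 20), sizes0, dense_output=True, rtol=1e-8)
        traj = sol.sol(np.linspace(0, 20, 200))
        assert np.all(np.diff(traj, axis=1) >= -1e-9)

        # oracle: scalar logistic ODE for one uncoupled follicle
        def scalar(t, s):
            return growth_rates(np.array([s[0]]), sens[:1], 40.0, 40.0, 0.0,
                                g)
        one = solve_ivp(scalar, (0, 20), sizes0[:1], rtol=1e-8)
        assert one.y[0, -1] == pytest.approx(traj[0, -1], rel=1e-5)

    def test_lower_sensitivity_reaches_size_first(self):
        """In a two-follicle race with equal start, the more sensitive
        follicle (lower threshold) leads at every instant."""
        g = GrowthParams(competition_strength=0.0)
        sens = np.array([4.0, 8.0])

        def rhs(t, s):
            return growth_rates(s, sens, fsh_ovary=6.0, fsh_rec_complex=6.0,
                                p4=0.0, params=g)

        sol = solve_ivp(rhs, (0, 30), [2.0, 2.0], rtol=1e-8)
        assert np.all(sol.y[0, 1:] >= sol.y[1, 1:])

    def test_larger_competitors_suppress(self):
        """The dominance load only runs downhill: the largest follicle feels
        no competition, smaller ones do."""
        g = GrowthParams(competition_strength=1.0, dominance_size=30.0)
        sens = np.array([3.0, 3.0])
        sizes = np.array([18.0, 6.0])
        with_comp = growth_rates(sizes, sens, 6.0, 6.0, 0.0, g)
        g0 = GrowthParams(competition_strength=0.0, dominance_size=30.0)
        without = growth_rates(sizes, sens, 6.0, 6.0, 0.0, g0)
        assert with_comp[0] == pytest.approx(without[0])     # leader untouched
        assert with_comp[1] < without[1]                     # follower slowed

    def test_high_fsh_opens_the_window(self):
        """Competition is switched off above the FSH window threshold, so
        several follicles can keep growing together under stimulation."""
        g = GrowthParams(competition_strength=0.5, dominance_size=50.0)
        sens = np.array([3.0, 5.0])
        sizes = np.array([16.0, 10.0])
        low = growth_rates(sizes, sens, g.fsh_window_threshold * 0.5, 20.0,
                           0.0, g)
        high = growth_rates(sizes, sens, g.fsh_window_threshold * 3.0, 20.0,
                            0.0, g)
        assert high[1] > low[1]
        assert high[1] > 0.0


class TestLifecycle:
    def test_atresia_below_floor(self):
        g = GrowthParams()
        shrunk = Follicle(0, 0.0, 5.0, size=g.atresia_floor * 0.5)
        fine = Follicle(1, 0.0, 5.0, size=5.0)
        retired = update_lifecycle([shrunk, fine], t=3.0, params=g)
        assert retired == [0]
        assert shrunk.status is FollicleStatus.ATRETIC
        assert shrunk.t_retired == 3.0
        assert fine.status is FollicleStatus.GROWING

    def test_retired_never_reexamined(self):
        g = GrowthParams()
        f = Follicle(0, 0.0, 5.0, size=0.1, status=FollicleStatus.OVULATED)
        assert update_lifecycle([f], 1.0, g) == []

    @pytest.mark.parametrize("sizes, threshold, expected", [
        ([], 18.0, []),
        ([12.0, 19.0], 18.0, [1]),
        ([18.0, 18.2, 7.0], 18.0, [0, 1]),
    ])
    def test_eligibility(self, sizes, threshold, expected):
        g = GrowthParams(ovulation_size_threshold=threshold)
        cohort = [Follicle(i, 0.0, 5.0, s) for i, s in enumerate(sizes)]
        assert eligible_for_ovulation(cohort, g) == expected

    def test_ovulated_excluded_from_eligibility(self):
        g = GrowthParams()
        f = Follicle(0, 0.0, 5.0, 20.0, status=FollicleStatus.OVULATED)
        assert eligible_for_ovulation([f], g) == []
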