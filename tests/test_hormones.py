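"""Hill machinery, luteal steroid curves, follicular E2 and the endocrine RHS."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ovsim
from ovsim.config import HillSpec, LutealCurveParams
from ovsim.hormones import (IDX, N_HORMONE_STATES, default_initial_state,
                            follicular_e2, hill, hormone_rhs, luteal_steroids,
                            steroid_levels)


class TestHill:
    @pytest.mark.parametrize("x, spec, expected", [
        (5.0, HillSpec(5.0, 1.0), 0.5),            # half-effect at threshold
        (5.0, HillSpec(5.0, 7.3), 0.5),            # for any exponent
        (0.0, HillSpec(2.0, 2.0), 0.0),            # stimulatory boundary
        (0.0, HillSpec(2.0, 2.0, "inhibitory"), 1.0),
        (2.0, HillSpec(1.0, 2.0), 0.8),            # 2T, n=2 -> 4/(1+4)
    ])
    def test_known_values(self, x, spec, expected):
        assert hill(x, spec) == pytest.approx(expected)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            hill(1.0, HillSpec(-1.0, 2.0))
        with pytest.raises(ValueError):
            hill(1.0, HillSpec(1.0, 0.0))

    @given(x=st.floats(0, 1e4), threshold=st.floats(0.01, 1e3),
           exponent=st.floats(0.1, 12))
    @settings(max_examples=200, deadline=None)
    def test_complementarity_and_bounds(self, x, threshold, exponent):
        """Stimulatory and inhibitory branches are complementary and both
        stay inside [0, 1]."""
        up = hill(x, HillSpec(threshold, exponent, "stimulatory"))
        down = hill(x, HillSpec(threshold, exponent, "inhibitory"))
        assert 0.0 <= up <= 1.0
        assert 0.0 <= down <= 1.0
        assert up + down == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_input(self):
        spec = HillSpec(6.0, 3.0)
        xs = np.linspace(0, 30, 100)
        ys = hill(xs, spec)
        assert np.all(np.diff(ys) >= 0)


class TestLutealSteroids:
    def test_no_prior_ovulation(self):
        assert luteal_steroids(10.0, None, LutealCurveParams()) == (0.0, 0.0)

    def test_peak_at_offset(self):
        p = LutealCurveParams()
        e2, p4 = luteal_steroids(20.0 + p.peak_offset, 20.0, p)
        assert p4 == pytest.approx(p.amplitude_p4)
        assert e2 == pytest.approx(p.amplitude_e2)

    def test_peak_is_mid_luteal(self):
        """The P4 maximum falls mid-way through the fixed 14-day phase."""
        p = LutealCurveParams()
        assert p.peak_offset == pytest.approx(p.luteal_length / 2.0)

    def test_zero_outside_support(self):
        p = LutealCurveParams()
        assert luteal_steroids(19.9, 20.0, p) == (0.0, 0.0)
        assert luteal_steroids(20.0 + p.luteal_length + 0.01, 20.0, p) == (0.0, 0.0)

    def test_support_cutoff_is_small(self):
        """Where the curve is cut off, it is already < 1% of its peak."""
        p = LutealCurveParams()
        edge = np.exp(-0.5 * ((p.luteal_length - p.peak_offset) / p.width) ** 2)
        assert edge < 0.01


class TestFollicularE2:
    def test_empty_cohort(self, params):
        assert follicular_e2([], params) == 0.0

    def test_additivity(self, params):
        one = follicular_e2([10.0], params)
        two = follicular_e2([10.0, 10.0], params)
        assert two == pytest.approx(2 * one)

    def test_monotone_in_size(self, params):
        sizes = np.linspace(1, 22, 40)
        vals = [follicular_e2([s], params) for s in sizes]
        assert np.all(np.diff(vals) > 0)

    def test_dominant_follicle_dominates(self, params):
        """A single large follicle outweighs a crowd of small ones."""
        assert (follicular_e2([18.0], params)
                > follicular_e2([4.0] * 10, params))


class TestHormoneRhs:
    def test_zero_state_derivatives(self, params):
        """From an all-zero state, pools with constitutive synthesis grow and
        nothing is cleared."""
        d = hormone_rhs(0.0, np.zeros(N_HORMONE_STATES), e2=0.0, p4=0.0,
                        dose_input=0.0, params=params.hormone_core)
        assert np.all(d >= 0.0)
        assert d[IDX["lh_pit"]] > 0
        assert d[IDX["fsh_pit"]] > 0

    def test_dose_input_linear(self, params):
        """Doubling the exogenous input raises d(fsh_ovary)/dt by exactly
        the increment and touches nothing else."""
        y = default_initial_state()
        d1 = hormone_rhs(0.0, y, 50.0, 0.5, 3.0, params.hormone_core)
        d2 = hormone_rhs(0.0, y, 50.0, 0.5, 6.0, params.hormone_core)
        diff = d2 - d1
        assert diff[IDX["fsh_ovary"]] == pytest.approx(3.0)
        mask = np.ones(N_HORMONE_STATES, bool)
        mask[IDX["fsh_ovary"]] = False
        assert np.allclose(diff[mask], 0.0)

    def test_non_finite_state_rejected(self, params):
        y = default_initial_state()
        y[0] = np.nan
        with pytest.raises(ovsim.IntegrationFailure):
            hormone_rhs(0.0, y, 50.0, 0.5, 0.0, params.hormone_core)

    def test_p4_suppresses_gonadotropin_synthesis(self, params):
        """Luteal-level P4 lowers both LH and FSH synthesis terms."""
        y = default_initial_state()
        low = hormone_rhs(0.0, y, 50.0, 0.3, 0.0, params.hormone_core)
        high = hormone_rhs(0.0, y, 50.0, 12.0, 0.0, params.hormone_core)
        assert high[IDX["lh_pit"]] < low[IDX["lh_pit"]]
        assert high[IDX["fsh_pit"]] < low[IDX["fsh_pit"]]


def test_steroid_levels_compose(params):
    """Total E2 = baseline + luteal + follicular; P4 = baseline + luteal."""
    hc = params.hormone_core
    e2, p4 = steroid_levels(10.0, [12.0], None, params)
    assert e2 == pytest.approx(hc.e2_baseline + follicular_e2([12.0], params))
    assert p4 == pytest.approx(hc.p4_baseline)
    e2l, p4l = steroid_levels(7.0 + 3.0, [], 3.0, params)
    assert p4l > hc.p4_baseline
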