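"""Model assembly and channel-kinetics unit tests.

Expected values tagged as hand-derived were computed independently from the
closed forms (sigmoid evaluations, rate-ratio limits, ODE steady states)
before being frozen here.
"""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from picsim import (build_default_model, build_model, extend_dendrite,
                    ModelConfig, ChannelKinetics, gating_steady_state,
                    gating_time_constant, nap_s_inf, channel_current, step_ca)
from picsim.model import (SectionGeometry, ConductancePlacement, CA_INF,
                          nap_s_rates, E_LEAK)


class TestGeometry:
    def test_soma_area_matches_cylinder(self, default_model):
        sl = default_model.section_slices["soma"]
        area_um2 = default_model.area_cm2[sl].sum() * 1e8
        assert area_um2 == pytest.approx(753.98, rel=0.005)

    def test_dendrite_default_dimensions(self, default_model):
        dend = default_model.sections[-1]
        assert dend.name == "dendrite"
        assert dend.n_compartments == 25
        assert dend.length_um == 600.0

    def test_dendrite_taper_rises_then_falls_to_closed_tip(self, default_model):
        d = np.asarray(default_model.sections[-1].diameter_profile_um)
        peak = int(np.argmax(d))
        assert d[0] < d[peak]
        assert np.all(np.diff(d[: peak + 1]) > 0)
        assert np.all(np.diff(d[peak:]) < 0)
        assert d.max() == pytest.approx(5.4, abs=0.2)
        assert d[-1] < 0.2  # closed taper tip (floored for area)

    def test_cal_confined_to_mid_dendritic_zone(self, default_model):
        m = default_model
        g = m.g_chan_ms["CaL"]
        nz = np.flatnonzero(g)
        sl = m.section_slices["dendrite"]
        n = sl.stop - sl.start
        pos = (nz - sl.start + 0.5) / n
        assert np.all(nz >= sl.start), "CaL must live in the dendrite only"
        assert np.all((pos > 0.32) & (pos < 0.56))
        # zone is the full (0.32, 0.56) interval at 25 compartments
        assert nz.size == 6

    def test_chain_is_unbranched_with_symmetric_coupling(self, default_model):
        m = default_model
        assert m.g_axial_ms.shape == (m.n_compartments - 1,)
        assert np.all(m.g_axial_ms > 0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            SectionGeometry("soma", 0, 20.0, (), 16666.0, 70.0, 1.0)
        with pytest.raises(ValueError):
            SectionGeometry("soma", 1, 20.0, (-1.0,), 16666.0, 70.0, 1.0)
        with pytest.raises(ValueError):
            ConductancePlacement("CaL", "dendrite", (0.6, 0.4), 0.03)
        with pytest.raises(KeyError):
            ConductancePlacement("NaX", "dendrite", (0.0, 1.0), 0.03)

    def test_unknown_config_key_rejected(self):
        with pytest.raises(KeyError):
            ModelConfig().with_overrides(g_nax_pct=50)


class TestGating:
    @pytest.mark.parametrize("channel,gate,v,expected", [
        ("NaP", "m", -37.3, 0.5),          # half-activation voltage
        ("CaL", "m", -41.0, 0.5),          # V_1/2 definition
        ("Kdr", "n", -25.0, 0.5),          # sigmoid midpoint
        ("NaP", "m", -32.3, 1 / (1 + math.exp(-1.0))),  # one slope above half
        ("NaT", "h", -40.5, 0.5),
    ])
    def test_steady_state_anchors(self, channel, gate, v, expected):
        assert gating_steady_state(channel, gate, v) == pytest.approx(expected, abs=1e-9)

    def test_unknown_gate_errors(self):
        with pytest.raises(KeyError):
            gating_steady_state("NaP", "h", -50.0)
        with pytest.raises(ValueError):
            gating_steady_state("NaP", "m", float("nan"))

    @given(v=st.floats(-120, 60), sgate=st.floats(0, 1))
    def test_all_steady_states_bounded(self, v, sgate):
        k = ChannelKinetics(nap_s_gate=sgate)
        for ch, g in [("NaT", "m"), ("NaT", "h"), ("NaP", "m"), ("NaP", "s"),
                      ("Kdr", "n"), ("CaL", "m"), ("CaHVA", "m")]:
            val = gating_steady_state(ch, g, v, k)
            assert 0.0 <= val <= 1.0

    @given(v=st.floats(-120, 60))
    def test_time_constants_positive(self, v):
        for ch, g in [("NaT", "m"), ("NaT", "h"), ("NaP", "s"), ("Kdr", "n")]:
            assert gating_time_constant(ch, g, v) > 0


class TestNaPSlowGate:
    def test_pinned_open_at_sgate_one(self):
        for v in (-100.0, -60.0, -30.0, 0.0):
            assert nap_s_inf(v, 1.0) == pytest.approx(1.0)

    def test_hyperpolarized_limit_is_full_availability(self):
        # alpha_s dominates at very negative V, so s_inf -> 1 even at floor 0
        assert nap_s_inf(-200.0, 0.0) == pytest.approx(1.0, abs=1e-3)

    def test_rate_ratio_value_at_minus_17(self):
        # beta_s(-17) = 0.0034/2; frozen from the corrected closed form
        a_s = 0.001 * math.exp(-(-17.0 + 85.0) / 30.0)
        expected = a_s / (a_s + 0.0017)
        assert nap_s_inf(-17.0, 0.0) == pytest.approx(expected, rel=1e-12)

    def test_slow_time_constant_near_threshold(self):
        # the gate must be slow (hundreds of ms to seconds) where PICs live,
        # otherwise no ramp hysteresis is possible
        for v in (-60.0, -45.0, -30.0):
            assert gating_time_constant("NaP", "s", v) > 300.0

    @given(v=st.floats(-100, 20), s1=st.floats(0, 1), s2=st.floats(0, 1))
    def test_monotone_in_floor_and_bounded_below_by_it(self, v, s1, s2):
        lo, hi = sorted((s1, s2))
        assert nap_s_inf(v, lo) <= nap_s_inf(v, hi) + 1e-12
        assert nap_s_inf(v, lo) >= lo - 1e-12

    def test_floor_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            nap_s_inf(-50.0, 1.5)


class TestChannelCurrent:
    def test_closed_activation_gate_means_no_current(self):
        assert channel_current("NaT", 0.0, {"m": 0.0, "h": 1.0}, g_max=30.0) == 0.0

    def test_nap_driving_force_sign(self):
        i = channel_current("NaP", 0.0, {"m": 1.0, "s": 1.0}, g_max=1.0)
        assert i == pytest.approx(-50.0)  # inward below E_Na

    def test_kca_silent_at_resting_calcium(self):
        n_inf = gating_steady_state("KCa", "n", -60.0, ca=CA_INF)
        assert n_inf == 0.0
        assert channel_current("KCa", -60.0, {"n": n_inf}, g_max=0.18) == 0.0


class TestCalciumPool:
    def test_resting_level_is_fixed_point(self):
        assert step_ca(CA_INF, 0.0, 1.0, 120.0, 100.0) == pytest.approx(CA_INF)

    def test_relaxation_rate(self):
        dt = 0.01
        ca = step_ca(CA_INF + 1.0, 0.0, dt, 120.0, 100.0)
        # linear relaxation toward Ca_inf at rate 1/tau
        assert (CA_INF + 1.0 - ca) == pytest.approx(1.0 * dt / 120.0, rel=1e-3)

    def test_steady_state_matches_fine_integration_oracle(self):
        # closed form: Ca_ss = Ca_inf - gain*i*tau; oracle: brute-force Euler
        i_ca, tau, depth, gain_scale = -2.0, 76.0, 0.6, 0.135
        gain = gain_scale / depth
        ca, dt = CA_INF, 0.001
        for _ in range(int(20 * tau / dt)):
            ca += dt * ((CA_INF - ca) / tau - gain * i_ca)
        expected = CA_INF - gain * i_ca * tau
        assert ca == pytest.approx(expected, rel=1e-6)
        stepped = CA_INF
        for _ in range(2000):
            stepped = step_ca(stepped, i_ca, 10.0, tau, depth, gain_scale=gain_scale)
        assert stepped == pytest.approx(expected, rel=1e-9)

    def test_inward_current_raises_calcium(self):
        assert step_ca(CA_INF, -1.0, 5.0, 120.0, 100.0) > CA_INF

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            step_ca(CA_INF, 0.0, 0.0, 120.0, 100.0)


class TestExtendDendrite:
    def test_identity_at_100_percent(self, default_model):
        m = extend_dendrite(default_model, 100.0)
        assert m.total_conductance("CaL") == pytest.approx(
            default_model.total_conductance("CaL"))
        assert m.n_compartments == default_model.n_compartments

    @pytest.mark.parametrize("pct,factor", [(200.0, 2.0), (300.0, 3.0)])
    def test_total_cal_conductance_scales_with_length(self, default_model, pct, factor):
        m = extend_dendrite(default_model, pct)
        base = default_model.total_conductance("CaL")
        assert m.total_conductance("CaL") == pytest.approx(base * factor, rel=0.01)
        dend = m.sections[-1]
        assert dend.length_um == pytest.approx(600.0 * pct / 100.0)
        assert dend.n_compartments == round(25 * pct / 100.0)

    def test_zone_stays_relative(self, default_model):
        m = extend_dendrite(default_model, 300.0)
        sl = m.section_slices["dendrite"]
        n = sl.stop - sl.start
        nz = np.flatnonzero(m.g_chan_ms["CaL"]) - sl.start
        pos = (nz + 0.5) / n
        assert pos.min() > 0.32 and pos.max() < 0.56

    def test_invalid_percent_rejected(self, default_model):
        with pytest.raises(ValueError):
            extend_dendrite(default_model, 0.0)
        with pytest.raises(ValueError):
            extend_dendrite(default_model, 5.0)
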