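"""Clamp-protocol tests: ideal clamp, linearity, metadata, membrane battery."""

import numpy as np
import pytest

from picsim import (build_default_model, build_model, ModelConfig, integrate,
                    RampProtocol, run_voltage_clamp_biramp,
                    run_current_clamp_biramp, leak_subtract,
                    extract_pic_features, extract_firing_features)
from picsim.protocols import (measure_input_resistance, find_rheobase,
                              measure_resting_potential, DEFAULT_CURRENT_RAMP)

FAST_VRAMP = RampProtocol("voltage", start=-70.0, peak=0.0,
                          duration_ms=4000.0, settle_ms=500.0)


@pytest.fixture(scope="module")
def passive_model():
    return build_default_model().passive_copy()


class TestVoltageClamp:
    def test_ideal_clamp_pins_soma_to_command(self, passive_model):
        ramp = FAST_VRAMP
        nsteps = int(round((ramp.settle_ms + ramp.duration_ms) / 0.025))
        t = np.arange(nsteps + 1) * 0.025
        cmd = ramp.command(t - ramp.settle_ms)
        state = integrate(passive_model, cmd, duration_ms=t[-1], dt_ms=0.025,
                          mode="voltage")
        assert np.max(np.abs(state.v_soma - state.command)) < 0.01

    def test_passive_iv_is_linear_and_leak_subtracts_to_zero(self, passive_model):
        trace = run_voltage_clamp_biramp(passive_model, FAST_VRAMP)
        sub = leak_subtract(trace)
        # only the constant dendritic charging offset of the descending limb
        # may remain after removing the ascending-limb leak line
        assert np.max(np.abs(sub.signal)) < 6.0
        assert not extract_pic_features(sub).has_pic

    def test_default_model_has_ccw_pic_with_both_troughs(self, default_vclamp_trace):
        f = extract_pic_features(leak_subtract(default_vclamp_trace))
        assert f.a_pic is not None and f.d_pic is not None
        assert f.a_pic > f.d_pic
        assert f.trajectory == "counterclockwise"
        assert f.v_onset is not None and f.v_offset is not None

    def test_tea_flag_removes_potassium_conductances(self):
        m = build_model(ModelConfig(tea=True))
        assert m.total_conductance("Kdr") == 0.0
        assert m.total_conductance("KCa") == 0.0
        assert m.total_conductance("NaT") > 0.0

    def test_wrong_ramp_mode_rejected(self, passive_model):
        with pytest.raises(ValueError):
            run_voltage_clamp_biramp(passive_model, DEFAULT_CURRENT_RAMP)


class TestCurrentClamp:
    def test_zero_peak_stays_near_rest_without_spikes(self, default_model):
        ramp = RampProtocol("current", start=0.0, peak=0.0, duration_ms=2000.0,
                            settle_ms=500.0)
        trace = run_current_clamp_biramp(default_model, ramp)
        assert trace.signal.max() < -50.0
        assert not extract_firing_features(trace).has_firing

    def test_default_ramp_fires_on_both_limbs(self, default_iclamp_trace):
        f = extract_firing_features(default_iclamp_trace)
        assert f.has_firing
        t_peak = default_iclamp_trace.time_ms[
            int(np.argmax(default_iclamp_trace.command))]
        assert (f.spike_times < t_peak).any()
        assert (f.spike_times > t_peak).any()
        assert f.asc_freq.shape[0] > 0 and f.desc_freq.shape[0] > 0

    def test_metadata_regenerates_command(self, default_iclamp_trace):
        ramp = RampProtocol.from_dict(default_iclamp_trace.metadata["protocol"])
        rebuilt = ramp.command(default_iclamp_trace.time_ms)
        assert np.allclose(rebuilt, default_iclamp_trace.command, atol=1e-9)

    def test_ramp_command_is_continuous_triangle(self):
        ramp = RampProtocol("current", 0.0, 70.0, duration_ms=10000.0)
        t = np.linspace(0, 10000.0, 100001)
        c = ramp.command(t)
        assert c[0] == 0.0 and c[-1] == pytest.approx(0.0, abs=1e-9)
        assert c.max() == pytest.approx(70.0, abs=0.01)
        assert np.max(np.abs(np.diff(c))) < 0.02  # no jumps


class TestMembraneBattery:
    def test_resting_potential_matches_model_target(self, membrane_props):
        assert membrane_props.e_m == pytest.approx(-62.0, abs=2.0)

    def test_input_resistance_reciprocity(self, default_model):
        r5 = measure_input_resistance(default_model, step_pa=-5.0)
        r10 = measure_input_resistance(default_model, step_pa=-10.0)
        assert abs(r5 - r10) / r10 < 0.01

    def test_rheobase_consistent_with_ramp_recruitment(self, membrane_props,
                                                       default_iclamp_trace):
        """The slow ramp recruits at a current at or above the step rheobase
        (slow NaP inactivation during the ramp can only delay recruitment)."""
        f = extract_firing_features(default_iclamp_trace)
        assert f.i_onset >= membrane_props.i_th - 1.0
        assert f.i_onset <= membrane_props.i_th + 15.0

    def test_passive_model_has_no_rheobase(self, passive_model):
        with pytest.raises(RuntimeError, match="no spike"):
            find_rheobase(passive_model, ceiling_pa=100.0)

    def test_spike_shape_sanity(self, membrane_props):
        p = membrane_props
        assert p.ap_height > 0 and p.ap_half_width > 0
        assert p.ahp_amplitude > 0 and p.ahp_half_width > 0
        assert p.r_in > 0
        assert p.v_th > p.e_m
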