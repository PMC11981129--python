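"""Trace-analysis tests: leak subtraction, PIC/firing extraction and the
pattern/type classifiers, validated against synthetic ground truth."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from picsim import (ClampTrace, FeatureConfig, PICFeatures, FiringFeatures,
                    leak_subtract, extract_pic_features, classify_pic_pattern,
                    extract_firing_features, classify_firing_type,
                    RampProtocol, SyntheticPICSpec, SyntheticFiringSpec,
                    TroughSpec, gen_pic_trace, gen_firing_trace,
                    make_pattern_spec)
from picsim.features import loop_signed_area

RAMP = RampProtocol("voltage", start=-70.0, peak=0.0, duration_ms=10000.0,
                    settle_ms=0.0)


def linear_trace(g=1.25, b=85.0, dt=1.0):
    n = int(10000 / dt) + 1
    t = np.arange(n) * dt
    v = RAMP.command(t)
    return ClampTrace(time_ms=t, command=v, signal=g * v + b,
                      metadata={"protocol": RAMP.to_dict(), "mode": "voltage_clamp"})


class TestLeakSubtract:
    def test_pure_line_maps_to_zero(self):
        out = leak_subtract(linear_trace())
        assert np.allclose(out.signal, 0.0, atol=1e-9)

    def test_programmed_trough_survives_subtraction(self):
        spec = SyntheticPICSpec(noise_sd_pa=0.0)
        trace, truth = gen_pic_trace(spec)
        out = leak_subtract(trace)
        assert out.signal.min() == pytest.approx(-truth.a_pic, abs=0.5)
        # leak fit recovered the programmed line
        fit = out.metadata["leak_fit"]
        assert fit["g_pa_per_mv"] == pytest.approx(spec.leak_g_pa_per_mv, abs=0.01)

    def test_idempotent(self):
        trace, _ = gen_pic_trace(SyntheticPICSpec(noise_sd_pa=0.0))
        once = leak_subtract(trace)
        twice = leak_subtract(ClampTrace(once.time_ms, once.command, once.signal,
                                         {k: v for k, v in once.metadata.items()
                                          if k != "leak_subtracted"}))
        assert twice.metadata["leak_fit"]["g_pa_per_mv"] == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(once.signal, twice.signal, atol=1e-6)

    def test_short_fit_window_rejected(self):
        tr = linear_trace(dt=200.0)  # far fewer than 100 samples in window
        with pytest.raises(ValueError, match="100"):
            leak_subtract(tr)


class TestPICExtraction:
    def test_zero_trace_has_no_pic(self):
        out = extract_pic_features(leak_subtract(linear_trace()))
        assert not out.has_pic
        assert out.trajectory == "none"
        assert classify_pic_pattern(out).pattern_id is None

    def test_noise_free_recovery_is_exact_to_sampling(self):
        spec = SyntheticPICSpec(
            a_trough=TroughSpec(True, 100.0, 12.0),
            d_trough=TroughSpec(True, 60.0, 12.0),
            v_onset=-45.0, v_offset=-40.0, noise_sd_pa=0.0)
        trace, truth = gen_pic_trace(spec)
        f = extract_pic_features(leak_subtract(trace))
        assert f.v_onset == pytest.approx(-45.0, abs=1.0)
        assert f.v_offset == pytest.approx(-40.0, abs=1.0)
        assert f.a_pic == pytest.approx(100.0, abs=2.0)
        assert f.d_pic == pytest.approx(60.0, abs=2.0)
        assert f.delta_v == pytest.approx(5.0, abs=1.0)
        assert f.trajectory == "counterclockwise"

    def test_noisy_recovery_within_stated_tolerances(self):
        spec = SyntheticPICSpec(
            a_trough=TroughSpec(True, 60.0, 12.0),
            d_trough=TroughSpec(True, 80.0, 12.0),
            v_onset=-45.0, v_offset=-50.0, noise_sd_pa=2.0, seed=7)
        trace, _ = gen_pic_trace(spec)
        f = extract_pic_features(leak_subtract(trace))
        assert f.v_onset == pytest.approx(-45.0, abs=1.0)
        assert f.v_offset == pytest.approx(-50.0, abs=1.0)
        assert f.a_pic == pytest.approx(60.0, abs=5.0)
        assert f.d_pic == pytest.approx(80.0, abs=5.0)

    def test_single_component_trace(self):
        trace, _ = gen_pic_trace(make_pattern_spec(1, seed=3, noise_sd_pa=0.0))
        f = extract_pic_features(leak_subtract(trace))
        assert f.a_pic is not None
        assert f.d_pic is None  # below the detection floor
        assert f.delta_v is not None and f.delta_v > 0

    def test_trajectory_agrees_with_loop_area_sign(self):
        """Amplitude rule vs signed (V, I) loop area on noise-free traces."""
        for pid, seed in [(2, 1), (5, 2), (6, 3)]:
            trace, truth = gen_pic_trace(make_pattern_spec(pid, seed, 0.0))
            sub = leak_subtract(trace)
            f = extract_pic_features(sub)
            area = loop_signed_area(sub)
            if f.trajectory == "counterclockwise":
                assert area > 0
            elif f.trajectory == "clockwise":
                assert area < 0


class TestPatternClassifier:
    @pytest.mark.parametrize("a,d,dv,expected", [
        (60.0, None, 5.0, 1),
        (None, 60.0, -4.0, 4),
        (100.0, 60.0, 5.0, 2),
        (100.0, 60.0, 0.2, 3),
        (40.0, 90.0, -6.0, 5),
        (100.0, 60.0, -3.0, 6),
    ])
    def test_canonical_patterns(self, a, d, dv, expected):
        f = PICFeatures(v_onset=-45.0, v_offset=-45.0 + dv, a_pic=a, d_pic=d,
                        delta_v=dv if (a and d) or True else None,
                        trajectory="none", ratio=None)
        assert classify_pic_pattern(f).pattern_id == expected

    @given(a=st.one_of(st.none(), st.floats(5, 200)),
           d=st.one_of(st.none(), st.floats(5, 200)),
           dv=st.floats(-10, 10))
    def test_exhaustive_over_detected_components(self, a, d, dv):
        if a is None and d is None:
            return
        f = PICFeatures(v_onset=-45.0, v_offset=-45.0 + dv, a_pic=a, d_pic=d,
                        delta_v=dv, trajectory="none", ratio=None)
        pat = classify_pic_pattern(f)
        assert pat.pattern_id in {1, 2, 3, 4, 5, 6}

    def test_category_matches_delta_v_band(self):
        for dv, cat in [(2.0, "dV>0"), (0.3, "dV=0"), (-2.0, "dV<0")]:
            f = PICFeatures(-45.0, -45.0 + dv, 100.0, 60.0, dv, "none", 0.6)
            assert classify_pic_pattern(f).category == cat


class TestFiringFeatures:
    def test_spike_free_trace_is_no_firing(self):
        n = 1001
        t = np.arange(n) * 10.0
        tr = ClampTrace(t, np.zeros(n), np.full(n, -62.0), {})
        f = extract_firing_features(tr)
        assert not f.has_firing
        with pytest.raises(ValueError):
            classify_firing_type(f)

    def test_programmed_recruitment_currents_recovered(self):
        spec = SyntheticFiringSpec(i_onset_pa=25.0, i_offset_pa=35.0, seed=1)
        trace, truth = gen_firing_trace(spec)
        f = extract_firing_features(trace)
        assert f.i_onset == pytest.approx(25.0, abs=0.5)
        assert f.i_offset == pytest.approx(35.0, abs=0.5)
        assert f.delta_i == pytest.approx(10.0, abs=1.0)
        assert classify_firing_type(f).type_id == 1

    def test_frequencies_follow_programmed_gain(self):
        spec = SyntheticFiringSpec(i_onset_pa=20.0, i_offset_pa=20.0,
                                   gain_asc_hz_per_pa=0.5, f0_hz=2.0,
                                   noise_sd_mv=0.0, seed=2)
        trace, _ = gen_firing_trace(spec)
        f = extract_firing_features(trace)
        assert f.asc_freq.shape[0] > 3
        i_cmd, freq = f.asc_freq[:, 0], f.asc_freq[:, 1]
        pred = 2.0 + 0.5 * (i_cmd - 20.0)
        assert np.median(np.abs(freq - pred) / pred) < 0.15

    @pytest.mark.parametrize("di,expected", [(16.0, 1), (0.0, 2), (-70.0, 3),
                                             (0.9, 2), (-0.9, 2)])
    def test_type_rule(self, di, expected):
        f = FiringFeatures(i_onset=20.0, i_offset=20.0 + di, delta_i=di,
                           spike_times=np.array([1.0, 2.0]))
        assert classify_firing_type(f).type_id == expected
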