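"""Synthetic recording-like traces with programmed ground truth.

These generators stand in for patch-clamp recordings: they produce bi-ramp
voltage-clamp current traces (linear leak plus smooth inward troughs plus
Gaussian noise) and bi-ramp current-clamp spike trains with programmed
recruitment/de-recruitment currents.  The trough shape is a raised cosine
with compact support whose edges sit exactly at the programmed onset and
offset voltages, so the ground truth of every extracted feature is known by
construction — testability over realism.

Also here: the cohort bookkeeping that converts per-pattern / per-type
neuron counts into rounded percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .protocols import ClampTrace, RampProtocol
from .features import PICFeatures, FiringFeatures

__all__ = [
    "TroughSpec",
    "SyntheticPICSpec",
    "SyntheticFiringSpec",
    "CohortCounts",
    "gen_pic_trace",
    "gen_firing_trace",
    "cohort_proportions",
    "aggregate_pattern_categories",
    "make_pattern_spec",
]

DEFAULT_SYNTH_RAMP = RampProtocol("voltage", start=-70.0, peak=0.0,
                                  duration_ms=10000.0, settle_ms=0.0)


@dataclass(frozen=True)
class TroughSpec:
    """One limb's inward trough: a raised-cosine dip of given depth (pA)
    whose support spans ``width_mv`` starting at the limb's onset/offset
    voltage."""

    present: bool = True
    amplitude_pa: float = 60.0
    width_mv: float = 12.0

    def __post_init__(self) -> None:
        if self.present and (self.amplitude_pa <= 0 or self.width_mv <= 0):
            raise ValueError("trough amplitude and width must be positive")

    @property
    def center_offset_mv(self) -> float:
        return self.width_mv / 2.0


@dataclass(frozen=True)
class SyntheticPICSpec:
    """Recipe for a synthetic leak-subtractable PIC trace.

    The ascending trough rises from zero exactly at ``v_onset`` (its support
    is [v_onset, v_onset + width] in command voltage on the ascending limb);
    the descending trough's support is [v_offset, v_offset + width] on the
    descending limb, so the current returns to the leak line exactly at
    ``v_offset``.  The seed fully determines the trace.
    """

    ramp: RampProtocol = DEFAULT_SYNTH_RAMP
    leak_g_pa_per_mv: float = 1.25   # ≈ 800 MΩ cell
    leak_b_pa: float = 85.0
    a_trough: TroughSpec = TroughSpec(True, 60.0, 12.0)
    d_trough: TroughSpec = TroughSpec(True, 40.0, 12.0)
    v_onset: float = -45.0
    v_offset: float = -50.0
    noise_sd_pa: float = 2.0
    seed: int = 0
    sample_dt_ms: float = 1.0

    def validate(self) -> None:
        if self.ramp.mode != "voltage":
            raise ValueError("PIC traces require a voltage ramp")
        lo, hi = self.ramp.start, self.ramp.peak
        if self.a_trough.present:
            if not (lo <= self.v_onset and self.v_onset + self.a_trough.width_mv <= hi):
                raise ValueError("ascending trough support exceeds the ramp range")
        if self.d_trough.present:
            if not (lo <= self.v_offset and self.v_offset + self.d_trough.width_mv <= hi):
                raise ValueError("descending trough support exceeds the ramp range")
        if self.noise_sd_pa < 0:
            raise ValueError("noise_sd_pa must be non-negative")


def _raised_cosine(v: np.ndarray, v0: float, width: float, amp: float) -> np.ndarray:
    """Compact-support dip: 0 outside [v0, v0+width], depth ``amp`` at center."""
    x = (v - v0) / width
    inside = (x >= 0.0) & (x <= 1.0)
    out = np.zeros_like(v)
    out[inside] = -amp * 0.5 * (1.0 - np.cos(2.0 * math.pi * x[inside]))
    return out


def gen_pic_trace(spec: SyntheticPICSpec) -> tuple[ClampTrace, PICFeatures]:
    """Generate a synthetic voltage-clamp trace and its ground-truth features."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.ramp.duration_ms / spec.sample_dt_ms)) + 1
    t = np.arange(n) * spec.sample_dt_ms
    v = spec.ramp.command(t)
    i = spec.leak_g_pa_per_mv * v + spec.leak_b_pa

    i_peak = int(np.argmax(v))
    if spec.a_trough.present:
        bump = _raised_cosine(v[: i_peak + 1], spec.v_onset,
                              spec.a_trough.width_mv, spec.a_trough.amplitude_pa)
        i[: i_peak + 1] += bump
    if spec.d_trough.present:
        bump = _raised_cosine(v[i_peak:], spec.v_offset,
                              spec.d_trough.width_mv, spec.d_trough.amplitude_pa)
        i[i_peak:] += bump
    if spec.noise_sd_pa > 0:
        i = i + rng.normal(0.0, spec.noise_sd_pa, size=n)

    a = spec.a_trough.amplitude_pa if spec.a_trough.present else None
    d = spec.d_trough.amplitude_pa if spec.d_trough.present else None
    v_on = spec.v_onset if spec.a_trough.present else None
    v_off = spec.v_offset if spec.d_trough.present else None
    dv = (v_off - v_on) if (v_on is not None and v_off is not None) else None
    a_eff, d_eff = a or 0.0, d or 0.0
    if a is None and d is None:
        traj = "none"
    elif a_eff > d_eff:
        traj = "counterclockwise"
    elif d_eff > a_eff:
        traj = "clockwise"
    else:
        traj = "none"
    truth = PICFeatures(v_onset=v_on, v_offset=v_off, a_pic=a, d_pic=d,
                        delta_v=dv, trajectory=traj,
                        ratio=(d_eff / a if a else None))

    trace = ClampTrace(
        time_ms=t, command=v, signal=i,
        metadata={"protocol": spec.ramp.to_dict(),
                  "units": {"command": "mV", "signal": "pA", "time": "ms"},
                  "mode": "voltage_clamp", "synthetic": True,
                  "seed": spec.seed,
                  "ground_truth": {"v_onset": v_on, "v_offset": v_off,
                                   "a_pic": a, "d_pic": d}},
    )
    return trace, truth


DEFAULT_FIRING_RAMP = RampProtocol("current", start=0.0, peak=70.0,
                                   duration_ms=10000.0, settle_ms=0.0)


@dataclass(frozen=True)
class SyntheticFiringSpec:
    """Recipe for a synthetic bi-ramp spike train.

    Spikes are template waveforms placed so that the command current at the
    first and last spike equals the programmed I_onset and I_offset, with
    instantaneous rates following a linear frequency–current relation per
    limb above a base rate ``f0_hz``.
    """

    ramp: RampProtocol = DEFAULT_FIRING_RAMP
    i_onset_pa: float = 25.0
    i_offset_pa: float = 35.0
    gain_asc_hz_per_pa: float = 0.5
    gain_desc_hz_per_pa: float = 0.5
    f0_hz: float = 2.0
    v_rest_mv: float = -62.0
    r_mv_per_pa: float = 0.2
    spike_height_mv: float = 85.0
    spike_width_ms: float = 1.5
    noise_sd_mv: float = 0.3
    seed: int = 0
    sample_dt_ms: float = 0.2

    def validate(self) -> None:
        if self.ramp.mode != "current":
            raise ValueError("firing traces require a current ramp")
        if not (self.ramp.start <= self.i_onset_pa <= self.ramp.peak):
            raise ValueError("i_onset outside the ramp range")
        if not (self.ramp.start <= self.i_offset_pa <= self.ramp.peak):
            raise ValueError("i_offset outside the ramp range")
        if self.f0_hz <= 0:
            raise ValueError("f0_hz must be positive")


def _ramp_time_at(ramp: RampProtocol, level: float, limb: str) -> float:
    half = ramp.duration_ms / 2.0
    frac = (level - ramp.start) / (ramp.peak - ramp.start)
    return half * frac if limb == "asc" else ramp.duration_ms - half * frac


def gen_firing_trace(spec: SyntheticFiringSpec) -> tuple[ClampTrace, FiringFeatures]:
    """Generate a synthetic current-clamp trace and its ground-truth features."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ramp = spec.ramp
    n = int(round(ramp.duration_ms / spec.sample_dt_ms)) + 1
    t = np.arange(n) * spec.sample_dt_ms
    cmd = ramp.command(t)
    half = ramp.duration_ms / 2.0

    # ascending spikes: start exactly at I_onset, march forward
    spikes = []
    ti = _ramp_time_at(ramp, spec.i_onset_pa, "asc")
    while ti <= half:
        spikes.append(ti)
        i_here = float(np.interp(ti, t, cmd))
        f = spec.f0_hz + spec.gain_asc_hz_per_pa * max(0.0, i_here - spec.i_onset_pa)
        ti += 1000.0 / f
    # descending spikes: end exactly at I_offset, march backward
    desc = []
    ti = _ramp_time_at(ramp, spec.i_offset_pa, "desc")
    while ti > half:
        desc.append(ti)
        i_here = float(np.interp(ti, t, cmd))
        f = spec.f0_hz + spec.gain_desc_hz_per_pa * max(0.0, i_here - spec.i_offset_pa)
        ti -= 1000.0 / f
    spike_times = np.asarray(sorted(spikes + desc))

    v = spec.v_rest_mv + spec.r_mv_per_pa * cmd
    sigma = spec.spike_width_ms / 2.355  # FWHM → gaussian sd
    for ts in spike_times:
        sel = np.abs(t - ts) < 6 * sigma
        v[sel] += spec.spike_height_mv * np.exp(-0.5 * ((t[sel] - ts) / sigma) ** 2)
    if spec.noise_sd_mv > 0:
        v = v + rng.normal(0.0, spec.noise_sd_mv, size=n)

    truth = FiringFeatures(
        i_onset=spec.i_onset_pa, i_offset=spec.i_offset_pa,
        delta_i=spec.i_offset_pa - spec.i_onset_pa, spike_times=spike_times,
    )
    trace = ClampTrace(
        time_ms=t, command=cmd, signal=v,
        metadata={"protocol": ramp.to_dict(),
                  "units": {"command": "pA", "signal": "mV", "time": "ms"},
                  "mode": "current_clamp", "synthetic": True,
                  "seed": spec.seed,
                  "ground_truth": {"i_onset": spec.i_onset_pa,
                                   "i_offset": spec.i_offset_pa}},
    )
    return trace, truth


# ---------------------------------------------------------------------------
# Cohort statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortCounts:
    """Observed cohort: neurons per PIC pattern and per firing type.

    Defaults are the recorded cohort: patterns (18, 14, 5, 2, 5, 3) of 47
    neurons and firing types (60, 6, 13) of 79.
    """

    pattern_counts: tuple[int, ...] = (18, 14, 5, 2, 5, 3)
    type_counts: tuple[int, ...] = (60, 6, 13)


def cohort_proportions(counts) -> list[int]:
    """Percentages (nearest integer) of each category in ``counts``."""
    counts = list(counts)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total <= 0:
        raise ValueError("total count must be positive")
    return [round(100.0 * c / total) for c in counts]


def aggregate_pattern_categories(pattern_counts) -> tuple[int, int, int]:
    """Collapse the six pattern counts into the three ΔV categories.

    ΔV>0 aggregates patterns 1–2, ΔV=0 is pattern 3, ΔV<0 patterns 4–6.
    """
    c = list(pattern_counts)
    if len(c) != 6:
        raise ValueError("expected six pattern counts")
    return (c[0] + c[1], c[2], c[3] + c[4] + c[5])


# ---------------------------------------------------------------------------
# Pattern-spanning spec factory (used by the recovery property suite)
# ---------------------------------------------------------------------------

def make_pattern_spec(pattern_id: int, seed: int,
                      noise_sd_pa: float = 2.0) -> SyntheticPICSpec:
    """A randomized but consistent spec whose ground truth is one pattern.

    Amplitudes span the tens-of-pA range seen in recordings; the minor
    component of the single-sided patterns (1 and 4) is kept below the 5-pA
    detection floor, which is what defines those patterns.
    """
    rng = np.random.default_rng(seed)
    a_amp = float(rng.uniform(40.0, 120.0))
    width = float(rng.uniform(9.0, 15.0))
    v_on = float(rng.uniform(-50.0, -40.0))

    def spec(a, d, v_on, v_off):
        return SyntheticPICSpec(a_trough=a, d_trough=d, v_onset=v_on,
                                v_offset=v_off, noise_sd_pa=noise_sd_pa,
                                seed=seed)

    small = TroughSpec(True, 3.0, width)  # below the detection floor
    if pattern_id == 1:
        dv = float(rng.uniform(3.0, 8.0))
        return spec(TroughSpec(True, a_amp, width), small, v_on, v_on + dv)
    if pattern_id == 2:
        dv = float(rng.uniform(3.0, 8.0))
        d_amp = float(rng.uniform(10.0, max(11.0, 0.7 * a_amp)))
        return spec(TroughSpec(True, a_amp, width), TroughSpec(True, d_amp, width),
                    v_on, v_on + dv)
    if pattern_id == 3:
        d_amp = float(rng.uniform(10.0, max(11.0, 0.7 * a_amp)))
        return spec(TroughSpec(True, a_amp, width), TroughSpec(True, d_amp, width),
                    v_on, v_on)
    if pattern_id == 4:
        dv = float(rng.uniform(3.0, 8.0))
        return spec(small, TroughSpec(True, a_amp, width), v_on, v_on - dv)
    if pattern_id == 5:
        dv = float(rng.uniform(3.0, 8.0))
        d_amp = float(rng.uniform(1.4 * a_amp / 4, 120.0))
        a_small = float(rng.uniform(10.0, 60.0))
        return spec(TroughSpec(True, a_small, width),
                    TroughSpec(True, max(a_small + 10.0, d_amp), width),
                    v_on, v_on - dv)
    if pattern_id == 6:
        dv = float(rng.uniform(3.0, 8.0))
        d_amp = float(rng.uniform(10.0, max(11.0, 0.7 * a_amp)))
        return spec(TroughSpec(True, a_amp, width), TroughSpec(True, d_amp, width),
                    v_on, v_on - dv)
    raise ValueError(f"pattern_id must be 1..6, got {pattern_id}")
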