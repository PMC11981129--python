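"""Clamp protocols: slow triangular (bi-ramp) commands and the membrane-
property battery.

The voltage-clamp bi-ramp is the standard probe for persistent inward
currents: a 10-s symmetric triangle of the somatic command sweeps the cell
slowly enough that fast channels stay at quasi-steady state while the slow
NaP inactivation gate and the dendritic calcium plateau do not — their lag
is what separates the ascending-limb current from the descending-limb
current.  The current-clamp bi-ramp is the firing-side counterpart: a
triangular injected current recruits and de-recruits repetitive firing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from . import engine
from .engine import DEFAULT_DT, SimState, integrate
from .model import CompartmentalModel, build_model, ModelConfig

__all__ = [
    "RampProtocol",
    "ClampTrace",
    "MembraneProperties",
    "run_voltage_clamp_biramp",
    "run_current_clamp_biramp",
    "characterize_membrane",
    "DEFAULT_VOLTAGE_RAMP",
    "DEFAULT_CURRENT_RAMP",
]


@dataclass(frozen=True)
class RampProtocol:
    """A symmetric triangular command: holding → start, ramp to peak and back.

    ``mode`` is ``"voltage"`` (command in mV) or ``"current"`` (command in
    pA).  Ascending and descending limbs have equal duration; the waveform
    is continuous piecewise-linear.
    """

    mode: str
    start: float
    peak: float
    duration_ms: float = 10000.0
    holding: Optional[float] = None
    settle_ms: float = 1000.0

    def __post_init__(self) -> None:
        if self.mode not in ("voltage", "current"):
            raise ValueError("mode must be 'voltage' or 'current'")
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")

    @property
    def holding_level(self) -> float:
        if self.holding is not None:
            return self.holding
        return self.start if self.mode == "voltage" else 0.0

    def command(self, t_ms: np.ndarray) -> np.ndarray:
        """Command level at times measured from ramp onset (t=0)."""
        t = np.asarray(t_ms, dtype=float)
        half = self.duration_ms / 2.0
        up = self.start + (self.peak - self.start) * t / half
        down = self.peak - (self.peak - self.start) * (t - half) / half
        out = np.where(t <= half, up, down)
        out = np.where(t < 0, self.holding_level, out)
        out = np.where(t > self.duration_ms, self.holding_level, out)
        return out

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "RampProtocol":
        return RampProtocol(**d)


#: Default model voltage ramp.  The experimental family reaches +50 mV, but
#: the model's PICs activate and deactivate below 0 mV, so the default model
#: peak is 0 mV (configurable).
DEFAULT_VOLTAGE_RAMP = RampProtocol("voltage", start=-70.0, peak=0.0)

#: Default current ramp: 70 pA peak, holding 0 pA.
DEFAULT_CURRENT_RAMP = RampProtocol("current", start=0.0, peak=70.0)


@dataclass
class ClampTrace:
    """One recorded clamp sweep: time, command and recorded signal.

    ``signal`` is the clamp current (pA) for voltage clamp and the somatic
    potential (mV) for current clamp.  ``metadata`` carries everything
    needed to regenerate the command waveform and re-run the protocol.
    """

    time_ms: np.ndarray
    command: np.ndarray
    signal: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.time_ms) == len(self.command) == len(self.signal)):
            raise ValueError("time, command and signal must have equal length")

    @property
    def mode(self) -> str:
        return self.metadata.get("protocol", {}).get("mode", "unknown")

    def limb_split(self) -> int:
        """Index of the command peak (end of the ascending limb)."""
        if self.metadata.get("protocol", {}).get("mode") == "voltage":
            return int(np.argmax(self.command))
        return int(np.argmax(self.command))


def _run_ramp(model: CompartmentalModel, ramp: RampProtocol, dt: float,
              record_stride: int, mode: str) -> tuple[SimState, np.ndarray]:
    total = ramp.settle_ms + ramp.duration_ms

    def stim(t):
        return ramp.command(np.asarray(t) - ramp.settle_ms)

    nsteps = int(round(total / dt))
    t_cmd = np.arange(nsteps + 1) * dt
    cmd = stim(t_cmd)
    state = integrate(model, cmd, duration_ms=total, dt_ms=dt, mode=mode,
                      record_stride=record_stride)
    keep = state.time_ms >= ramp.settle_ms
    return state, keep


def run_voltage_clamp_biramp(model: CompartmentalModel,
                             ramp: RampProtocol = DEFAULT_VOLTAGE_RAMP,
                             dt: float = DEFAULT_DT,
                             record_stride: int = 4,
                             tea: bool = False) -> ClampTrace:
    """Somatic voltage-clamp bi-ramp; returns the clamp current trace (pA).

    The clamp is ideal (zero series resistance): the somatic potential
    equals the command exactly while axon and dendrites remain free.  Inward
    current deflections are negative.  ``tea`` zeroes the voltage- and
    calcium-activated potassium conductances, mimicking the K-channel
    blockade of the recording solution.
    """
    if ramp.mode != "voltage":
        raise ValueError("ramp.mode must be 'voltage'")
    if tea:
        model = build_model(model.config.with_overrides(tea=True))
    state, keep = _run_ramp(model, ramp, dt, record_stride, "voltage")
    t = state.time_ms[keep] - ramp.settle_ms
    trace = ClampTrace(
        time_ms=t,
        command=state.command[keep],
        signal=state.i_clamp_pa[keep],
        metadata={
            "protocol": ramp.to_dict(),
            "units": {"command": "mV", "signal": "pA", "time": "ms"},
            "mode": "voltage_clamp",
            "dt_ms": dt, "record_stride": record_stride, "tea": tea,
            "model_overrides": asdict(model.config),
            "aux_v_dendrite_mid": state.v_aux[keep],
            "gate_min": state.gate_min, "gate_max": state.gate_max,
        },
    )
    return trace


def run_current_clamp_biramp(model: CompartmentalModel,
                             ramp: RampProtocol = DEFAULT_CURRENT_RAMP,
                             dt: float = DEFAULT_DT,
                             record_stride: int = 4) -> ClampTrace:
    """Somatic current-clamp bi-ramp; returns the voltage trace (mV)."""
    if ramp.mode != "current":
        raise ValueError("ramp.mode must be 'current'")
    state, keep = _run_ramp(model, ramp, dt, record_stride, "current")
    t = state.time_ms[keep] - ramp.settle_ms
    return ClampTrace(
        time_ms=t,
        command=state.command[keep],
        signal=state.v_soma[keep],
        metadata={
            "protocol": ramp.to_dict(),
            "units": {"command": "pA", "signal": "mV", "time": "ms"},
            "mode": "current_clamp",
            "dt_ms": dt, "record_stride": record_stride,
            "model_overrides": asdict(model.config),
            "gate_min": state.gate_min, "gate_max": state.gate_max,
        },
    )


# ---------------------------------------------------------------------------
# Membrane-property battery
# ---------------------------------------------------------------------------

@dataclass
class MembraneProperties:
    """The eight standard passive/spike observables of the cell."""

    e_m: float            # resting potential, mV
    r_in: float           # input resistance, MΩ
    i_th: float           # rheobase, pA (1-s somatic steps, 1 pA resolution)
    v_th: float           # spike threshold, mV (dV/dt > 10 mV/ms criterion)
    ap_height: float      # mV, peak − threshold
    ap_half_width: float  # ms, width at half height
    ahp_amplitude: float  # mV, threshold − post-spike minimum
    ahp_half_width: float # ms, time below half-recovery level

    def __post_init__(self) -> None:
        if self.ap_height is not None and self.ap_height <= 0:
            raise ValueError("AP height must be positive")


def _spike_in(state: SimState, t0: float, threshold: float = 0.0,
              dvdt_min: float = 10.0) -> bool:
    """True if a genuine spike (fast upward threshold crossing) occurs after t0.

    The dV/dt guard distinguishes spikes from slow passive depolarization
    that merely drifts across the voltage threshold.
    """
    sel = state.time_ms >= t0
    v = state.v_soma[sel]
    if v.size < 3:
        return False
    up = (v[:-1] <= threshold) & (v[1:] > threshold)
    if not np.any(up):
        return False
    dvdt = np.diff(v) / state.dt_ms
    return bool(np.any(dvdt[up] > dvdt_min))


def measure_resting_potential(model: CompartmentalModel, dt: float = DEFAULT_DT,
                              duration_ms: float = 5000.0) -> float:
    """Somatic potential after a free run (no injected current)."""
    state = integrate(model, None, duration_ms=duration_ms, dt_ms=dt,
                      record_stride=40)
    return float(state.v_soma[-1])


def measure_input_resistance(model: CompartmentalModel, step_pa: float = -10.0,
                             dt: float = DEFAULT_DT, settle_ms: float = 3000.0,
                             step_ms: float = 2000.0) -> float:
    """R_in (MΩ) from the steady-state deflection to a small somatic step."""
    if step_pa == 0:
        raise ValueError("step_pa must be nonzero")
    total = settle_ms + step_ms

    nsteps = int(round(total / dt))
    t = np.arange(nsteps + 1) * dt
    cmd = np.where(t >= settle_ms, step_pa, 0.0)
    state = integrate(model, cmd, duration_ms=total, dt_ms=dt, record_stride=40)
    pre = state.v_soma[(state.time_ms > settle_ms - 300) &
                       (state.time_ms <= settle_ms)].mean()
    post = state.v_soma[state.time_ms > total - 300].mean()
    return float((post - pre) / step_pa * 1000.0)  # mV/pA → MΩ


def find_rheobase(model: CompartmentalModel, dt: float = DEFAULT_DT,
                  settle_ms: float = 1000.0, step_ms: float = 1000.0,
                  ceiling_pa: float = 500.0, resolution_pa: float = 1.0) -> float:
    """Rheobase by bisection over 1-s somatic current steps."""

    def spikes_at(i_pa: float) -> bool:
        total = settle_ms + step_ms
        nsteps = int(round(total / dt))
        t = np.arange(nsteps + 1) * dt
        cmd = np.where(t >= settle_ms, i_pa, 0.0)
        state = integrate(model, cmd, duration_ms=total, dt_ms=dt,
                          record_stride=8)
        return _spike_in(state, settle_ms)

    lo, hi = 0.0, 20.0
    while not spikes_at(hi):
        lo, hi = hi, hi * 2.0
        if hi > ceiling_pa:
            raise RuntimeError(f"no spike found up to {ceiling_pa} pA")
    while hi - lo > resolution_pa:
        mid = 0.5 * (lo + hi)
        if spikes_at(mid):
            hi = mid
        else:
            lo = mid
    return float(math.ceil(hi))


def _first_spike_metrics(state: SimState, t0: float,
                         dvdt_crit: float = 10.0) -> dict:
    """Threshold/height/width/AHP of the first spike after t0.

    Threshold is the voltage at which dV/dt first exceeds ``dvdt_crit``
    (mV/ms) on the spike upstroke; AP height = peak − threshold; AHP
    amplitude = threshold − post-spike minimum; half-widths at 50 % of the
    respective amplitudes.
    """
    t = state.time_ms
    v = state.v_soma
    dt = state.dt_ms
    sel = t >= t0
    t = t[sel]; v = v[sel]

    above = v > 0.0
    crossings = np.flatnonzero(~above[:-1] & above[1:])
    if crossings.size == 0:
        raise RuntimeError("no spike in trace")
    peak_region_end = crossings[1] if crossings.size > 1 else v.size
    i_peak = int(np.argmax(v[:peak_region_end]))

    dvdt = np.gradient(v, dt)
    up = np.flatnonzero(dvdt[:i_peak + 1] > dvdt_crit)
    if up.size == 0:
        raise RuntimeError("no dV/dt threshold crossing before peak")
    # first sustained crossing belonging to this spike's upstroke
    i_th = int(up[0])
    v_th = float(v[i_th])
    v_peak = float(v[i_peak])
    height = v_peak - v_th

    half_level = v_th + height / 2.0
    i_up = i_th + int(np.argmax(v[i_th:i_peak + 1] >= half_level))
    after = np.flatnonzero(v[i_peak:] < half_level)
    if after.size == 0:
        raise RuntimeError("spike does not repolarize")
    i_down = i_peak + int(after[0])
    ap_half_width = float(t[i_down] - t[i_up])

    # AHP window: from peak to the next spike upstroke (or trace end)
    if crossings.size > 1:
        i_next = int(crossings[1])
    else:
        i_next = v.size - 1
    win = v[i_peak:i_next]
    i_min = i_peak + int(np.argmin(win))
    v_min = float(v[i_min])
    ahp_amp = v_th - v_min
    ahp_level = v_min + ahp_amp / 2.0
    below = v[i_peak:i_next] < ahp_level
    first_below = np.flatnonzero(below)
    if first_below.size == 0:
        ahp_half_width = 0.0
    else:
        start = first_below[0]
        rest = np.flatnonzero(~below[start:])
        end = start + (int(rest[0]) if rest.size else below.size - start)
        ahp_half_width = float((end - start) * dt)

    return {"v_th": v_th, "ap_height": height, "ap_half_width": ap_half_width,
            "ahp_amplitude": ahp_amp, "ahp_half_width": ahp_half_width,
            "v_peak": v_peak, "t_spike": float(t[i_peak])}


def characterize_membrane(model: CompartmentalModel,
                          dt: float = DEFAULT_DT) -> MembraneProperties:
    """Run the full membrane-property battery on a model.

    E_m from a 5-s free run; R_in from a −10 pA step; rheobase by bisection
    of 1-s steps; spike and AHP shape measured on the first spike of a long
    step at rheobase.

    Raises ``RuntimeError`` if the cell cannot be made to spike (e.g. a
    passive model), in which case only E_m/R_in are meaningful — callers
    that need those alone should use the ``measure_*`` functions.
    """
    e_m = measure_resting_potential(model, dt)
    r_in = measure_input_resistance(model, dt=dt)
    i_th = find_rheobase(model, dt)

    settle = 1000.0
    total = settle + 3000.0
    nsteps = int(round(total / dt))
    t = np.arange(nsteps + 1) * dt
    cmd = np.where(t >= settle, i_th, 0.0)
    state = integrate(model, cmd, duration_ms=total, dt_ms=dt, record_stride=1)
    m = _first_spike_metrics(state, settle)

    return MembraneProperties(
        e_m=e_m, r_in=r_in, i_th=i_th, v_th=m["v_th"],
        ap_height=m["ap_height"], ap_half_width=m["ap_half_width"],
        ahp_amplitude=m["ahp_amplitude"], ahp_half_width=m["ahp_half_width"],
    )
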