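"""Multicompartment serotonergic (5-HT) neuron model.

The cell is an unbranched cable chain of four sections — axon, initial
segment (IS), soma, dendrite — carrying six active conductances:

* ``NaT``  transient sodium (spike upstroke), m^3·h kinetics
* ``NaP``  persistent sodium with a slowly inactivating gate ``s`` whose
  floor ``s_gate`` controls how much of the current survives prolonged
  depolarization; NaP is one of the two carriers of the persistent
  inward current (PIC)
* ``Kdr``  delayed-rectifier potassium, n^4
* ``KCa``  calcium-activated potassium driven by a first-order calcium
  pool; the somatic pool shapes the afterhyperpolarization (AHP), the
  dendritic pool opposes the dendritic calcium plateau
* ``CaL``  L-type calcium, the second PIC carrier, confined to a
  mid-dendritic zone
* ``leak`` ohmic leak set by the specific membrane resistance R_M

plus ``CaHVA``, a small spike-activated somatic calcium source that
feeds the AHP calcium pool (the tabulated channel set places no calcium
channel at the soma, yet the somatic KCa pool needs an influx to
produce the cell's slow AHP; see docs/methods.md).

Units: mV, ms, µm, µA (absolute currents), mS (absolute conductances),
µF (absolute capacitances), mS/cm² (densities), Ω·cm² (R_M), Ω·cm (R_A).
Calcium is in dimensionless model units with resting level ``CA_INF``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SectionGeometry",
    "ChannelKinetics",
    "ConductancePlacement",
    "CompartmentalModel",
    "ModelConfig",
    "build_default_model",
    "build_model",
    "extend_dendrite",
    "gating_steady_state",
    "gating_time_constant",
    "nap_s_inf",
    "channel_current",
    "step_ca",
    "CHANNEL_IDS",
]

# ---------------------------------------------------------------------------
# Fixed biophysical constants
# ---------------------------------------------------------------------------

E_NA = 50.0      # mV, sodium reversal
E_K = -77.0      # mV, potassium reversal
E_CA = 80.0      # mV, ohmic approximation of the calcium driving force
Q_T = 2.46       # temperature factor (37 °C); divides NaT time constants

#: Leak reversal, mV.  Not a measurable parameter: calibrated once so that
#: the free-running somatic potential of the default model is -62 mV.
E_LEAK = -62.35

CA_INF = 0.1     # resting calcium, model units

#: Global calcium-influx gain (model units · cm² / (µA·ms·µm)).  Calcium is
#: carried in arbitrary model units, so only the product of this scale with
#: the KCa activation coefficient is meaningful; it is calibrated once
#: against the somatic AHP (amplitude and half-width) and then frozen.
CA_GAIN_SCALE = 0.135

#: Shell depths (µm) of the two calcium pools: a deep distal-dendrite pool
#: (slow, weakly coupled) and a thin sub-membrane somatic pool for the AHP.
CA_DEPTH_DENDRITE = 100.0
CA_DEPTH_SOMA = 0.6
TAU_CA_DENDRITE = 120.0  # ms
TAU_CA_SOMA = 76.0       # ms

#: Spike-activated somatic calcium source feeding the AHP pool (m², fast).
G_CAHVA_SOMA = 0.52      # mS/cm², calibrated against the AHP observables
CAHVA_VHALF = 10.0
CAHVA_VS = 4.0
CAHVA_TAU = 0.5          # ms

#: Floor diameter for the closed dendritic taper tip (µm): keeps the final
#: compartment's membrane area and axial resistance finite.
TIP_DIAMETER_FLOOR = 0.1

#: Tabulated potassium-leak densities (mS/cm²).  These double-book part of
#: the sectional R_M (1/R_M − Kleak ≈ 0.02 mS/cm² uniformly), and the cell's
#: printed passive observables (input resistance, rheobase) are consistent
#: only with the uniform ~0.02 mS/cm² component: the implemented leak
#: density is therefore 1/R_M − Kleak per section.  See docs/methods.md.
KLEAK_DENSITY = {"axon": 0.001, "initial_segment": 0.001,
                 "soma": 0.04, "dendrite": 0.01}

CHANNEL_IDS = ("NaT", "NaP", "Kdr", "KCa", "CaL", "CaHVA", "leak")


# ---------------------------------------------------------------------------
# Gating kinetics (reference implementations; the integrator in engine.py
# repeats these in numba-compiled form)
# ---------------------------------------------------------------------------

def _trap(v: float, th: float, a: float, q: float) -> float:
    """Linoid rate a·(v-th)/(1-exp(-(v-th)/q)) with its removable singularity."""
    x = v - th
    if abs(x) < 1e-6:
        return a * q
    return a * x / (1.0 - math.exp(-x / q))


def nat_rates(v: float) -> tuple[float, float, float, float]:
    """(alpha_m, beta_m, alpha_h, beta_h) for the transient sodium channel."""
    am = _trap(v, -20.0, 0.4, 7.2)
    bm = _trap(-v, 20.0, 0.124, 7.2)
    ah = _trap(v, -25.0, 0.06, 1.3)
    bh = _trap(-v, 25.0, 0.01, 1.3)
    return am, bm, ah, bh


def nat_h_inf(v: float) -> float:
    return 1.0 / (1.0 + math.exp((v + 40.5) / 4.8))


def nap_m_inf(v: float, v_s: float = 5.0, v_half: float = -37.3) -> float:
    return 1.0 / (1.0 + math.exp(-(v - v_half) / v_s))


def nap_s_rates(v: float) -> tuple[float, float]:
    """Slow-inactivation opening/closing rates (1/ms) of the persistent Na gate.

    alpha_s is largest at hyperpolarized potentials (recovery); beta_s
    saturates at depolarized potentials (inactivation).  Both are of order
    1e-3/ms, giving the seconds-scale time constant that makes the a-PIC /
    d-PIC asymmetry possible on a 10-s ramp.
    """
    a_s = 0.001 * math.exp(-(v + 85.0) / 30.0)
    b_s = 0.0034 / (1.0 + math.exp(-(v + 17.0) / 10.0))
    return a_s, b_s


def nap_s_inf(v: float, s_gate: float) -> float:
    """Steady state of the NaP slow gate: s_gate + (1-s_gate)·α/(α+β).

    ``s_gate`` is the floor of the gate — the fraction of persistent sodium
    conductance that never inactivates.  At s_gate = 1 the gate is pinned
    open and the PIC loses its hysteresis.
    """
    if not 0.0 <= s_gate <= 1.0:
        raise ValueError(f"s_gate must lie in [0, 1], got {s_gate}")
    a_s, b_s = nap_s_rates(v)
    return s_gate + (1.0 - s_gate) * a_s / (a_s + b_s)


def kdr_n_inf(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-(v + 25.0) / 20.0))


def kdr_tau_n(v: float) -> float:
    e = math.exp((v + 39.0) / 5.5)
    return 0.8 + 20.0 * e / (1.0 + e) ** 2


def kca_rates(ca: float, ca_inf: float = CA_INF) -> tuple[float, float]:
    a_n = 0.1 * (ca - ca_inf) ** 2
    return a_n, 0.1


def cal_m_inf(v: float, v_half: float = -41.0, v_s: float = 4.0) -> float:
    return 1.0 / (1.0 + math.exp(-(v - v_half) / v_s))


def cahva_m_inf(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-(v - CAHVA_VHALF) / CAHVA_VS))


@dataclass(frozen=True)
class ChannelKinetics:
    """Adjustable kinetic parameters of the two PIC channels.

    Only the knobs the parameter studies turn are exposed; all other rate
    constants are fixed by the channel definitions above.
    """

    nap_v_half: float = -37.3  # mV, NaP activation midpoint
    nap_v_s: float = 5.0       # mV, NaP activation slope
    nap_s_gate: float = 0.4    # floor of the NaP slow-inactivation gate
    nap_tau_m: float = 1.0     # ms
    cal_v_half: float = -41.0  # mV, CaL activation midpoint
    cal_v_s: float = 4.0       # mV, CaL activation slope
    cal_tau_m: float = 1.0     # ms

    def __post_init__(self) -> None:
        if not 0.0 <= self.nap_s_gate <= 1.0:
            raise ValueError("nap_s_gate must lie in [0, 1]")
        if self.nap_v_s <= 0 or self.cal_v_s <= 0:
            raise ValueError("activation slopes must be positive")


def gating_steady_state(channel_id: str, gate_id: str, v: float,
                        kinetics: ChannelKinetics | None = None,
                        ca: float = CA_INF) -> float:
    """Steady-state open probability of one gate at membrane potential ``v``.

    For sigmoid-defined gates this returns the printed closed form; for
    rate-defined gates it returns alpha/(alpha+beta).
    """
    k = kinetics or ChannelKinetics()
    if not math.isfinite(v):
        raise ValueError("v must be finite")
    key = (channel_id, gate_id)
    if key == ("NaT", "m"):
        am, bm, _, _ = nat_rates(v)
        return am / (am + bm)
    if key == ("NaT", "h"):
        return nat_h_inf(v)
    if key == ("NaP", "m"):
        return nap_m_inf(v, k.nap_v_s, k.nap_v_half)
    if key == ("NaP", "s"):
        return nap_s_inf(v, k.nap_s_gate)
    if key == ("Kdr", "n"):
        return kdr_n_inf(v)
    if key == ("KCa", "n"):
        a_n, b_n = kca_rates(ca)
        return a_n / (a_n + b_n)
    if key == ("CaL", "m"):
        return cal_m_inf(v, k.cal_v_half, k.cal_v_s)
    if key == ("CaHVA", "m"):
        return cahva_m_inf(v)
    raise KeyError(f"unknown channel/gate: {channel_id}/{gate_id}")


def gating_time_constant(channel_id: str, gate_id: str, v: float,
                         kinetics: ChannelKinetics | None = None,
                         ca: float = CA_INF) -> float:
    """Time constant (ms) of one gate; NaT values carry the Q(T) speed-up."""
    k = kinetics or ChannelKinetics()
    key = (channel_id, gate_id)
    if key == ("NaT", "m"):
        am, bm, _, _ = nat_rates(v)
        return 1.0 / (am + bm) / Q_T
    if key == ("NaT", "h"):
        _, _, ah, bh = nat_rates(v)
        return 1.0 / (ah + bh) / Q_T
    if key == ("NaP", "m"):
        return k.nap_tau_m
    if key == ("NaP", "s"):
        a_s, b_s = nap_s_rates(v)
        return 1.0 / (a_s + b_s)
    if key == ("Kdr", "n"):
        return kdr_tau_n(v)
    if key == ("KCa", "n"):
        a_n, b_n = kca_rates(ca)
        return 1.0 / (a_n + b_n)
    if key == ("CaL", "m"):
        return k.cal_tau_m
    if key == ("CaHVA", "m"):
        return CAHVA_TAU
    raise KeyError(f"unknown channel/gate: {channel_id}/{gate_id}")


def channel_current(channel_id: str, v: float, gates: dict[str, float],
                    ca: float = CA_INF, g_max: float = 1.0) -> float:
    """Ohmic channel current density (µA/cm² for g_max in mS/cm²).

    Inward current is negative, matching the sign convention of recorded
    clamp traces.
    """
    if channel_id == "NaT":
        return g_max * gates["m"] ** 3 * gates["h"] * (v - E_NA)
    if channel_id == "NaP":
        return g_max * gates["m"] * gates["s"] * (v - E_NA)
    if channel_id == "Kdr":
        return g_max * gates["n"] ** 4 * (v - E_K)
    if channel_id == "KCa":
        return g_max * gates["n"] * (v - E_K)
    if channel_id == "CaL":
        return g_max * gates["m"] * (v - E_CA)
    if channel_id == "CaHVA":
        return g_max * gates["m"] ** 2 * (v - E_CA)
    if channel_id == "leak":
        return g_max * (v - E_LEAK)
    raise KeyError(f"unknown channel: {channel_id}")


def step_ca(ca: float, i_ca: float, dt: float, tau_ca: float,
            depth_um: float, ca_inf: float = CA_INF,
            gain_scale: float = CA_GAIN_SCALE) -> float:
    """One exact exponential step of the first-order calcium pool.

    dCa/dt = (Ca∞ - Ca)/τ - gain·i_Ca with gain = gain_scale/depth, so an
    inward (negative) calcium current density raises Ca.  The update uses
    the closed-form solution for constant i_Ca over the step, hence it is
    unconditionally stable.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    gain = gain_scale / depth_um
    target = ca_inf - gain * i_ca * tau_ca
    new = target + (ca - target) * math.exp(-dt / tau_ca)
    return max(new, 0.0)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SectionGeometry:
    """One cable section: compartment count, taper and passive constants."""

    name: str
    n_compartments: int
    length_um: float
    diameter_profile_um: tuple[float, ...]  # per-compartment center diameters
    r_m: float   # Ω·cm², total specific membrane resistance
    r_a: float   # Ω·cm, axial resistivity
    c_m: float   # µF/cm²

    def __post_init__(self) -> None:
        if self.n_compartments < 1:
            raise ValueError("n_compartments must be >= 1")
        if len(self.diameter_profile_um) != self.n_compartments:
            raise ValueError("diameter profile length mismatch")
        if any(d < 0 for d in self.diameter_profile_um):
            raise ValueError("diameters must be non-negative")

    @property
    def compartment_length_um(self) -> float:
        return self.length_um / self.n_compartments

    def effective_diameters(self) -> np.ndarray:
        """Diameters with the closed-tip floor applied."""
        return np.maximum(np.asarray(self.diameter_profile_um, float),
                          TIP_DIAMETER_FLOOR)

    def areas_cm2(self) -> np.ndarray:
        """Membrane areas π·d·L per compartment, cm²."""
        d_cm = self.effective_diameters() * 1e-4
        l_cm = self.compartment_length_um * 1e-4
        return math.pi * d_cm * l_cm


def _dendrite_diameters(n: int, rise_frac: float = 0.2,
                        d_start: float = 1.4, d_peak: float = 5.4) -> tuple[float, ...]:
    """Taper rising d_start→d_peak over the proximal fraction, then falling
    linearly to a closed (zero-diameter) tip, sampled at compartment centers."""
    out = []
    for i in range(n):
        x = (i + 0.5) / n  # normalized distance from soma
        if x <= rise_frac:
            d = d_start + (d_peak - d_start) * x / rise_frac
        else:
            d = d_peak * (1.0 - (x - rise_frac) / (1.0 - rise_frac))
        out.append(d)
    return tuple(out)


def default_sections(dendrite_length_pct: float = 100.0) -> list[SectionGeometry]:
    """The default four-section geometry, optionally with a rescaled dendrite.

    When the dendrite is extended the compartment count scales with length
    (keeping per-compartment electrotonic length comparable) and the taper
    is preserved in relative coordinates.
    """
    if dendrite_length_pct <= 0:
        raise ValueError("dendrite_length_pct must be positive")
    n_dend = max(1, int(round(25 * dendrite_length_pct / 100.0)))
    length_dend = 600.0 * dendrite_length_pct / 100.0
    is_d = tuple(1.8 + (8.2 - 1.8) * (i + 0.5) / 7 for i in range(7))  # axon→soma
    return [
        SectionGeometry("axon", 9, 20.0, (1.8,) * 9, 50000.0, 70.0, 1.0),
        SectionGeometry("initial_segment", 7, 10.0, is_d, 50000.0, 70.0, 1.0),
        SectionGeometry("soma", 1, 20.0, (12.0,), 16666.0, 70.0, 1.0),
        SectionGeometry("dendrite", n_dend, length_dend,
                        _dendrite_diameters(n_dend), 34483.0, 70.0, 1.0),
    ]


@dataclass(frozen=True)
class ConductancePlacement:
    """A channel density over a normalized path interval of one section."""

    channel_id: str
    section: str
    zone: tuple[float, float]  # normalized [a, b) along the section
    density: float             # mS/cm²

    def __post_init__(self) -> None:
        a, b = self.zone
        if not (0.0 <= a < b <= 1.0):
            raise ValueError(f"invalid zone {self.zone}")
        if self.channel_id not in CHANNEL_IDS:
            raise KeyError(f"unknown channel {self.channel_id}")


def default_placements() -> list[ConductancePlacement]:
    """Active-conductance distribution of the default model.

    The leak is not listed here: it is carried per-section as the uniform
    passive component 1/R_M − Kleak (see ``KLEAK_DENSITY``).
    """
    P = ConductancePlacement
    out = []
    for sec in ("axon", "initial_segment"):
        out += [P("NaT", sec, (0, 1), 139.0),
                P("NaP", sec, (0, 1), 0.158),
                P("Kdr", sec, (0, 1), 40.0)]
    out += [P("NaT", "soma", (0, 1), 30.0),
            P("NaP", "soma", (0, 1), 0.1),
            P("Kdr", "soma", (0, 1), 10.0),
            P("KCa", "soma", (0, 1), 0.18),
            P("CaHVA", "soma", (0, 1), G_CAHVA_SOMA)]
    out += [P("NaT", "dendrite", (0.0, 0.04), 4.4),
            P("NaT", "dendrite", (0.04, 1.0), 0.0075),
            P("NaP", "dendrite", (0.0, 0.04), 0.0044),
            P("NaP", "dendrite", (0.04, 1.0), 0.00015),
            P("Kdr", "dendrite", (0.0, 0.04), 1.0),
            P("Kdr", "dendrite", (0.04, 1.0), 0.00033),
            P("KCa", "dendrite", (0.32, 0.56), 0.04),
            P("CaL", "dendrite", (0.32, 0.56), 0.03)]
    return out


# ---------------------------------------------------------------------------
# Model configuration and assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Every default of the model that the parameter studies override.

    Conductance scales are percentages of the default densities (100 = as
    tabulated); a scale of 0 blocks the channel, which is how the studies
    isolate NaP from CaL.  ``CaHVA`` (the somatic AHP calcium source) is
    deliberately not scaled with ``g_cal_pct``: it is a calibration element
    of the AHP, not part of the dendritic L-type distribution under study.
    """

    g_nat_pct: float = 100.0
    g_nap_pct: float = 100.0
    g_kdr_pct: float = 100.0
    g_kca_pct: float = 100.0
    g_cal_pct: float = 100.0
    g_cahva_pct: float = 100.0
    nap_v_s: float = 5.0
    nap_s_gate: float = 0.4
    nap_v_half: float = -37.3
    cal_v_half: float = -41.0
    cal_v_s: float = 4.0
    dendrite_length_pct: float = 100.0
    e_leak: float = E_LEAK
    e_ca: float = E_CA
    tea: bool = False  # zero the K conductances (recording-solution analog)

    def kinetics(self) -> ChannelKinetics:
        return ChannelKinetics(nap_v_half=self.nap_v_half, nap_v_s=self.nap_v_s,
                               nap_s_gate=self.nap_s_gate,
                               cal_v_half=self.cal_v_half, cal_v_s=self.cal_v_s)

    def with_overrides(self, **kw) -> "ModelConfig":
        import dataclasses
        unknown = set(kw) - {f.name for f in dataclasses.fields(ModelConfig)}
        if unknown:
            raise KeyError(f"unknown ModelConfig keys: {sorted(unknown)}")
        return replace(self, **kw)


@dataclass
class CompartmentalModel:
    """Assembled cable model: geometry-derived arrays plus channel densities.

    Compartments are ordered axon tip → initial segment → soma → dendrite
    tip; coupling is a symmetric tridiagonal chain.
    """

    sections: list[SectionGeometry]
    placements: list[ConductancePlacement]
    config: ModelConfig
    # derived arrays (per compartment)
    area_cm2: np.ndarray = field(repr=False, default=None)
    cm_uf: np.ndarray = field(repr=False, default=None)
    g_leak_ms: np.ndarray = field(repr=False, default=None)
    g_axial_ms: np.ndarray = field(repr=False, default=None)  # len ncomp-1
    g_chan_ms: dict = field(repr=False, default=None)  # channel → array (mS)
    tau_ca: np.ndarray = field(repr=False, default=None)
    ca_gain: np.ndarray = field(repr=False, default=None)
    section_slices: dict = field(default=None)
    metadata: dict = field(default_factory=dict)

    @property
    def n_compartments(self) -> int:
        return int(self.area_cm2.size)

    @property
    def soma_index(self) -> int:
        return self.section_slices["soma"].start

    @property
    def dendrite_mid_index(self) -> int:
        s = self.section_slices["dendrite"]
        return s.start + (s.stop - s.start) // 2

    def total_conductance(self, channel_id: str) -> float:
        """Summed absolute conductance (mS) of one channel over the cell."""
        return float(self.g_chan_ms[channel_id].sum())

    def passive_copy(self) -> "CompartmentalModel":
        """A copy with every active conductance zeroed (leak only)."""
        import copy
        m = copy.deepcopy(self)
        for k in m.g_chan_ms:
            m.g_chan_ms[k] = np.zeros_like(m.g_chan_ms[k])
        return m


def _scale_for(channel_id: str, cfg: ModelConfig) -> float:
    pct = {"NaT": cfg.g_nat_pct, "NaP": cfg.g_nap_pct, "Kdr": cfg.g_kdr_pct,
           "KCa": cfg.g_kca_pct, "CaL": cfg.g_cal_pct,
           "CaHVA": cfg.g_cahva_pct}[channel_id]
    if cfg.tea and channel_id in ("Kdr", "KCa"):
        return 0.0
    return pct / 100.0


def build_model(config: ModelConfig | None = None) -> CompartmentalModel:
    """Assemble the compartmental model from a configuration."""
    cfg = config or ModelConfig()
    sections = default_sections(cfg.dendrite_length_pct)
    placements = default_placements()

    areas, cms, gleaks, taus, gains = [], [], [], [], []
    slices: dict[str, slice] = {}
    diam_all: list[float] = []
    start = 0
    for sec in sections:
        a = sec.areas_cm2()
        areas.append(a)
        cms.append(sec.c_m * a)
        leak_dens = 1000.0 / sec.r_m - KLEAK_DENSITY[sec.name]  # mS/cm²
        gleaks.append(a * leak_dens)
        slices[sec.name] = slice(start, start + sec.n_compartments)
        start += sec.n_compartments
        diam_all.extend(sec.effective_diameters())
        if sec.name == "soma":
            taus.append(np.full(sec.n_compartments, TAU_CA_SOMA))
            gains.append(np.full(sec.n_compartments,
                                 CA_GAIN_SCALE / CA_DEPTH_SOMA))
        else:
            taus.append(np.full(sec.n_compartments, TAU_CA_DENDRITE))
            gains.append(np.full(sec.n_compartments,
                                 CA_GAIN_SCALE / CA_DEPTH_DENDRITE))

    area = np.concatenate(areas)
    ncomp = area.size

    # axial half-resistances (Ω) per compartment, then series-coupled
    half_r = np.empty(ncomp)
    for sec in sections:
        sl = slices[sec.name]
        d_cm = sec.effective_diameters() * 1e-4
        l_cm = sec.compartment_length_um * 1e-4
        half_r[sl] = sec.r_a * (l_cm / 2.0) / (math.pi * (d_cm / 2.0) ** 2)
    g_ax = 1000.0 / (half_r[:-1] + half_r[1:])  # mS between neighbors

    g_chan = {c: np.zeros(ncomp) for c in CHANNEL_IDS if c != "leak"}
    kin = cfg.kinetics()  # validates kinetic overrides
    for p in placements:
        sec = next(s for s in sections if s.name == p.section)
        sl = slices[p.section]
        n = sec.n_compartments
        centers = (np.arange(n) + 0.5) / n
        in_zone = (centers > p.zone[0]) & (centers < p.zone[1])
        dens = p.density * _scale_for(p.channel_id, cfg)
        g_chan[p.channel_id][sl][in_zone] += dens * area[sl][in_zone]  # mS

    model = CompartmentalModel(
        sections=sections, placements=placements, config=cfg,
        area_cm2=area, cm_uf=np.concatenate(cms),
        g_leak_ms=np.concatenate(gleaks), g_axial_ms=g_ax,
        g_chan_ms=g_chan, tau_ca=np.concatenate(taus),
        ca_gain=np.concatenate(gains), section_slices=slices,
        metadata={"e_leak": cfg.e_leak, "e_na": E_NA, "e_k": E_K,
                  "e_ca": cfg.e_ca, "q_t": Q_T, "ca_inf": CA_INF,
                  "kinetics": kin, "dendrite_length_pct": cfg.dendrite_length_pct},
    )
    return model


def build_default_model() -> CompartmentalModel:
    """The default cell, parameter-for-parameter from the tabulated values."""
    return build_model(ModelConfig())


def extend_dendrite(model: CompartmentalModel, length_percent: float) -> CompartmentalModel:
    """Rebuild the model with the dendrite scaled to ``length_percent`` of 600 µm.

    The CaL/KCa zone stays at the same relative interval and density, so the
    summed L-type conductance grows in proportion to dendritic length.
    """
    if length_percent <= 0:
        raise ValueError("length_percent must be positive")
    if length_percent < 10:
        raise ValueError("length_percent below 10% is outside the supported range")
    return build_model(model.config.with_overrides(dendrite_length_pct=float(length_percent)))
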