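"""Parameter studies: 1-D sweeps, 2-D/3-D grids and threshold queries.

Each grid point rebuilds the cell with the requested overrides, runs the
bi-ramp voltage clamp and/or current clamp, extracts PIC and firing
features and classifies them.  Following the experimental design, a sweep
of one PIC channel is normally run with the other channel blocked
(conductance set to zero) so the two contributions can be separated.

Sweepable parameters (``SweepSpec.parameters`` keys):

================  =======================================================
``g_nap_pct``     NaP maximal-conductance scale, % of default
``g_cal_pct``     CaL maximal-conductance scale, % of default
``nap_v_s``       NaP activation slope, mV
``nap_s_gate``    NaP slow-inactivation floor, 0–1
``cal_v_s``       CaL activation slope, mV
``cal_v_half``    CaL activation midpoint, mV
``dendrite_pct``  dendritic length, % of 600 µm (CaL zone scales with it)
================  =======================================================
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import ModelConfig, build_model
from .protocols import (RampProtocol, DEFAULT_VOLTAGE_RAMP, DEFAULT_CURRENT_RAMP,
                        run_voltage_clamp_biramp, run_current_clamp_biramp)
from .features import (FeatureConfig, DEFAULT_CONFIG, leak_subtract,
                       extract_pic_features, classify_pic_pattern,
                       extract_firing_features, classify_firing_type)

__all__ = ["SweepSpec", "SweepResult", "run_sweep", "run_grid2", "run_grid3",
           "find_threshold_crossing", "CrossingResult", "PARAM_KEYS"]

PARAM_KEYS = {
    "g_nap_pct": "g_nap_pct",
    "g_cal_pct": "g_cal_pct",
    "nap_v_s": "nap_v_s",
    "nap_s_gate": "nap_s_gate",
    "cal_v_s": "cal_v_s",
    "cal_v_half": "cal_v_half",
    "dendrite_pct": "dendrite_length_pct",
}

BLOCK_FIELDS = {"NaP": "g_nap_pct", "CaL": "g_cal_pct", "NaT": "g_nat_pct",
                "Kdr": "g_kdr_pct", "KCa": "g_kca_pct"}

METRIC_COLUMNS = ("v_onset", "v_offset", "a_pic", "d_pic", "delta_v", "ratio",
                  "pattern", "i_onset", "i_offset", "delta_i", "firing_type",
                  "n_spikes")


@dataclass(frozen=True)
class SweepSpec:
    """One parameter study: grids, blocked channels, protocols to run."""

    parameters: dict  # ordered {param key: sequence of values}
    blocked: tuple = ()
    protocols: tuple = ("vclamp", "iclamp")
    base_config: ModelConfig = field(default_factory=ModelConfig)
    voltage_ramp: RampProtocol = DEFAULT_VOLTAGE_RAMP
    current_ramp: RampProtocol = DEFAULT_CURRENT_RAMP
    feature_config: FeatureConfig = DEFAULT_CONFIG
    dt_ms: float = 0.025

    def __post_init__(self) -> None:
        for key in self.parameters:
            if key not in PARAM_KEYS:
                raise KeyError(f"unknown sweep parameter {key!r}; "
                               f"known: {sorted(PARAM_KEYS)}")
        for ch in self.blocked:
            if ch not in BLOCK_FIELDS:
                raise KeyError(f"cannot block unknown channel {ch!r}")
        bad = set(self.protocols) - {"vclamp", "iclamp"}
        if bad:
            raise ValueError(f"unknown protocols: {sorted(bad)}")

    def config_at(self, point: dict) -> ModelConfig:
        over = {PARAM_KEYS[k]: float(v) for k, v in point.items()}
        for ch in self.blocked:
            over[BLOCK_FIELDS[ch]] = 0.0
        return self.base_config.with_overrides(**over)


@dataclass
class SweepResult:
    """Feature table over a grid, plus per-point failure records."""

    spec: SweepSpec
    rows: list = field(default_factory=list)      # dicts: params + metrics
    failures: list = field(default_factory=list)  # dicts: params + error

    @property
    def param_names(self) -> list:
        return list(self.spec.parameters.keys())

    def table(self) -> pd.DataFrame:
        """Wide table: one row per grid point, one column per metric."""
        return pd.DataFrame(self.rows)

    def long_table(self) -> pd.DataFrame:
        """Tidy long format: one row per (grid point, metric)."""
        wide = self.table()
        return wide.melt(id_vars=self.param_names, var_name="metric",
                         value_name="value")

    def series(self, metric: str, along: Optional[str] = None) -> pd.Series:
        along = along or self.param_names[0]
        df = self.table()
        return df.set_index(along)[metric]


def _evaluate_point(spec: SweepSpec, point: dict) -> dict:
    cfg = spec.config_at(point)
    model = build_model(cfg)
    row = dict(point)
    if "vclamp" in spec.protocols:
        trace = run_voltage_clamp_biramp(model, spec.voltage_ramp, dt=spec.dt_ms)
        sub = leak_subtract(trace, spec.feature_config)
        pf = extract_pic_features(sub, spec.feature_config)
        pat = classify_pic_pattern(pf, spec.feature_config.tau_dv_mv,
                                   spec.feature_config.tau_amp_pa)
        row.update(v_onset=pf.v_onset, v_offset=pf.v_offset, a_pic=pf.a_pic,
                   d_pic=pf.d_pic, delta_v=pf.delta_v, ratio=pf.ratio,
                   trajectory=pf.trajectory, pattern=pat.pattern_id)
    if "iclamp" in spec.protocols:
        trace = run_current_clamp_biramp(model, spec.current_ramp, dt=spec.dt_ms)
        ff = extract_firing_features(trace, spec.feature_config)
        row.update(i_onset=ff.i_onset, i_offset=ff.i_offset, delta_i=ff.delta_i,
                   n_spikes=int(ff.spike_times.size),
                   firing_type=(classify_firing_type(ff, spec.feature_config.tau_i_pa).type_id
                                if ff.has_firing else None))
    return row


def run_sweep(spec: SweepSpec, resume: Optional[SweepResult] = None) -> SweepResult:
    """Evaluate every grid point; per-point failures are recorded and the
    sweep continues.  Passing a previous result resumes it (completed points
    are skipped), and re-running any sweep reproduces identical tables — the
    model and protocols are fully deterministic."""
    result = resume or SweepResult(spec=spec)
    done = {tuple(r[k] for k in result.param_names) for r in result.rows}
    names = list(spec.parameters.keys())
    for values in itertools.product(*spec.parameters.values()):
        point = dict(zip(names, values))
        key = tuple(point[k] for k in names)
        if key in done:
            continue
        try:
            result.rows.append(_evaluate_point(spec, point))
        except Exception as exc:  # recorded, sweep continues
            result.failures.append({**point, "error": str(exc)})
    return result


def run_grid2(spec: SweepSpec) -> SweepResult:
    """2-D grid study (e.g. NaP V_S × S_gate with CaL blocked)."""
    if len(spec.parameters) != 2:
        raise ValueError("run_grid2 requires exactly two parameters")
    return run_sweep(spec)


def run_grid3(spec: SweepSpec) -> SweepResult:
    """3-D grid study (CaL V_1/2 × V_S × dendritic length, NaP blocked)."""
    if len(spec.parameters) != 3:
        raise ValueError("run_grid3 requires exactly three parameters")
    return run_sweep(spec)


@dataclass(frozen=True)
class CrossingResult:
    """Outcome of a threshold query along one swept parameter.

    ``value`` is the smallest grid value at which the metric has crossed
    ``level``; ``bracket`` is (last value before the crossing, value).  When
    no crossing exists both are None and the metric range is reported.
    """

    found: bool
    value: Optional[float]
    bracket: Optional[tuple]
    metric_min: float
    metric_max: float


def find_threshold_crossing(result: SweepResult, metric: str, level: float,
                            along: Optional[str] = None) -> CrossingResult:
    """Locate where ``metric`` first crosses ``level`` along a parameter.

    The crossing is reported as a bracketing grid interval, not an
    interpolated value: on a sampled grid only the bracket is defensible.
    """
    s = result.series(metric, along).sort_index().dropna()
    if s.size < 1:
        raise ValueError("no data for metric " + metric)
    vals = s.to_numpy(dtype=float)
    grid = s.index.to_numpy(dtype=float)
    side0 = vals[0] > level
    for i in range(1, vals.size):
        if (vals[i] > level) != side0:
            return CrossingResult(True, float(grid[i]),
                                  (float(grid[i - 1]), float(grid[i])),
                                  float(vals.min()), float(vals.max()))
    return CrossingResult(False, None, None, float(vals.min()), float(vals.max()))
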