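"""Trace files, run configuration and serialization.

Traces travel as delimited text (CSV with a header) plus a JSON metadata
sidecar sharing the basename — a deliberately plain interchange format,
since no vendor-format recordings are involved.  The sidecar carries the
protocol, units, model overrides and seed, enough to regenerate the command
waveform and re-run the simulation.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .model import ModelConfig
from .protocols import ClampTrace, RampProtocol
from .features import FeatureConfig

__all__ = ["read_trace", "write_trace", "RunConfig", "FORMAT_VERSION"]

FORMAT_VERSION = 1


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def write_trace(trace: ClampTrace, path: str | Path) -> Path:
    """Write a trace as ``<path>.csv`` plus a ``<path>.json`` sidecar.

    ``path`` may be given with or without the ``.csv`` suffix.  Returns the
    CSV path.
    """
    p = Path(path)
    if p.suffix == ".csv":
        p = p.with_suffix("")
    csv_path = p.with_suffix(".csv")
    pd.DataFrame({"time_ms": trace.time_ms, "command": trace.command,
                  "signal": trace.signal}).to_csv(csv_path, index=False,
                                                  float_format="%.17g")
    slim = {k: v for k, v in trace.metadata.items()
            if k not in ("aux_v_dendrite_mid",)}  # bulky, regenerable
    meta = {"format_version": FORMAT_VERSION, "package_version": _pkg_version,
            **_jsonable(slim)}
    p.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return csv_path


def read_trace(path: str | Path) -> ClampTrace:
    """Read a trace CSV (+ optional JSON sidecar) back into a ClampTrace.

    A missing sidecar yields minimal metadata with a warning; malformed rows
    and non-monotone time raise with the offending line.
    """
    csv_path = Path(path)
    try:
        df = pd.read_csv(csv_path, float_precision="round_trip")
    except Exception as exc:
        raise ValueError(f"cannot parse {csv_path}: {exc}") from exc
    required = {"time_ms", "command", "signal"}
    if not required.issubset(df.columns):
        raise ValueError(f"{csv_path}: expected columns {sorted(required)}, "
                         f"got {list(df.columns)}")
    for col in required:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"{csv_path}: malformed value in column {col!r} "
                             f"at line {int(bad[0]) + 2}")  # +2: header + 1-based
    t = df["time_ms"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        line = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 3  # header + 1-based + next row
        raise ValueError(f"{csv_path}: non-monotone time at line {line}")

    sidecar = csv_path.with_suffix(".json")
    if sidecar.exists():
        metadata = json.loads(sidecar.read_text())
    else:
        warnings.warn(f"no metadata sidecar next to {csv_path}; "
                      "using minimal defaults", stacklevel=2)
        metadata = {"format_version": FORMAT_VERSION,
                    "units": {"command": "unknown", "signal": "unknown",
                              "time": "ms"}}
    return ClampTrace(time_ms=t, command=df["command"].to_numpy(float),
                      signal=df["signal"].to_numpy(float), metadata=metadata)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_SECTION_TYPES = {"model": ModelConfig, "analysis": FeatureConfig}


@dataclass
class RunConfig:
    """A full run configuration: model overrides, protocol, tolerances, dt.

    Loaded from YAML with sections ``model``, ``protocol``, ``analysis`` and
    ``integrator``; unknown sections or keys are rejected so typos fail
    loudly rather than silently running defaults.
    """

    model: ModelConfig = field(default_factory=ModelConfig)
    protocol: dict = field(default_factory=dict)
    analysis: FeatureConfig = field(default_factory=FeatureConfig)
    dt_ms: float = 0.025

    @staticmethod
    def from_dict(data: dict) -> "RunConfig":
        known = {"model", "protocol", "analysis", "integrator"}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config sections: {sorted(unknown)}")
        kw = {}
        for section, cls in _SECTION_TYPES.items():
            entries = data.get(section) or {}
            names = {f.name for f in dataclasses.fields(cls)}
            bad = set(entries) - names
            if bad:
                raise KeyError(f"unknown keys in [{section}]: {sorted(bad)}")
            kw[section] = cls(**entries)
        integ = data.get("integrator") or {}
        bad = set(integ) - {"dt_ms"}
        if bad:
            raise KeyError(f"unknown keys in [integrator]: {sorted(bad)}")
        return RunConfig(model=kw["model"], analysis=kw["analysis"],
                         protocol=data.get("protocol") or {},
                         dt_ms=float(integ.get("dt_ms", 0.025)))

    @staticmethod
    def load(path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config root must be a mapping")
        return RunConfig.from_dict(data)

    def ramp(self, default: RampProtocol) -> RampProtocol:
        if not self.protocol:
            return default
        d = default.to_dict()
        unknown = set(self.protocol) - set(d)
        if unknown:
            raise KeyError(f"unknown keys in [protocol]: {sorted(unknown)}")
        d.update(self.protocol)
        return RampProtocol.from_dict(d)
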