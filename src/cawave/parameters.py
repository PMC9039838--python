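"""Waveform-level parameter registry and aggregation.

Each well's trace is summarised by a fixed vector of 38 named parameters.
They fall into four normalisation classes:

* ``value``     -- absolute quantities (times, widths, amplitudes, rates);
                   plate-normalised by subtracting the vehicle mean and
                   dividing by the vehicle median;
* ``ratio``     -- dimensionless shape ratios; shift-normalised only;
* ``deviation`` -- dispersion aggregates and quantities whose vehicle-plate
                   level is structurally near zero (per-cycle valleys after
                   rescaling, subpeak counts); shift-normalised only;
* ``binary``    -- waveform-normality flags, excluded from correlation and
                   modelling (35 non-binary parameters remain).

The registry is the single source of truth for names, classes, and analysis
inclusion; it serialises to YAML for audit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
import yaml

from .cycles import CycleMeasures
from .detection import Cycle
from .io import Trace

__all__ = [
    "ParameterSpec",
    "ParameterRegistry",
    "DEFAULT_REGISTRY",
    "ParameterVector",
    "derive_parameters",
    "multi_peak_statistics",
]


@dataclass(frozen=True)
class ParameterSpec:
    name: str
    cls: str  # value | ratio | deviation | binary
    aggregator: str  # mean | sd | max | count | rate | rms | flag
    source: str  # cycle-measure field or trace-level quantity


@dataclass
class ParameterRegistry:
    entries: list[ParameterSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("registry names must be unique")
        if len(self.entries) != 38:
            raise ValueError(f"registry must hold exactly 38 entries, got {len(self.entries)}")
        if len(self.binary_names()) != 3:
            raise ValueError("registry must hold exactly 3 binary entries")

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def binary_names(self) -> list[str]:
        return [e.name for e in self.entries if e.cls == "binary"]

    def analysis_names(self) -> list[str]:
        """The 35 non-binary parameters that enter correlation analysis."""
        return [e.name for e in self.entries if e.cls != "binary"]

    def class_of(self, name: str) -> str:
        for e in self.entries:
            if e.name == name:
                return e.cls
        raise KeyError(name)

    def to_yaml(self, path) -> None:
        data = [
            {"name": e.name, "class": e.cls, "aggregator": e.aggregator, "source": e.source}
            for e in self.entries
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ParameterRegistry":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            [ParameterSpec(d["name"], d["class"], d["aggregator"], d["source"]) for d in data]
        )


def _default_entries() -> list[ParameterSpec]:
    P = ParameterSpec
    return [
        # --- value: absolute quantities, full plate normalisation
        P("peak_frequency", "value", "rate", "real peak count / record duration"),
        P("peak_count", "value", "count", "real peaks"),
        P("mean_peak_space", "value", "mean", "peak_space"),
        P("mean_rise_time", "value", "mean", "rise_time"),
        P("mean_decay_time", "value", "mean", "decay_time"),
        P("mean_peak_to_end", "value", "mean", "peak_to_end"),
        P("mean_tail_duration", "value", "mean", "tail_duration"),
        P("mean_pw10", "value", "mean", "pw10"),
        P("mean_pw25", "value", "mean", "pw25"),
        P("mean_pw50", "value", "mean", "pw50"),
        P("mean_pw80", "value", "mean", "pw80"),
        P("mean_pw90", "value", "mean", "pw90"),
        P("mean_amplitude", "value", "mean", "amplitude"),
        P("max_amplitude", "value", "max", "amplitude"),
        P("mean_intensity", "value", "mean", "intensity"),
        P("rms_signal", "value", "rms", "whole trace"),
        # --- ratio: dimensionless shape parameters, shift normalisation
        P("mean_rise_decay_ratio", "ratio", "mean", "rise_decay_ratio"),
        P("mean_tail_proportion", "ratio", "mean", "tail_proportion"),
        P("mean_shoulder_position", "ratio", "mean", "shoulder_position"),
        P("mean_shoulder_tail", "ratio", "mean", "shoulder_tail_ratio"),
        P("max_shoulder_tail", "ratio", "max", "shoulder_tail_ratio"),
        # --- deviation: dispersion aggregates and near-zero-vehicle quantities
        P("sd_peak_space", "deviation", "sd", "peak_space"),
        P("sd_intensity", "deviation", "sd", "intensity"),
        P("sd_rise_time", "deviation", "sd", "rise_time"),
        P("sd_decay_time", "deviation", "sd", "decay_time"),
        P("sd_tail_duration", "deviation", "sd", "tail_duration"),
        P("sd_amplitude", "deviation", "sd", "amplitude"),
        P("sd_pw50", "deviation", "sd", "pw50"),
        P("sd_valley", "deviation", "sd", "valley"),
        P("sd_rise_decay_ratio", "deviation", "sd", "rise_decay_ratio"),
        P("sd_tail_proportion", "deviation", "sd", "tail_proportion"),
        P("mean_valley", "deviation", "mean", "valley"),
        P("inner_peak_space", "deviation", "mean", "inner_peak_space"),
        P("multi_peak_count", "deviation", "count", "subpeaks"),
        P("multi_peak_max", "deviation", "max", "subpeaks per cycle"),
        # --- binary: waveform-normality flags
        P("zero_beat", "binary", "flag", "no real peak detected"),
        P("has_multi_peak", "binary", "flag", "any subpeak present"),
        P("keypoint_failure", "binary", "flag", "any cycle with unlocatable key points"),
    ]


DEFAULT_REGISTRY = ParameterRegistry(_default_entries())


@dataclass
class ParameterVector:
    """The 38 named parameters of one waveform plus provenance."""

    values: pd.Series
    plate_id: str = ""
    well_id: str = ""
    n_cycles_used: int = 0
    trace_ma: float = 0.0

    def __getitem__(self, name: str) -> float:
        return float(self.values[name])

    def to_row(self) -> dict:
        row = {"plate_id": self.plate_id, "well_id": self.well_id}
        row.update(self.values.to_dict())
        row["n_cycles_used"] = self.n_cycles_used
        row["trace_ma"] = self.trace_ma
        return row


def multi_peak_statistics(cycles: list[Cycle]) -> tuple[int, int, bool]:
    """(total subpeak count, max subpeaks in one cycle, any present)."""
    counts = [len(c.subpeaks) for c in cycles]
    total = int(sum(counts))
    mx = int(max(counts)) if counts else 0
    return total, mx, mx >= 1


def _nanmean(x: list[float]) -> float:
    arr = np.asarray(x, dtype=float)
    arr = arr[np.isfinite(arr)]
    return float(arr.mean()) if arr.size else 0.0


def _nansd(x: list[float]) -> float:
    arr = np.asarray(x, dtype=float)
    arr = arr[np.isfinite(arr)]
    return float(arr.std(ddof=1)) if arr.size >= 2 else 0.0


def _nanmax(x: list[float]) -> float:
    arr = np.asarray(x, dtype=float)
    arr = arr[np.isfinite(arr)]
    return float(arr.max()) if arr.size else 0.0


def derive_parameters(
    trace: Trace,
    cycles: list[Cycle],
    measures: list[CycleMeasures],
    registry: ParameterRegistry = DEFAULT_REGISTRY,
) -> ParameterVector:
    """Aggregate per-cycle measures into the 38-parameter waveform vector.

    Peak frequency is the real-peak count divided by the record duration.  A
    trace with no real peak (or no usable full cycle) yields the
    zero-frequency convention: all non-binary slots 0 and ``zero_beat`` set,
    keeping beat-stop wells usable as maximal-effect observations.
    """
    names = registry.names()
    out = pd.Series(0.0, index=names)
    real_peaks = {c.start for c in cycles if not c.is_partial}
    for c in cycles:
        if c.start_peak is not None:
            real_peaks.add(c.start_peak.index)
    n_real = len(real_peaks)
    mp_count, mp_max, mp_any = multi_peak_statistics(cycles)
    any_kp_failure = any(c.keypoint_failure for c in cycles if not c.is_partial)

    out["has_multi_peak"] = float(mp_any)
    out["keypoint_failure"] = float(any_kp_failure)

    if n_real == 0 or not measures:
        out["zero_beat"] = 1.0
        vec = ParameterVector(
            out,
            plate_id=trace.plate_id,
            well_id=trace.well_id,
            n_cycles_used=0,
            trace_ma=float(np.ptp(trace.values)),
        )
        return vec

    def col(fieldname: str) -> list[float]:
        vals = []
        for m in measures:
            v = getattr(m, fieldname)
            vals.append(math.nan if v is None else float(v))
        return vals

    out["peak_frequency"] = n_real / trace.duration
    out["peak_count"] = float(n_real)
    out["mean_peak_space"] = _nanmean(col("peak_space"))
    out["mean_rise_time"] = _nanmean(col("rise_time"))
    out["mean_decay_time"] = _nanmean(col("decay_time"))
    out["mean_peak_to_end"] = _nanmean(col("peak_to_end"))
    out["mean_tail_duration"] = _nanmean(col("tail_duration"))
    for f, name in ((10, "mean_pw10"), (25, "mean_pw25"), (50, "mean_pw50"),
                    (80, "mean_pw80"), (90, "mean_pw90")):
        out[name] = _nanmean(col(f"pw{f}"))
    out["mean_amplitude"] = _nanmean(col("amplitude"))
    out["max_amplitude"] = _nanmax(col("amplitude"))
    out["mean_intensity"] = _nanmean(col("intensity"))
    out["rms_signal"] = float(np.sqrt(np.mean(trace.values**2)))
    out["mean_rise_decay_ratio"] = _nanmean(col("rise_decay_ratio"))
    out["mean_tail_proportion"] = _nanmean(col("tail_proportion"))
    positions = [m.shoulder_position for m in measures if m.shoulder_position is not None]
    out["mean_shoulder_position"] = _nanmean(positions) if positions else 0.0
    out["mean_shoulder_tail"] = _nanmean(col("shoulder_tail_ratio"))
    out["max_shoulder_tail"] = _nanmax(col("shoulder_tail_ratio"))
    out["sd_peak_space"] = _nansd(col("peak_space"))
    out["sd_intensity"] = _nansd(col("intensity"))
    out["sd_rise_time"] = _nansd(col("rise_time"))
    out["sd_decay_time"] = _nansd(col("decay_time"))
    out["sd_tail_duration"] = _nansd(col("tail_duration"))
    out["sd_amplitude"] = _nansd(col("amplitude"))
    out["sd_pw50"] = _nansd(col("pw50"))
    out["sd_valley"] = _nansd(col("valley"))
    out["sd_rise_decay_ratio"] = _nansd(col("rise_decay_ratio"))
    out["sd_tail_proportion"] = _nansd(col("tail_proportion"))
    out["mean_valley"] = _nanmean(col("valley"))
    out["inner_peak_space"] = _nanmean(col("inner_peak_space"))
    out["multi_peak_count"] = float(mp_count)
    out["multi_peak_max"] = float(mp_max)

    return ParameterVector(
        out,
        plate_id=trace.plate_id,
        well_id=trace.well_id,
        n_cycles_used=len(measures),
        trace_ma=float(np.ptp(trace.values)),
    )
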