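"""Plate time-series ingestion, smoothing, and rescaling.

Fast-kinetic fluorescence plate readers report one relative-fluorescence-unit
(RFU) trace per well at ~100 ms resolution.  Two table dialects are supported:

* ``az``  -- 1,150 reads per well: the first 350 reads are a pre-compound
  baseline recording, the remaining 800 reads cover 100 s post-addition.
  Baseline and post-addition segments are split into linked trace pairs.
* ``gsk`` -- 600 reads covering 65.5 s, no baseline segment.

Tables may be wide (one column per well, optional ``time`` column) or tidy
long format (``plate``, ``well``, ``time``, ``rfu``, optional
``is_baseline``).  Every well must be covered by a sample-metadata table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "Trace",
    "SampleMeta",
    "TraceSet",
    "DIALECTS",
    "read_plate_table",
    "write_plate_table",
    "read_metadata",
    "smooth_trace",
    "rescale_trace",
]

#: sampling layouts per source dialect: (n_baseline_reads, n_main_reads, main_duration_s)
DIALECTS = {
    "az": {"n_baseline": 350, "n_main": 800, "duration": 100.0},
    "gsk": {"n_baseline": 0, "n_main": 600, "duration": 65.5},
}

_MIN_TRACE_LEN = 11
_UNIFORM_RTOL = 1e-9


@dataclass
class Trace:
    """One well's fluorescence time series on a uniform time grid."""

    times: np.ndarray
    values: np.ndarray
    well_id: str = ""
    plate_id: str = ""
    is_baseline: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("trace times and values must be 1-D")
        if self.times.size != self.values.size:
            raise ValueError("times and values length mismatch")
        if self.times.size < _MIN_TRACE_LEN:
            raise ValueError(
                f"trace too short ({self.times.size} < {_MIN_TRACE_LEN} samples)"
            )
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite samples")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ValueError("trace times must be strictly increasing")
        dt = steps.mean()
        if np.any(np.abs(steps - dt) > _UNIFORM_RTOL * max(abs(dt), 1.0)):
            raise ValueError("trace time grid is not uniform")

    @property
    def sampling_interval(self) -> float:
        """Sampling interval in seconds."""
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        """Record span in seconds (n samples x interval)."""
        return self.times.size * self.sampling_interval

    @property
    def key(self) -> tuple[str, str]:
        return (self.plate_id, self.well_id)

    def __len__(self) -> int:
        return self.times.size


@dataclass
class SampleMeta:
    """Per-well sample annotation.

    Vehicle (0.1% DMSO) and positive (10 uM verapamil) control wells carry no
    concentration; treated wells require a compound and a positive
    concentration in uM.
    """

    compound_id: str
    concentration: Optional[float]
    role: str  # treated | vehicle | positive
    plate_id: str
    well_id: str
    source: str = "gsk"  # az | gsk
    exposure: str = "30min"
    smiles: Optional[str] = None
    cardiac_active: Optional[int] = None

    def __post_init__(self) -> None:
        if self.role not in ("treated", "vehicle", "positive"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "treated":
            if not self.compound_id:
                raise ValueError(f"treated well {self.well_id} lacks compound_id")
            if self.concentration is None or not self.concentration > 0:
                raise ValueError(
                    f"treated well {self.well_id} needs a positive concentration"
                )
        elif self.concentration is not None:
            raise ValueError(
                f"{self.role} control {self.well_id} must not carry a concentration"
            )


@dataclass
class TraceSet:
    """Traces plus metadata keyed by (plate_id, well_id).

    ``baseline_links`` maps a treated/control trace key to its pre-compound
    baseline trace; only present for az-dialect plates.
    """

    traces: list[Trace] = field(default_factory=list)
    meta: dict[tuple[str, str], SampleMeta] = field(default_factory=dict)
    baseline_links: dict[tuple[str, str], Trace] = field(default_factory=dict)

    def validate(self) -> None:
        for tr in self.main_traces():
            if tr.key not in self.meta:
                raise ValueError(f"trace {tr.key} has no metadata row")

    def main_traces(self) -> list[Trace]:
        return [t for t in self.traces if not t.is_baseline]

    def baseline_for(self, trace: Trace) -> Optional[Trace]:
        return self.baseline_links.get(trace.key)

    def __len__(self) -> int:
        return len(self.main_traces())


# ---------------------------------------------------------------------------
# reading / writing


def read_metadata(meta_path: str | Path) -> dict[tuple[str, str], SampleMeta]:
    """Read a sample-metadata CSV into SampleMeta rows keyed by (plate, well)."""
    df = pd.read_csv(meta_path)
    required = {"compound_id", "role", "plate_id", "well_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata table lacks columns: {sorted(missing)}")
    out: dict[tuple[str, str], SampleMeta] = {}
    for _, row in df.iterrows():
        conc = row.get("concentration")
        conc = None if pd.isna(conc) else float(conc)
        label = row.get("cardiac_active")
        label = None if pd.isna(label) else int(label)
        smiles = row.get("smiles")
        smiles = None if (smiles is None or pd.isna(smiles)) else str(smiles)
        meta = SampleMeta(
            compound_id=str(row["compound_id"]),
            concentration=conc,
            role=str(row["role"]),
            plate_id=str(row["plate_id"]),
            well_id=str(row["well_id"]),
            source=str(row.get("source", "gsk")),
            exposure=str(row.get("exposure", "30min")),
            smiles=smiles,
            cardiac_active=label,
        )
        out[(meta.plate_id, meta.well_id)] = meta
    return out


def _split_az(times: np.ndarray, values: np.ndarray, n_baseline: int):
    """Split an az-dialect read-out into (baseline, main) segments.

    The main segment's clock is re-zeroed at compound addition.
    """
    t_base, v_base = times[:n_baseline], values[:n_baseline]
    t_main, v_main = times[n_baseline:], values[n_baseline:]
    return (t_base - t_base[0], v_base), (t_main - t_main[0], v_main)


def read_plate_table(
    path: str | Path,
    dialect: str,
    meta_path: str | Path,
    plate_id: Optional[str] = None,
) -> TraceSet:
    """Read a plate table (wide or tidy long CSV/TSV) into a TraceSet.

    For the az dialect each well's read-out is split into a 350-read baseline
    trace and an 800-read post-addition trace, linked in
    ``TraceSet.baseline_links``.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}")
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    # round_trip parsing keeps rfu/time values bit-exact through write/read
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    meta = read_metadata(meta_path)

    ts = TraceSet(meta=meta)
    long_cols = {"plate", "well", "time", "rfu"}
    if long_cols.issubset(df.columns):
        _read_long(df, dialect, ts)
    else:
        _read_wide(df, dialect, ts, plate_id or path.stem)

    missing = [t.key for t in ts.main_traces() if t.key not in meta]
    if missing:
        raise ValueError(
            "metadata missing for wells: "
            + ", ".join(f"{p}/{w}" for p, w in sorted(missing))
        )
    ts.validate()
    return ts


def _read_wide(df: pd.DataFrame, dialect: str, ts: TraceSet, plate_id: str) -> None:
    spec = DIALECTS[dialect]
    cols = list(df.columns)
    if "time" in cols:
        times = df["time"].to_numpy(dtype=float)
        well_cols = [c for c in cols if c != "time"]
    else:
        n = len(df)
        n_expected = spec["n_baseline"] + spec["n_main"]
        dt = spec["duration"] / spec["n_main"]
        times = np.arange(n) * dt
        well_cols = cols
        if n != n_expected:
            raise ValueError(
                f"{dialect} dialect expects {n_expected} reads per well, got {n}"
            )
    for well in well_cols:
        values = df[well].to_numpy(dtype=float)
        _add_well(ts, dialect, plate_id, str(well), times, values)


def _read_long(df: pd.DataFrame, dialect: str, ts: TraceSet) -> None:
    has_flag = "is_baseline" in df.columns
    for (plate, well), sub in df.groupby(["plate", "well"], sort=True):
        sub = sub.sort_values("time")
        if has_flag:
            base = sub[sub["is_baseline"].astype(bool)]
            main = sub[~sub["is_baseline"].astype(bool)]
            if len(base):
                tr = Trace(
                    base["time"].to_numpy(float),
                    base["rfu"].to_numpy(float),
                    well_id=str(well),
                    plate_id=str(plate),
                    is_baseline=True,
                )
                ts.traces.append(tr)
                ts.baseline_links[(str(plate), str(well))] = tr
            ts.traces.append(
                Trace(
                    main["time"].to_numpy(float),
                    main["rfu"].to_numpy(float),
                    well_id=str(well),
                    plate_id=str(plate),
                )
            )
        else:
            _add_well(
                ts,
                dialect,
                str(plate),
                str(well),
                sub["time"].to_numpy(float),
                sub["rfu"].to_numpy(float),
            )


def _add_well(
    ts: TraceSet,
    dialect: str,
    plate_id: str,
    well_id: str,
    times: np.ndarray,
    values: np.ndarray,
) -> None:
    spec = DIALECTS[dialect]
    if spec["n_baseline"] and len(times) == spec["n_baseline"] + spec["n_main"]:
        (tb, vb), (tm, vm) = _split_az(times, values, spec["n_baseline"])
        base = Trace(tb, vb, well_id=well_id, plate_id=plate_id, is_baseline=True)
        ts.traces.append(base)
        ts.baseline_links[(plate_id, well_id)] = base
        ts.traces.append(Trace(tm, vm, well_id=well_id, plate_id=plate_id))
    else:
        ts.traces.append(Trace(times, values, well_id=well_id, plate_id=plate_id))


def write_plate_table(traceset: TraceSet, path: str | Path) -> pd.DataFrame:
    """Write the canonical tidy trace table (plate, well, is_baseline, time, rfu)."""
    rows = []
    for tr in traceset.traces:
        rows.append(
            pd.DataFrame(
                {
                    "plate": tr.plate_id,
                    "well": tr.well_id,
                    "is_baseline": tr.is_baseline,
                    "time": tr.times,
                    "rfu": tr.values,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    out.to_csv(path, index=False, float_format="%.17g")
    return out


# ---------------------------------------------------------------------------
# smoothing / rescaling


def smooth_trace(trace: Trace, window: int = 5, order: int = 2) -> Trace:
    """Savitzky-Golay smoothing (default: 5-point quadratic).

    Boundary samples are filled from the polynomial fitted to the first/last
    window rather than by truncation, so the trace keeps its length.
    """
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    if window >= len(trace):
        raise ValueError("smoothing window must be shorter than the trace")
    if order >= window:
        raise ValueError("polynomial order must be below the window length")
    smoothed = savgol_filter(trace.values, window, order, mode="interp")
    return replace(trace, values=smoothed)


def rescale_trace(trace: Trace) -> Trace:
    """Shift the trace so its minimum RFU is zero (per-well offset removal)."""
    return replace(trace, values=trace.values - trace.values.min())
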