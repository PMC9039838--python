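"""Sample- and plate-level quality control, vehicle-control normalisation,
and concentration gridding.

QC cascade (all applicable reasons are accumulated, never short-circuited):

* ``zero_frequency``     -- no real beat detected in the sample;
* ``baseline_multipeak`` -- the pre-compound baseline contains a multiple
                            peak (abnormal cells; baseline-linked data only);
* ``baseline_low_MA``    -- baseline maximum amplitude below 100 RFU
                            (cells have stopped beating);
* ``keypoint_failure``   -- a cycle whose key time points cannot be located;
* ``frequency_outlier``  -- peak frequency outside +/-20% of the plate's
                            vehicle-control median frequency;
* ``plate_excluded``     -- the whole plate failed the vehicle RCV gate.

Plates whose vehicle controls show a robust coefficient of variation (RCV,
1.4826 x MAD / |median|) above 20% on the designated QC parameters are
excluded wholesale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .parameters import DEFAULT_REGISTRY, ParameterRegistry

__all__ = [
    "QCConfig",
    "QCResult",
    "qc_sample",
    "robust_cv",
    "qc_plate",
    "normalize_plate",
    "normalize_dataset",
    "qc_dataset",
    "map_concentration",
    "STANDARD_CONCENTRATIONS",
    "select_modeling_samples",
]

STANDARD_CONCENTRATIONS = (0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0)


@dataclass
class QCConfig:
    baseline_ma_min: float = 100.0
    frequency_band: float = 0.20
    plate_rcv_max: float = 0.20
    plate_rcv_parameters: tuple[str, ...] = ("peak_frequency", "mean_amplitude")
    rcv_consistency_constant: float = 1.4826
    baseline_multipeak_strict: bool = False  # True: literal "count > 1" reading
    vehicle_median_eps: float = 1e-12


@dataclass
class QCResult:
    plate_id: str
    well_id: str
    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.reasons


def qc_sample(
    params: pd.Series,
    baseline_params: Optional[pd.Series] = None,
    plate_vehicle_freq_median: Optional[float] = None,
    config: QCConfig | None = None,
    plate_id: str = "",
    well_id: str = "",
) -> QCResult:
    """Apply the per-sample QC rules to one parameter row.

    ``params`` is a derived parameter row (including the ``trace_ma``
    provenance column for baselines).  Baseline rules run only when a baseline
    row is supplied; the frequency-outlier rule is skipped (with a warning)
    when the plate has no vehicle wells.
    """
    config = config or QCConfig()
    reasons: list[str] = []
    if params.get("zero_beat", 0.0) >= 1.0 or params.get("peak_frequency", 0.0) == 0.0:
        reasons.append("zero_frequency")
    if baseline_params is not None:
        count = baseline_params.get("multi_peak_count", 0.0)
        bad = count > 1 if config.baseline_multipeak_strict else count >= 1
        if bad:
            reasons.append("baseline_multipeak")
        if baseline_params.get("trace_ma", np.inf) < config.baseline_ma_min:
            reasons.append("baseline_low_MA")
    if params.get("keypoint_failure", 0.0) >= 1.0:
        reasons.append("keypoint_failure")
    if plate_vehicle_freq_median is None:
        warnings.warn(
            f"plate {plate_id!r}: no vehicle wells, frequency-outlier rule skipped",
            stacklevel=2,
        )
    elif plate_vehicle_freq_median > 0:
        f = params.get("peak_frequency", 0.0)
        # beat-stop wells carry the more specific zero_frequency reason only
        if f > 0 and abs(f - plate_vehicle_freq_median) > (
            config.frequency_band * plate_vehicle_freq_median
        ):
            reasons.append("frequency_outlier")
    return QCResult(plate_id=plate_id, well_id=well_id, reasons=reasons)


def robust_cv(values: Sequence[float], consistency: float = 1.4826) -> float:
    """Robust coefficient of variation: consistency x MAD / |median|.

    The default consistency constant makes the MAD estimate the standard
    deviation under normality; pass 1.0 for the plain MAD/median ratio.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("robust_cv needs at least 2 values")
    med = float(np.median(arr))
    if med == 0:
        raise ValueError("robust_cv undefined for zero median")
    mad = float(np.median(np.abs(arr - med)))
    return consistency * mad / abs(med)


def qc_plate(
    plate_vehicle_params: pd.DataFrame, config: QCConfig | None = None
) -> bool:
    """True when the plate's vehicle controls pass the RCV gate.

    The gate checks each designated QC parameter; any RCV strictly above the
    threshold excludes the plate.  Fewer than two vehicle wells exclude the
    plate with a warning.
    """
    config = config or QCConfig()
    if len(plate_vehicle_params) < 2:
        warnings.warn("plate has fewer than 2 vehicle wells; excluded", stacklevel=2)
        return False
    for name in config.plate_rcv_parameters:
        vals = plate_vehicle_params[name].to_numpy(dtype=float)
        try:
            rcv = robust_cv(vals, config.rcv_consistency_constant)
        except ValueError:
            return False
        if rcv > config.plate_rcv_max:
            return False
    return True


# ---------------------------------------------------------------------------
# normalisation


def normalize_plate(
    param_df: pd.DataFrame,
    vehicle_mask: np.ndarray,
    registry: ParameterRegistry = DEFAULT_REGISTRY,
    eps: float = 1e-12,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vehicle-control normalisation of one plate's parameter rows.

    Value-class parameters: (x - vehicle mean) / vehicle median.  Ratio- and
    deviation-class parameters: x - vehicle mean.  Binary flags pass through.
    Returns the normalised frame and the per-parameter vehicle reference stats.
    """
    if not vehicle_mask.any():
        raise ValueError("plate has no vehicle wells; cannot normalise")
    out = param_df.copy()
    stats_rows = []
    for entry in registry.entries:
        name = entry.name
        veh = param_df.loc[vehicle_mask, name].to_numpy(dtype=float)
        ref_mean = float(veh.mean())
        ref_median = float(np.median(veh))
        stats_rows.append(
            {"parameter": name, "class": entry.cls,
             "vehicle_mean": ref_mean, "vehicle_median": ref_median}
        )
        if entry.cls == "binary":
            continue
        if entry.cls == "value":
            if abs(ref_median) <= eps:
                raise ValueError(
                    f"vehicle median of value-class parameter {name!r} is ~0; "
                    "cannot divide"
                )
            out[name] = (param_df[name] - ref_mean) / ref_median
        else:  # ratio / deviation: shift only
            out[name] = param_df[name] - ref_mean
    return out, pd.DataFrame(stats_rows)


def qc_dataset(
    param_table: pd.DataFrame,
    meta_df: pd.DataFrame,
    baseline_table: Optional[pd.DataFrame] = None,
    config: QCConfig | None = None,
) -> pd.DataFrame:
    """Run sample QC then the plate RCV gate over a full parameter table.

    ``param_table`` holds one row per (plate_id, well_id) with the 38
    parameter columns plus provenance; ``meta_df`` carries at least plate_id,
    well_id, and role.  Returns a QC report with pass flags and reason lists.
    """
    config = config or QCConfig()
    meta = meta_df.set_index(["plate_id", "well_id"])
    base = (
        baseline_table.set_index(["plate_id", "well_id"])
        if baseline_table is not None and len(baseline_table)
        else None
    )
    rows = []
    for plate, group in param_table.groupby("plate_id", sort=True):
        roles = meta.loc[[(plate, w) for w in group["well_id"]], "role"].to_numpy()
        veh_mask = roles == "vehicle"
        veh = group[veh_mask]
        freq_median = (
            float(veh["peak_frequency"].median()) if len(veh) else None
        )
        plate_ok = qc_plate(veh, config) if len(veh) else False
        for (_, row), role in zip(group.iterrows(), roles):
            key = (row["plate_id"], row["well_id"])
            brow = base.loc[key] if base is not None and key in base.index else None
            res = qc_sample(
                row, brow, freq_median, config,
                plate_id=row["plate_id"], well_id=row["well_id"],
            )
            if not plate_ok:
                res.reasons.append("plate_excluded")
            rows.append(
                {"plate_id": res.plate_id, "well_id": res.well_id, "role": role,
                 "passed": res.passed, "reasons": ";".join(res.reasons)}
            )
    return pd.DataFrame(rows)


def normalize_dataset(
    param_table: pd.DataFrame,
    meta_df: pd.DataFrame,
    registry: ParameterRegistry = DEFAULT_REGISTRY,
    eps: float = 1e-12,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plate-by-plate vehicle normalisation of a full parameter table."""
    meta = meta_df.set_index(["plate_id", "well_id"])
    frames, stats = [], []
    for plate, group in param_table.groupby("plate_id", sort=True):
        roles = np.array(
            [meta.loc[(plate, w), "role"] for w in group["well_id"]]
        )
        norm, ref = normalize_plate(group, roles == "vehicle", registry, eps)
        ref.insert(0, "plate_id", plate)
        frames.append(norm)
        stats.append(ref)
    return (
        pd.concat(frames, ignore_index=True),
        pd.concat(stats, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# concentration gridding


def map_concentration(
    conc_um: float, grid: Sequence[float] = STANDARD_CONCENTRATIONS
) -> float:
    """Snap a tested concentration (uM) to the nearest standard grid point on
    a log10 scale; exact log-midpoint ties map to the higher concentration."""
    if not conc_um > 0:
        raise ValueError(f"concentration must be positive, got {conc_um}")
    logs = np.log10(np.asarray(grid, dtype=float))
    d = np.abs(logs - np.log10(conc_um))
    best = d.min()
    candidates = np.nonzero(d <= best + 1e-12)[0]
    return float(np.asarray(grid, dtype=float)[candidates].max())


def select_modeling_samples(
    dataset: pd.DataFrame,
    target: float = 100.0,
    compound_col: str = "compound_id",
    conc_col: str = "std_concentration",
) -> pd.DataFrame:
    """Per compound, keep all samples at the target standard concentration,
    falling back to the compound's highest gridded concentration.

    Replicate multiplicity is preserved; compounds with no samples are
    dropped with a warning upstream.
    """
    parts = []
    for _, group in dataset.groupby(compound_col, sort=True):
        concs = group[conc_col].to_numpy(dtype=float)
        use = target if (concs == target).any() else concs.max()
        parts.append(group[group[conc_col] == use])
    if not parts:
        return dataset.iloc[0:0]
    return pd.concat(parts, ignore_index=True)
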