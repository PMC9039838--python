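"""End-to-end orchestration: trace -> parameters -> QC -> normalisation -> model.

Every stage reads and writes plain CSV/JSON artifacts, so stages can be
re-run individually (from the CLI or from R/other tools) and a fixed
configuration plus seed reproduces a run byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .cycles import CycleMeasures, ShoulderConfig, measure_cycles
from .detection import DetectionConfig, detect_cycles
from .io import Trace, TraceSet, rescale_trace, smooth_trace
from .model import DEFAULT_SEED, CardiacActivityModel
from .parameters import DEFAULT_REGISTRY, ParameterRegistry, ParameterVector, derive_parameters
from .qc import QCConfig, map_concentration, normalize_dataset, qc_dataset, select_modeling_samples

__all__ = [
    "RunConfig",
    "analyze_trace",
    "derive_parameter_table",
    "cycle_table",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """All pipeline thresholds plus seed; round-trips losslessly through YAML."""

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    shoulder: ShoulderConfig = field(default_factory=ShoulderConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    smoothing_window: int = 5
    smoothing_order: int = 2
    n_features: int = 25
    redundancy_threshold: float = 0.95
    per_fold_selection: bool = True
    target_concentration: float = 100.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.smoothing_window % 2 == 0 or self.smoothing_window < 3:
            raise ValueError("smoothing_window must be an odd integer >= 3")
        if not 0 < self.redundancy_threshold <= 1:
            raise ValueError("redundancy_threshold must lie in (0, 1]")
        if self.n_features < 1:
            raise ValueError("n_features must be positive")

    def to_yaml(self, path) -> None:
        def unpack(obj):
            if dataclasses.is_dataclass(obj):
                return {k: unpack(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        with open(path, "w") as fh:
            yaml.safe_dump(unpack(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)

        def build(klass, payload):
            fields = {f.name: f for f in dataclasses.fields(klass)}
            kwargs = {}
            for k, v in payload.items():
                if k not in fields:
                    raise ValueError(f"unknown config key {k!r} for {klass.__name__}")
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[k] = v
            return klass(**kwargs)

        kwargs = {}
        for key, val in data.items():
            if key == "detection":
                kwargs[key] = build(DetectionConfig, val)
            elif key == "shoulder":
                kwargs[key] = build(ShoulderConfig, val)
            elif key == "qc":
                kwargs[key] = build(QCConfig, val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


def analyze_trace(
    trace: Trace, config: RunConfig | None = None
) -> tuple[ParameterVector, list, list[CycleMeasures]]:
    """Smooth, rescale, detect, and parameterise one trace.

    Returns the 38-parameter vector plus the cycle partition and per-cycle
    measures for auditing.
    """
    config = config or RunConfig()
    tr = smooth_trace(trace, config.smoothing_window, config.smoothing_order)
    tr = rescale_trace(tr)
    _, cycles = detect_cycles(tr, config.detection)
    measures = measure_cycles(tr, cycles, config.shoulder)
    vector = derive_parameters(tr, cycles, measures)
    return vector, cycles, measures


def derive_parameter_table(
    traceset: TraceSet, config: RunConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parameter table (one row per well) for main and baseline traces."""
    config = config or RunConfig()
    main_rows, base_rows = [], []
    for trace in traceset.traces:
        vec, _, _ = analyze_trace(trace, config)
        (base_rows if trace.is_baseline else main_rows).append(vec.to_row())
    main = pd.DataFrame(main_rows)
    base = pd.DataFrame(base_rows)
    return main, base


def cycle_table(traceset: TraceSet, config: RunConfig | None = None) -> pd.DataFrame:
    """Tidy per-cycle measure table keyed by (plate, well, cycle_index)."""
    config = config or RunConfig()
    rows = []
    for trace in traceset.traces:
        if trace.is_baseline:
            continue
        _, cycles, measures = analyze_trace(trace, config)
        for m in measures:
            row = dataclasses.asdict(m)
            row["plate_id"] = trace.plate_id
            row["well_id"] = trace.well_id
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    traceset: TraceSet,
    meta_df: pd.DataFrame,
    out_dir: str | Path,
    config: RunConfig | None = None,
    registry: ParameterRegistry = DEFAULT_REGISTRY,
    fit_model: bool = True,
) -> dict:
    """Run derive -> qc -> normalise -> select -> model, writing artifacts.

    Returns a dict of the in-memory artifacts; CSV/JSON copies land in
    ``out_dir``.  Model fitting requires compound labels in the metadata and
    can be disabled for parameter-only runs.
    """
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry.to_yaml(out / "registry.yaml")
    config.to_yaml(out / "config.yaml")

    params, base_params = derive_parameter_table(traceset, config)
    params.to_csv(out / "parameters.csv", index=False)
    if len(base_params):
        base_params.to_csv(out / "baseline_parameters.csv", index=False)

    qc_report = qc_dataset(params, meta_df, base_params, config.qc)
    qc_report.to_csv(out / "qc_report.csv", index=False)
    passed = set(
        map(tuple, qc_report.loc[qc_report["passed"], ["plate_id", "well_id"]].values)
    )
    kept = params[
        [tuple(k) in passed for k in params[["plate_id", "well_id"]].values]
    ].reset_index(drop=True)

    normalized, ref_stats = normalize_dataset(kept, meta_df, registry)
    normalized.to_csv(out / "normalized_parameters.csv", index=False)
    ref_stats.to_csv(out / "vehicle_reference.csv", index=False)

    merged = normalized.merge(meta_df, on=["plate_id", "well_id"], how="left")
    treated = merged[merged["role"] == "treated"].copy()
    treated["std_concentration"] = [
        map_concentration(c) for c in treated["concentration"]
    ]
    modeling = select_modeling_samples(treated, config.target_concentration)
    modeling.to_csv(out / "modeling_samples.csv", index=False)

    artifacts = {
        "parameters": params,
        "baseline_parameters": base_params,
        "qc_report": qc_report,
        "normalized": normalized,
        "modeling": modeling,
    }
    if fit_model and modeling["cardiac_active"].notna().all() and len(modeling):
        model = CardiacActivityModel.from_dataframe(
            modeling,
            feature_columns=registry.analysis_names(),
            n_features=config.n_features,
            redundancy_threshold=config.redundancy_threshold,
            per_fold_selection=config.per_fold_selection,
        )
        results = model.fit(seed=config.seed)
        results.sample_predictions.to_csv(out / "sample_predictions.csv", index=False)
        results.compound_predictions.to_csv(
            out / "compound_predictions.csv", index=False
        )
        results.report.roc_compound_wise.to_csv(out / "roc_points.csv", index=False)
        metrics = {
            "sample_wise": results.metrics("sample_wise"),
            "compound_wise": results.metrics("compound_wise"),
            "seed": config.seed,
        }
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True)
        (out / "summary.txt").write_text(results.summary() + "\n")
        artifacts["results"] = results
    return artifacts
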