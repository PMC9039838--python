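import warnings

import numpy as np
import pandas as pd
import pytest

from cawave.pipeline import run_pipeline
from cawave.synthetic import (
    CycleTemplate,
    benchmark_design,
    recovery_template,
    simulate_plate,
    simulate_trace,
)


@pytest.fixture(scope="session")
def recovery_tpl() -> CycleTemplate:
    return recovery_template()


@pytest.fixture(scope="session")
def clean_recovery(recovery_tpl):
    """Noiseless slow-beat trace plus ground-truth annotations."""
    return simulate_trace(recovery_tpl, duration=30.0, dt=0.1)


@pytest.fixture(scope="session")
def subpeak_template() -> CycleTemplate:
    """Slow template with one injected double peak per cycle."""
    return CycleTemplate(
        period=2.5, amplitude=200.0, rise_fraction=0.24,
        decay_constant=0.18, subpeak=(0.8, 0.9),
    )


@pytest.fixture(scope="session")
def benchmark_artifacts(tmp_path_factory):
    """The bundled 40-compound separable benchmark, run once per session."""
    design = benchmark_design(seed=20220210)
    traceset, meta = simulate_plate(design)
    out = tmp_path_factory.mktemp("benchmark")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        artifacts = run_pipeline(traceset, meta, out, fit_model=True)
    artifacts["meta"] = meta
    artifacts["out_dir"] = out
    return artifacts
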