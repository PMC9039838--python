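"""Synthetic calcium-transient plates with ground-truth annotations.

The generator emulates spontaneously beating hiPSC-cardiomyocyte wells as
recorded by a fast-kinetic fluorescence plate reader: ~1 Hz transients at
~100 ms sampling, with a fast sigmoidal upstroke, an exponential decay that
may carry a mid-decay shoulder plateau or a secondary (double-peak) bump, and
a near-baseline dwell (tail) before the next beat.  Shapes are
phenomenological -- no electrophysiological ODE model is attempted.

Every trace carries ground-truth annotations (peak/subpeak indices, amplitude,
period, and time-parameter values measured from the clean samples by simple
threshold scans) so downstream detection and parameterization can be tested
against the generator rather than against themselves.

Whole labelled plates are simulated from a :class:`PlateDesign`: shared
vehicle-control behaviour with well-to-well jitter, near-flat positive
controls (95% transient suppression), and active compounds that perturb the
control template through Hill functions of concentration (amplitude
suppression, frequency increase, shoulder induction, or double-peak
induction).  Inactive compounds draw from the control distribution at every
concentration, and SMILES are assigned randomly from a bundled pool so
structure carries no activity signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from ._smiles import SMILES_POOL
from .io import SampleMeta, Trace, TraceSet

__all__ = [
    "CycleTemplate",
    "TraceAnnotations",
    "EffectSpec",
    "CompoundSpec",
    "PlateDesign",
    "simulate_trace",
    "recovery_template",
    "fig_shapes_triplet",
    "simulate_plate",
    "benchmark_design",
]

_CAP_DROP = 0.10    # fractional amplitude drop across the quadratic peak cap
_FLOOR_FRAC = 0.05  # dwell level (fraction of amplitude) between beats
_RISE_START_FRAC = 0.10  # upstroke enters the scan window at 10% amplitude
_SUBPEAK_WIDTH = 0.12    # s, Gaussian half-width of the double-peak bump


@dataclass
class CycleTemplate:
    """Shape of one beat cycle.

    ``rise_fraction`` is the duration of the upstroke (10%-of-amplitude level
    to peak) as a fraction of the period.  ``decay_constant`` (s) and
    ``tail_dwell`` (s) are alternative ways to fix the decay speed: give
    exactly one; the other is derived from the period budget.  ``shoulder`` is
    (position as prominence fraction, dwell s); ``subpeak`` is (offset after
    the peak s, height as fraction of amplitude).
    """

    period: float = 1.25
    amplitude: float = 200.0
    rise_fraction: float = 0.35
    decay_constant: Optional[float] = 0.05
    tail_dwell: Optional[float] = None
    shoulder: Optional[tuple[float, float]] = None
    subpeak: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not 0 < self.rise_fraction < 0.5:
            raise ValueError("rise_fraction must lie in (0, 0.5)")
        if self.period <= 0 or self.amplitude <= 0:
            raise ValueError("period and amplitude must be positive")
        if (self.decay_constant is None) == (self.tail_dwell is None):
            raise ValueError("give exactly one of decay_constant or tail_dwell")
        if self.shoulder is not None:
            pos, dwell = self.shoulder
            if not 0.15 < pos < 0.8:
                raise ValueError("shoulder position must lie in (0.15, 0.8)")
            if dwell <= 0 or dwell >= self.period:
                raise ValueError("shoulder dwell must lie in (0, period)")
        if self.subpeak is not None:
            off, rel = self.subpeak
            if not 0 < off < self.period:
                raise ValueError("subpeak offset must lie inside the cycle")
            if not 0 < rel < 1:
                raise ValueError("subpeak relative height must lie in (0, 1)")


@dataclass
class TraceAnnotations:
    """Ground truth attached to a simulated trace.

    Time parameters are measured from the clean (noise-free) samples by
    linear threshold scans, so they include sampling quantisation exactly the
    way an ideal detector would see it.
    """

    peak_indices: np.ndarray
    peak_times: np.ndarray
    subpeak_indices: np.ndarray
    amplitude: float
    period: float
    frequency: float
    rise_time: float
    decay_time: float
    tail_duration: float
    peak_space: float
    n_subpeaks_per_cycle: int
    clean_values: np.ndarray


@dataclass(frozen=True)
class _Geometry:
    """Resolved per-sampling-rate cycle geometry (all in seconds from peak).

    The peak and the valley sit on quadratic caps wide enough that a 5-point
    quadratic smoothing filter reproduces them exactly; cap and foot widths
    shrink for fast beats where fewer samples per cycle are available.
    """

    q_p: float       # peak-cap half-width
    v_half: float    # valley-cap half-width
    foot: float      # sub-10% upstroke foot duration
    rise_dur: float  # 10% level -> peak
    tc: float        # exponential decay constant
    dwell: float     # flat inter-beat dwell at the floor level
    tau_d: float     # decay reaches the floor level (valley-cap left edge)
    tau_level: float # decay reaches the shoulder level (inf without shoulder)


def _geometry(tpl: CycleTemplate, dt: float) -> _Geometry:
    P = tpl.period
    rise_dur = tpl.rise_fraction * P
    wide = P / dt >= 16
    q_p = (3 if wide else 2) * dt
    v_half = (2 if wide else 1) * dt
    foot = (2 if wide else 1) * dt
    if rise_dur < q_p + dt:
        raise ValueError(
            f"rise duration {rise_dur:.3f}s too short for sampling interval {dt}s"
        )
    d_s = tpl.shoulder[1] if tpl.shoulder else 0.0
    span = math.log((1 - _CAP_DROP) / _FLOOR_FRAC)
    budget = P - rise_dur - q_p - 2 * v_half - foot - d_s
    if tpl.decay_constant is not None:
        tc = tpl.decay_constant
        dwell = budget - tc * span
    else:
        dwell = tpl.tail_dwell
        tc = (budget - dwell) / span
    if tc <= 0 or dwell < -1e-12:
        raise ValueError(
            "inconsistent template: decay, shoulder dwell and rise do not fit "
            f"in the period (tc={tc:.4f}, dwell={dwell:.4f})"
        )
    dwell = max(dwell, 0.0)
    tau_d = q_p + d_s + tc * span
    if tpl.shoulder:
        level = (1 - tpl.shoulder[0]) * tpl.amplitude
        a_q = tpl.amplitude * (1 - _CAP_DROP)
        tau_level = q_p + tc * math.log(a_q / level)
    else:
        tau_level = math.inf
    return _Geometry(q_p, v_half, foot, rise_dur, tc, dwell, tau_d, tau_level)


def _hermite(u: np.ndarray, y0: float, y1: float, s0: float, s1: float, h: float) -> np.ndarray:
    """Cubic Hermite on u in [0, 1] with endpoint slopes given per unit time."""
    return (
        (2 * u**3 - 3 * u**2 + 1) * y0
        + (u**3 - 2 * u**2 + u) * h * s0
        + (-2 * u**3 + 3 * u**2) * y1
        + (u**3 - u**2) * h * s1
    )


def _cycle_values(tpl: CycleTemplate, tau: np.ndarray, dt: float) -> np.ndarray:
    """Evaluate the clean cycle waveform at phases ``tau`` in [0, period)."""
    A, P = tpl.amplitude, tpl.period
    g = _geometry(tpl, dt)
    c_p = _CAP_DROP / g.q_p**2
    a_q = A * (1 - _CAP_DROP)
    floor = _FLOOR_FRAC * A
    cv = floor / g.v_half**2
    tau_v = g.tau_d + g.v_half          # valley minimum
    tau_dwell0 = g.tau_d + 2 * g.v_half
    tau_foot0 = tau_dwell0 + g.dwell
    tau_rise0 = tau_foot0 + g.foot      # 10% level reached here
    d_s = tpl.shoulder[1] if tpl.shoulder else 0.0
    sh_level = (1 - tpl.shoulder[0]) * A if tpl.shoulder else None

    y = np.zeros_like(tau)
    # decay-side peak cap
    m = tau <= g.q_p
    y[m] = A * (1 - c_p * tau[m] ** 2)
    # exponential decay with optional shoulder plateau
    m = (tau > g.q_p) & (tau <= g.tau_d)
    td = tau[m]
    yd = a_q * np.exp(-(td - g.q_p) / g.tc)
    if tpl.shoulder:
        on_sh = (td > g.tau_level) & (td <= g.tau_level + d_s)
        after = td > g.tau_level + d_s
        yd[on_sh] = sh_level
        yd[after] = sh_level * np.exp(-(td[after] - g.tau_level - d_s) / g.tc)
    y[m] = yd
    # valley cap (the trace minimum; quadratic so smoothing preserves it)
    m = (tau > g.tau_d) & (tau <= tau_dwell0)
    y[m] = cv * (tau[m] - tau_v) ** 2
    # inter-beat dwell above the valley
    m = (tau > tau_dwell0) & (tau <= tau_foot0)
    y[m] = floor
    # foot: smooth approach from the dwell to the 10% level
    m = (tau > tau_foot0) & (tau <= tau_rise0)
    u = (tau[m] - tau_foot0) / g.foot
    y[m] = floor + (_RISE_START_FRAC * A - floor) * (3 * u**2 - 2 * u**3)
    # main upstroke: C1 into the rise-side cap
    s_cap = 2 * A * _CAP_DROP / g.q_p
    m = (tau > tau_rise0) & (tau <= P - g.q_p)
    h = (P - g.q_p) - tau_rise0
    u = (tau[m] - tau_rise0) / h
    y[m] = _hermite(u, _RISE_START_FRAC * A, a_q, 0.0, s_cap, h)
    # rise-side peak cap
    m = tau > P - g.q_p
    y[m] = A * (1 - c_p * (P - tau[m]) ** 2)

    if tpl.subpeak is not None:
        off, rel = tpl.subpeak
        target = rel * A
        base_at = _cycle_base_value(tpl, off, dt)
        if target > base_at:
            bump = (target - base_at) * np.exp(
                -0.5 * ((tau - off) / _SUBPEAK_WIDTH) ** 2
            )
            y = y + bump
    return y


def _cycle_base_value(tpl: CycleTemplate, off: float, dt: float) -> float:
    stripped = replace(tpl, subpeak=None)
    return float(_cycle_values(stripped, np.array([off]), dt)[0])


def recovery_template() -> CycleTemplate:
    """Slow template whose breakpoints all land on the 0.1 s grid.

    With the quadratic peak and valley caps spanning the full smoothing
    window, the pipeline recovers amplitude and peak positions of noiseless
    traces exactly; used by the parameter-recovery checks.
    """
    tc = 0.7 / math.log((1 - _CAP_DROP) / _FLOOR_FRAC)
    return CycleTemplate(
        period=2.5, amplitude=200.0, rise_fraction=0.24, decay_constant=tc
    )


def _scan_annotations(
    tpl: CycleTemplate,
    times: np.ndarray,
    clean: np.ndarray,
    dt: float,
) -> TraceAnnotations:
    """Measure ground-truth parameters from the clean samples by linear scans."""
    P = tpl.period
    g = _geometry(tpl, dt)
    first_peak_t = g.rise_dur + g.foot
    duration = times.size * dt
    n_peaks = int(math.floor((duration - dt - first_peak_t) / P)) + 1
    nominal = first_peak_t + np.arange(n_peaks) * P
    idx = []
    for t_k in nominal:
        j = int(round(t_k / dt))
        lo, hi = max(j - 2, 0), min(j + 3, clean.size)
        idx.append(lo + int(np.argmax(clean[lo:hi])))
    peak_idx = np.asarray(idx, dtype=int)

    sub_idx: list[int] = []
    if tpl.subpeak is not None:
        off = tpl.subpeak[0]
        for t_k in nominal:
            j = int(round((t_k + off) / dt))
            if 0 <= j < clean.size:
                lo, hi = max(j - 2, 0), min(j + 3, clean.size)
                sub_idx.append(lo + int(np.argmax(clean[lo:hi])))

    vmin = float(clean.min())
    amplitude = float(clean[peak_idx].max()) - vmin
    rise = decay = tail = math.nan
    if len(peak_idx) >= 2:
        p0, p1 = peak_idx[0], peak_idx[1]
        seg = clean[p0:p1]
        valley = float(seg.min())
        level = valley + 0.10 * (clean[p0] - valley)
        below = np.nonzero(seg < level)[0]
        below = below[below > 0]
        if below.size:
            decay = times[p0 + below[0]] - times[p0]
            rising = p0 + below[-1]
            tail = times[rising] - times[p0 + below[0]]
            rise = times[p1] - times[rising]
    return TraceAnnotations(
        peak_indices=peak_idx,
        peak_times=times[peak_idx],
        subpeak_indices=np.asarray(sub_idx, dtype=int),
        amplitude=amplitude,
        period=P,
        frequency=n_peaks / duration,
        rise_time=float(rise),
        decay_time=float(decay),
        tail_duration=float(tail),
        peak_space=P,
        n_subpeaks_per_cycle=0 if tpl.subpeak is None else 1,
        clean_values=clean,
    )


def simulate_trace(
    template: CycleTemplate,
    duration: float = 30.0,
    dt: float = 0.1,
    noise_sigma: float = 0.0,
    seed: Optional[int] = None,
    baseline_offset: float = 0.0,
    drift: Optional[tuple[float, float]] = None,
    well_id: str = "A01",
    plate_id: str = "SIM",
    is_baseline: bool = False,
) -> tuple[Trace, TraceAnnotations]:
    """Simulate one well's trace plus its ground-truth annotations.

    The record starts at the beginning of an upstroke, so the first peak sits
    ``rise_fraction x period + dt`` into the record.  ``drift`` is an optional
    (amplitude RFU, frequency Hz) low-frequency sinusoid emulating platform
    drift; Gaussian noise is added per sample.
    """
    if duration < 3 * template.period:
        raise ValueError("duration must cover at least 3 cycles")
    n = int(round(duration / dt))
    times = np.arange(n) * dt
    g = _geometry(template, dt)
    phase = template.period - g.rise_dur - g.foot  # record starts at the foot
    tau = np.mod(times + phase, template.period)
    clean = _cycle_values(template, tau, dt)
    # ground truth is measured on the smoothed clean samples: the pipeline
    # always applies the 5-point quadratic filter, so an ideal detector sees
    # exactly these values on a noiseless trace
    smoothed_clean = savgol_filter(clean, 5, 2, mode="interp")
    ann = _scan_annotations(template, times, smoothed_clean - smoothed_clean.min(), dt)

    values = clean + baseline_offset
    if drift is not None:
        amp_d, freq_d = drift
        values = values + amp_d * np.sin(2 * math.pi * freq_d * times)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sigma, size=n)
    trace = Trace(
        times, values, well_id=well_id, plate_id=plate_id, is_baseline=is_baseline
    )
    return trace, ann


def fig_shapes_triplet() -> tuple[CycleTemplate, CycleTemplate, CycleTemplate]:
    """Three equal-period, equal-amplitude templates spanning the shoulder/tail
    morphology space:

    (i) no shoulder, short tail; (ii) no shoulder, long tail; (iii) a
    mid-decay shoulder.  Only the third exhibits a shoulder density mode, so
    its shoulder/tail ratio dominates the other two by an order of magnitude.
    """
    base = dict(period=3.0, amplitude=200.0, rise_fraction=0.2, decay_constant=None)
    slow = CycleTemplate(**base, tail_dwell=0.20)              # (i) short tail
    fast = CycleTemplate(**base, tail_dwell=1.20)              # (ii) long tail
    shoulder = CycleTemplate(
        **base, tail_dwell=0.15, shoulder=(0.5, 0.75)
    )                                                          # (iii)
    return slow, fast, shoulder


# ---------------------------------------------------------------------------
# plate designs


@dataclass
class EffectSpec:
    """Concentration effect of an active compound on the control template.

    The effect fraction follows a Hill curve
    ``e(c) = emax * c^h / (c^h + ec50^h)``; the mode decides which template
    field it perturbs.
    """

    mode: str = "amplitude_suppression"
    emax: float = 0.9
    ec50: float = 1.0
    hill: float = 1.5

    _MODES = (
        "none",
        "amplitude_suppression",
        "frequency_change",
        "shoulder_induction",
        "subpeak_induction",
    )

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"unknown effect mode {self.mode!r}")
        if not 0 <= self.emax <= 1:
            raise ValueError("emax must lie in [0, 1]")
        if self.ec50 <= 0 or self.hill <= 0:
            raise ValueError("ec50 and hill must be positive")

    def fraction(self, conc: float) -> float:
        if self.mode == "none" or conc <= 0:
            return 0.0
        ch = conc**self.hill
        return self.emax * ch / (ch + self.ec50**self.hill)

    def apply(self, template: CycleTemplate, conc: float) -> CycleTemplate:
        e = self.fraction(conc)
        if e <= 0:
            return template
        if self.mode == "amplitude_suppression":
            return replace(template, amplitude=template.amplitude * (1 - e))
        if self.mode == "frequency_change":
            # transient slowing (bradycardic), kept within the plate QC band
            return replace(template, period=template.period * (1 + 0.18 * e))
        if self.mode == "shoulder_induction":
            if 0.30 * e < 0.08:
                return template
            return replace(
                template,
                period=template.period * (1 + 0.18 * e),
                decay_constant=0.04,
                shoulder=(0.5, 0.30 * e),
            )
        if self.mode == "subpeak_induction":
            if e < 0.3:
                return template
            return replace(
                template,
                period=template.period * (1 + 0.18 * e),
                decay_constant=0.09,
                subpeak=(0.5, 0.92),
            )
        return template


@dataclass
class CompoundSpec:
    compound_id: str
    active: bool
    effect: EffectSpec
    concentrations: tuple[float, ...] = (100.0,)
    smiles: Optional[str] = None


@dataclass
class PlateDesign:
    """Layout and noise model of a simulated screening campaign."""

    compounds: list[CompoundSpec]
    n_vehicle: int = 6
    n_positive: int = 0
    replicates: int = 3
    dialect: str = "gsk"
    duration: float = 32.0
    dt: float = 0.1
    baseline_duration: float = 12.0
    noise_sigma: float = 4.0
    well_jitter: float = 0.03
    drift: Optional[tuple[float, float]] = None
    wells_per_plate: int = 96
    exposure: str = "30min"
    seed: int = 0
    control_template: CycleTemplate = field(default_factory=CycleTemplate)
    positive_suppression: float = 0.95  # verapamil-like near-total suppression

    def __post_init__(self) -> None:
        if self.n_vehicle < 2:
            raise ValueError("designs need at least 2 vehicle wells per plate")
        if self.dialect not in ("az", "gsk"):
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if self.dialect == "gsk" and self.n_positive:
            raise ValueError("gsk-dialect plates carry no positive controls")


def _well_ids(n: int) -> list[str]:
    rows = "ABCDEFGH"
    ids = [f"{r}{c:02d}" for r in rows for c in range(1, 13)]
    if n > len(ids):
        raise ValueError("more wells than a 96-well plate")
    return ids[:n]


def _jitter_template(
    tpl: CycleTemplate, rng: np.random.Generator, jitter: float
) -> CycleTemplate:
    amp = tpl.amplitude * float(rng.normal(1.0, jitter))
    per = tpl.period * float(rng.normal(1.0, jitter / 2))
    return replace(tpl, amplitude=max(amp, 1.0), period=max(per, 0.2))


def simulate_plate(design: PlateDesign) -> tuple[TraceSet, pd.DataFrame]:
    """Simulate a full labelled campaign from a plate design.

    Treated wells are chunked into as many plates as needed; every plate gets
    its own vehicle (and, for the az dialect, positive-control) wells.  The az
    dialect additionally emits linked pre-compound baseline traces drawn from
    the control distribution.  Returns the TraceSet and a tidy metadata table.
    """
    rng = np.random.default_rng(design.seed)
    smiles_pool = list(SMILES_POOL)
    rng.shuffle(smiles_pool)
    if len(design.compounds) > len(smiles_pool):
        smiles_pool = smiles_pool * (len(design.compounds) // len(smiles_pool) + 1)

    jobs = []  # (compound or None, role, concentration)
    for comp in design.compounds:
        for conc in comp.concentrations:
            for _ in range(design.replicates):
                jobs.append((comp, "treated", conc))

    n_controls = design.n_vehicle + design.n_positive
    capacity = design.wells_per_plate - n_controls
    n_plates = max(1, math.ceil(len(jobs) / capacity))

    ts = TraceSet()
    meta_rows = []
    smiles_of = {
        comp.compound_id: comp.smiles or smiles_pool[i]
        for i, comp in enumerate(design.compounds)
    }

    job_iter = iter(jobs)
    jobs_left = len(jobs)
    for p in range(n_plates):
        plate_id = f"P{p + 1:02d}"
        plate_jobs = [next(job_iter) for _ in range(min(capacity, jobs_left))]
        jobs_left -= len(plate_jobs)
        entries = (
            [(None, "vehicle", None)] * design.n_vehicle
            + [(None, "positive", None)] * design.n_positive
            + plate_jobs
        )
        wells = _well_ids(len(entries))
        for well_id, (comp, role, conc) in zip(wells, entries):
            base_tpl = _jitter_template(
                design.control_template, rng, design.well_jitter
            )
            if role == "vehicle":
                tpl = base_tpl
            elif role == "positive":
                tpl = replace(
                    base_tpl,
                    amplitude=base_tpl.amplitude * (1 - design.positive_suppression),
                )
            else:
                tpl = comp.effect.apply(base_tpl, conc) if comp.active else base_tpl
            trace, _ = simulate_trace(
                tpl,
                duration=design.duration,
                dt=design.dt,
                noise_sigma=design.noise_sigma,
                seed=int(rng.integers(0, 2**31 - 1)),
                drift=design.drift,
                well_id=well_id,
                plate_id=plate_id,
            )
            ts.traces.append(trace)
            if design.dialect == "az":
                btrace, _ = simulate_trace(
                    base_tpl,
                    duration=design.baseline_duration,
                    dt=design.dt,
                    noise_sigma=design.noise_sigma,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    well_id=well_id,
                    plate_id=plate_id,
                    is_baseline=True,
                )
                ts.traces.append(btrace)
                ts.baseline_links[(plate_id, well_id)] = btrace
            meta = SampleMeta(
                compound_id=comp.compound_id if comp else role.upper(),
                concentration=conc,
                role=role,
                plate_id=plate_id,
                well_id=well_id,
                source=design.dialect,
                exposure=design.exposure,
                smiles=smiles_of[comp.compound_id] if comp else None,
                cardiac_active=int(comp.active) if comp else None,
            )
            ts.meta[(plate_id, well_id)] = meta
            meta_rows.append(
                {
                    "compound_id": meta.compound_id,
                    "concentration": meta.concentration,
                    "role": meta.role,
                    "plate_id": meta.plate_id,
                    "well_id": meta.well_id,
                    "source": meta.source,
                    "exposure": meta.exposure,
                    "smiles": meta.smiles,
                    "cardiac_active": meta.cardiac_active,
                }
            )
    ts.validate()
    return ts, pd.DataFrame(meta_rows)


def benchmark_design(seed: int = 0, n_compounds: int = 40) -> PlateDesign:
    """The bundled separable benchmark: half active, half inactive compounds.

    Active compounds cycle through the effect modes with near-saturating
    potency at the top tested concentration, so waveform features separate the
    classes while the randomly assigned structures do not.
    """
    if n_compounds % 2:
        raise ValueError("benchmark needs an even compound count")
    modes = [
        "amplitude_suppression",
        "frequency_change",
        "shoulder_induction",
        "subpeak_induction",
    ]
    compounds = []
    half = n_compounds // 2
    for i in range(half):
        compounds.append(
            CompoundSpec(
                compound_id=f"ACT{i + 1:02d}",
                active=True,
                effect=EffectSpec(
                    mode=modes[i % len(modes)],
                    emax=0.7 if modes[i % len(modes)] == "amplitude_suppression" else 0.9,
                    ec50=2.0,
                ),
                concentrations=(10.0, 100.0),
            )
        )
    for i in range(half):
        compounds.append(
            CompoundSpec(
                compound_id=f"INA{i + 1:02d}",
                active=False,
                effect=EffectSpec(mode="none"),
                concentrations=(10.0, 100.0),
            )
        )
    return PlateDesign(compounds=compounds, replicates=3, seed=seed)
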