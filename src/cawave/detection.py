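"""Peak, subpeak, and cycle detection for calcium-transient traces.

A beating trace is segmented at its *real* peaks.  Detection proceeds in
stages:

1. every strict local maximum is found with its prominence (boundary peaks use
   one-sided prominence measured on the inner side of the record);
2. false peaks -- prominence below a fraction of the trace's maximum amplitude
   (MA = max - min) -- are discarded;
3. remaining low-prominence peaks that sit close in height to the previous
   real peak, or that are not preceded by a near-baseline tail, are annotated
   as subpeaks (double peaks); subpeaks never start cycles;
4. samples are partitioned into groups delimited by real peaks; the first and
   last groups are partial and excluded from parameter derivation;
5. each full cycle's key time points (rising point, peak, tail start, valley)
   are located from the 10%-of-amplitude level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .io import Trace

__all__ = [
    "Peak",
    "KeyPoints",
    "Cycle",
    "DetectionConfig",
    "detect_peaks",
    "filter_false_peaks",
    "flag_subpeaks",
    "segment_cycles",
    "locate_key_points",
    "detect_cycles",
]


@dataclass
class DetectionConfig:
    """Thresholds of the detection cascade.

    ``false_peak_frac`` is the primary false-peak gate (fraction of MA); if
    fewer than two peaks survive it, the filter is retried once at
    ``false_peak_frac_fallback``.  The subpeak prominence threshold is a
    fraction of the maximum prominence (MP), switching at ``ma_switch`` RFU.
    """

    false_peak_frac: float = 0.20
    false_peak_frac_fallback: float = 0.10
    subpeak_prom_frac_low_ma: float = 0.50
    subpeak_prom_frac_high_ma: float = 0.70
    ma_switch: float = 250.0
    closeness_frac: float = 0.10
    closeness_mode: str = "height"  # or "amplitude"
    tail_subpeak_frac: float = 0.25
    keypoint_level_frac: float = 0.10

    def __post_init__(self) -> None:
        for name in (
            "false_peak_frac",
            "false_peak_frac_fallback",
            "subpeak_prom_frac_low_ma",
            "subpeak_prom_frac_high_ma",
            "closeness_frac",
            "tail_subpeak_frac",
            "keypoint_level_frac",
        ):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.ma_switch <= 0:
            raise ValueError("ma_switch must be positive")
        if self.closeness_mode not in ("height", "amplitude"):
            raise ValueError("closeness_mode must be 'height' or 'amplitude'")


@dataclass
class Peak:
    index: int
    time: float
    height: float
    prominence: float
    kind: str = "real"  # real | sub_prominence | sub_tail

    @property
    def is_subpeak(self) -> bool:
        return self.kind != "real"


@dataclass
class KeyPoints:
    """Key sample indices of one cycle.

    ``rising_point`` is the rising point of the *next* cycle's upstroke: the
    last sample before the next peak still below the 10%-of-amplitude level.
    It lives in this cycle's sample group.
    """

    rising_point: Optional[int]
    peak_point: int
    tail_start: Optional[int]
    valley_point: int


@dataclass
class Cycle:
    """One peak-delimited sample group ``[start, stop)``.

    Full cycles run peak-to-peak; the leading group (before the first real
    peak) and the trailing group (from the last real peak to the record end)
    are partial and carry no measures.
    """

    start: int
    stop: int
    start_peak: Optional[Peak]
    end_peak: Optional[Peak]
    is_partial: bool = False
    subpeaks: list[Peak] = field(default_factory=list)
    key_points: Optional[KeyPoints] = None
    keypoint_failure: bool = False

    @property
    def amplitude_ok(self) -> bool:
        return self.start_peak is not None and not self.is_partial


# ---------------------------------------------------------------------------
# peak detection


def _one_sided_base(values: np.ndarray, peak: int, direction: int) -> float:
    """Minimum between ``peak`` and the nearest strictly higher ground
    (or the record edge) in the given direction."""
    h = values[peak]
    i = peak + direction
    lo = h
    while 0 <= i < values.size and values[i] <= h:
        lo = min(lo, values[i])
        i += direction
    return lo


def detect_peaks(trace: Trace) -> list[Peak]:
    """All strict local maxima with prominences.

    Interior peaks use the standard prominence (height above the higher of the
    two flanking bases).  The leftmost peak bases only on its right side and
    the rightmost only on its left side, so boundary peaks are not penalised
    by the record ends.
    """
    values = trace.values
    idx, _ = find_peaks(values)
    peaks: list[Peak] = []
    for k, p in enumerate(idx):
        left = _one_sided_base(values, int(p), -1)
        right = _one_sided_base(values, int(p), +1)
        if len(idx) > 1 and k == 0:
            base = right
        elif len(idx) > 1 and k == len(idx) - 1:
            base = left
        else:
            base = max(left, right)
        prom = float(values[p] - base)
        if prom <= 0:
            continue
        peaks.append(
            Peak(index=int(p), time=float(trace.times[p]), height=float(values[p]),
                 prominence=prom)
        )
    return peaks


def filter_false_peaks(
    peaks: list[Peak], trace: Trace, config: DetectionConfig | None = None
) -> list[Peak]:
    """Drop peaks whose prominence falls below a fraction of the trace MA.

    If fewer than two peaks survive the primary threshold, the filter is
    retried once at the fallback fraction, preserving weak but regular beats.
    """
    config = config or DetectionConfig()
    if not peaks:
        return []
    ma = float(np.ptp(trace.values))
    if ma == 0:
        return []
    kept = [p for p in peaks if p.prominence >= config.false_peak_frac * ma]
    if len(kept) < 2:
        kept = [p for p in peaks if p.prominence >= config.false_peak_frac_fallback * ma]
    return kept


def _tail_lengths(
    peaks: list[Peak], trace: Trace, config: DetectionConfig
) -> np.ndarray:
    """Near-baseline dwell (s) in the inter-peak segment *preceding* each peak.

    A real peak is preceded by the previous cycle's tail (a dwell below
    min + 10% MA); a subpeak interrupting a decay is not.  The first peak has
    no preceding peak and gets NaN (exempt from the tail rule).
    """
    values = trace.values
    dt = trace.sampling_interval
    # robust floor: a low quantile rather than the minimum, so a single noise
    # excursion cannot drag the near-baseline band below the dwell level
    floor = float(np.quantile(values, 0.05))
    level = floor + config.keypoint_level_frac * np.ptp(values)
    out = np.full(len(peaks), np.nan)
    for k in range(1, len(peaks)):
        seg = values[peaks[k - 1].index + 1 : peaks[k].index]
        out[k] = np.count_nonzero(seg < level) * dt
    return out


def flag_subpeaks(
    peaks: list[Peak], trace: Trace, config: DetectionConfig | None = None
) -> list[Peak]:
    """Annotate subpeaks (double peaks) among false-filtered peaks.

    Prominence rule: a peak below 50% of MP (MA < 250 RFU) or 70% of MP
    (MA >= 250 RFU) whose height lies within 10% of MA of the previous real
    peak's height is a subpeak.  Tail rule: a peak preceded by a near-baseline
    dwell shorter than ``tail_subpeak_frac`` of the longest such dwell in the
    trace is a subpeak.
    """
    config = config or DetectionConfig()
    if len(peaks) < 2:
        return peaks
    values = trace.values
    ma = float(np.ptp(values))
    mp = max(p.prominence for p in peaks)
    frac = (
        config.subpeak_prom_frac_low_ma
        if ma < config.ma_switch
        else config.subpeak_prom_frac_high_ma
    )
    threshold = frac * mp
    tails = _tail_lengths(peaks, trace, config)
    max_tail = np.nanmax(tails) if np.isfinite(tails).any() else 0.0

    def _local_amplitude(k: int) -> float:
        # peak height above the minimum since the preceding peak (record start
        # for the first peak): the candidate's cycle-local amplitude
        lo = peaks[k - 1].index if k > 0 else 0
        return float(peaks[k].height - values[lo : peaks[k].index + 1].min())

    last_real: Optional[Peak] = None
    last_real_amp = np.nan
    for k, p in enumerate(peaks):
        p.kind = "real"
        if last_real is not None and p.prominence < threshold:
            if config.closeness_mode == "height":
                close = abs(p.height - last_real.height) <= config.closeness_frac * ma
            else:
                close = abs(
                    _local_amplitude(k) - last_real_amp
                ) <= config.closeness_frac * ma
            if close:
                p.kind = "sub_prominence"
        if (
            p.kind == "real"
            and k > 0
            and max_tail > 0
            and tails[k] < config.tail_subpeak_frac * max_tail
        ):
            p.kind = "sub_tail"
        if p.kind == "real":
            last_real = p
            last_real_amp = _local_amplitude(k)
    return peaks


# ---------------------------------------------------------------------------
# cycle segmentation


def segment_cycles(trace: Trace, peaks: list[Peak]) -> list[Cycle]:
    """Partition samples into peak-delimited groups.

    Groups run from one real peak to the last sample before the next real
    peak; the leading and trailing groups are partial.  Subpeaks are attached
    to their containing group.  With no real peak the cycle list is empty
    (zero-frequency trace).
    """
    real = [p for p in peaks if p.kind == "real"]
    subs = [p for p in peaks if p.kind != "real"]
    n = len(trace)
    if not real:
        return []
    cycles: list[Cycle] = []
    if real[0].index > 0:
        cycles.append(Cycle(0, real[0].index, None, real[0], is_partial=True))
    for a, b in zip(real[:-1], real[1:]):
        cycles.append(Cycle(a.index, b.index, a, b))
    cycles.append(Cycle(real[-1].index, n, real[-1], None, is_partial=True))
    for sp in subs:
        for cyc in cycles:
            if cyc.start <= sp.index < cyc.stop:
                cyc.subpeaks.append(sp)
                break
    return cycles


def locate_key_points(cycle: Cycle, trace: Trace, level_frac: float = 0.10) -> KeyPoints:
    """Locate the key time points of one full cycle.

    The peak point is the cycle's starting peak, the valley the cycle's
    minimum (earliest on ties), the tail start the first sample after the peak
    below valley + ``level_frac`` x amplitude, and the rising point the last
    sample before the next peak still below that level.  A cycle where either
    threshold crossing is missing is flagged as a key-point failure.
    """
    if cycle.is_partial or cycle.start_peak is None:
        raise ValueError("key points are defined for full cycles only")
    values = trace.values
    seg = values[cycle.start : cycle.stop]
    valley_rel = int(np.argmin(seg))
    valley = cycle.start + valley_rel
    valley_val = float(seg[valley_rel])
    amplitude = float(values[cycle.start] - valley_val)
    level = valley_val + level_frac * amplitude

    below = np.nonzero(seg < level)[0]
    below = below[below > 0]  # the peak sample itself does not count
    tail_start: Optional[int] = None
    rising: Optional[int] = None
    if below.size:
        tail_start = cycle.start + int(below[0])
        rising = cycle.start + int(below[-1])
    kp = KeyPoints(
        rising_point=rising,
        peak_point=cycle.start,
        tail_start=tail_start,
        valley_point=valley,
    )
    cycle.key_points = kp
    cycle.keypoint_failure = tail_start is None or rising is None or amplitude <= 0
    return kp


def _leading_rising_point(
    trace: Trace, first_peak: int, level_frac: float
) -> Optional[int]:
    """Rising point of the first full cycle, located in the leading partial group."""
    if first_peak == 0:
        return None
    seg = trace.values[:first_peak]
    vmin = seg.min()
    level = vmin + level_frac * (trace.values[first_peak] - vmin)
    below = np.nonzero(seg < level)[0]
    return int(below[-1]) if below.size else None


def detect_cycles(
    trace: Trace, config: DetectionConfig | None = None
) -> tuple[list[Peak], list[Cycle]]:
    """Run the full detection cascade on a rescaled trace.

    Returns the annotated peak list and the cycle partition with key points
    located on every full cycle (and a rising point on the leading partial
    group, which the first full cycle's rise-time computation consumes).
    """
    config = config or DetectionConfig()
    peaks = detect_peaks(trace)
    peaks = filter_false_peaks(peaks, trace, config)
    peaks = flag_subpeaks(peaks, trace, config)
    cycles = segment_cycles(trace, peaks)
    for cyc in cycles:
        if not cyc.is_partial:
            locate_key_points(cyc, trace, config.keypoint_level_frac)
    if cycles and cycles[0].is_partial and cycles[0].start_peak is None:
        rp = _leading_rising_point(trace, cycles[0].stop, config.keypoint_level_frac)
        cycles[0].key_points = KeyPoints(
            rising_point=rp, peak_point=cycles[0].stop, tail_start=None,
            valley_point=int(np.argmin(trace.values[: cycles[0].stop])),
        )
    return peaks, cycles
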