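import math

import numpy as np
import pytest

from cawave.cycles import (
    ShoulderConfig,
    amplitude_parameters,
    density_modes,
    kde_decay_density,
    measure_cycles,
    peak_widths,
    shoulder_analysis,
    time_parameters,
)
from cawave.detection import detect_cycles
from cawave.io import Trace, rescale_trace, smooth_trace
from cawave.synthetic import CycleTemplate, fig_shapes_triplet, simulate_trace


def make_trace(values, dt=0.1):
    values = np.asarray(values, dtype=float)
    return Trace(np.arange(values.size) * dt, values)


def analyzed(trace):
    tr = rescale_trace(smooth_trace(trace))
    _, cycles = detect_cycles(tr)
    return tr, cycles


class TestTimeParameters:
    def test_recovery_times_within_one_sample(self, clean_recovery):
        trace, ann = clean_recovery
        tr, cycles = analyzed(trace)
        measures = measure_cycles(tr, cycles)
        dt = tr.sampling_interval + 1e-9
        for m in measures:
            assert abs(m.peak_space - ann.peak_space) <= dt
            assert abs(m.decay_time - ann.decay_time) <= dt
            assert abs(m.tail_duration - ann.tail_duration) <= dt
            if not math.isnan(m.rise_time):
                assert abs(m.rise_time - ann.rise_time) <= dt

    def test_time_identity_decay_tail_rise_vs_peak_space(self, clean_recovery):
        # decay + tail + next rise spans the cycle up to one sampling interval
        trace, _ = clean_recovery
        tr, cycles = analyzed(trace)
        measures = measure_cycles(tr, cycles)
        dt = tr.sampling_interval
        for prev, nxt in zip(measures[:-1], measures[1:]):
            total = prev.decay_time + prev.tail_duration + nxt.rise_time
            assert abs(total - prev.peak_space) <= dt + 1e-9

    def test_symmetric_triangle_rise_equals_decay_side(self):
        # triangle cycles: time from peak to valley equals valley to next peak
        tooth = list(np.linspace(0, 100, 6)) + list(np.linspace(100, 0, 6)[1:-1])
        tr = make_trace(tooth * 5)
        _, cycles = detect_cycles(tr)
        measures = measure_cycles(tr, cycles)
        for m in measures:
            assert m.peak_to_end == pytest.approx(m.peak_space - m.peak_to_end, abs=0.11)

    def test_tail_proportion_matches_design(self):
        # template with a long dwell: tail occupies a known share of the cycle
        tpl = CycleTemplate(period=2.5, amplitude=200.0, rise_fraction=0.24,
                            decay_constant=None, tail_dwell=0.8)
        trace, ann = simulate_trace(tpl, duration=25.0, dt=0.1)
        tr, cycles = analyzed(trace)
        measures = measure_cycles(tr, cycles)
        expected = ann.tail_duration / ann.peak_space
        for m in measures:
            assert m.tail_proportion == pytest.approx(expected, abs=0.1 / 2.5)


class TestPeakWidths:
    def test_isoceles_triangle_pw50_is_half_base(self):
        # teeth of base b = 1.2 s: at 50% prominence the width is b/2
        tooth = list(np.linspace(0, 100, 7)) + list(np.linspace(100, 0, 7)[1:-1])
        tr = make_trace(tooth * 5)
        _, cycles = detect_cycles(tr)
        full = [c for c in cycles if not c.is_partial]
        widths, clipped = peak_widths(full[1], tr, left_bound=full[0].start)
        assert widths[0.50] == pytest.approx(0.6, abs=1e-9)
        assert not clipped

    def test_monotone_in_fraction_on_generator_cycles(self, clean_recovery):
        trace, _ = clean_recovery
        tr, cycles = analyzed(trace)
        for m in measure_cycles(tr, cycles):
            assert m.pw10 <= m.pw25 <= m.pw50 <= m.pw80 <= m.pw90 <= m.peak_space

    def test_gaussian_pulse_fwhm(self):
        # Gaussian-shaped beats: PW50 = 2 sigma sqrt(2 ln 2) up to interpolation
        dt, sigma, period = 0.05, 0.3, 3.0
        t = np.arange(0, 15, dt)
        phase = np.mod(t, period) - period / 2
        values = 100 * np.exp(-0.5 * (phase / sigma) ** 2)
        tr = Trace(t, values)
        _, cycles = detect_cycles(tr)
        full = [c for c in cycles if not c.is_partial]
        expected = 2 * sigma * math.sqrt(2 * math.log(2))
        # numeric oracle on a dense grid
        td = np.arange(0, period, 1e-4)
        yd = 100 * np.exp(-0.5 * ((td - period / 2) / sigma) ** 2)
        dense = np.ptp(td[yd >= 50])
        assert dense == pytest.approx(expected, abs=1e-3)
        for i, c in enumerate(full[1:], start=1):
            widths, _ = peak_widths(c, tr, left_bound=full[i - 1].start)
            assert widths[0.50] == pytest.approx(expected, abs=2 * dt)

    def test_level_never_crossed_sets_clipped_flag(self):
        # the record starts above the crossing level: the left flank of the
        # first cycle's peak cannot be resolved and the width clips there
        v = np.concatenate([[50, 60], np.linspace(55, 5, 8), [100], np.zeros(4)])
        tr = make_trace(v)
        _, cycles = detect_cycles(tr)
        full = [c for c in cycles if not c.is_partial]
        widths, clipped = peak_widths(full[0], tr, left_bound=0)
        assert clipped


class TestAmplitudeParameters:
    def test_definition(self):
        v = np.concatenate([[30, 150], np.linspace(140, 30, 8), [150], [30] * 4])
        tr = make_trace(v)
        _, cycles = detect_cycles(tr)
        full = [c for c in cycles if not c.is_partial][0]
        intensity, valley, amplitude = amplitude_parameters(full, tr)
        assert (intensity, valley) == (150.0, 30.0)
        assert amplitude == 120.0

    def test_identity_is_exact(self, clean_recovery):
        trace, _ = clean_recovery
        tr, cycles = analyzed(trace)
        for m in measure_cycles(tr, cycles):
            assert m.amplitude == m.intensity - m.valley  # exact, no tolerance

    def test_rescaled_global_min_gives_zero_valley(self, clean_recovery):
        trace, _ = clean_recovery
        tr, cycles = analyzed(trace)
        valleys = [m.valley for m in measure_cycles(tr, cycles)]
        assert min(valleys) == 0.0


class TestShoulderAnalysis:
    def test_ratio_cap_hit_exactly(self):
        # mid-decay plateau then an instant drop with no dwell near baseline:
        # strong shoulder mode, vanishing tail density -> exactly the cap
        cycle_vals = [200.0, 198.0] + [100.0] * 12 + [2.0, 0.0, 120.0, 200.0]
        v = np.array(cycle_vals * 3)
        tr = make_trace(v)
        _, cycles = detect_cycles(tr)
        full = [c for c in cycles if not c.is_partial]
        pos, ratio = shoulder_analysis(full[0], tr)
        assert ratio == 2.5
        assert pos == pytest.approx(0.5, abs=0.05)

    def test_pure_exponential_decay_has_no_shoulder(self):
        tpl = CycleTemplate(period=3.0, amplitude=200.0, rise_fraction=0.2,
                            decay_constant=None, tail_dwell=0.2)
        trace, _ = simulate_trace(tpl, duration=30.0, dt=0.1)
        tr, cycles = analyzed(trace)
        for m in measure_cycles(tr, cycles):
            assert m.shoulder_tail_ratio == 0.0
            assert m.shoulder_position is None

    def test_fig_triplet_ordering(self):
        ratios = []
        for tpl in fig_shapes_triplet():
            trace, _ = simulate_trace(tpl, duration=30.0, dt=0.1)
            tr, cycles = analyzed(trace)
            measures = measure_cycles(tr, cycles)
            ratios.append(np.mean([m.shoulder_tail_ratio for m in measures]))
        slow, fast, shoulder = ratios
        assert shoulder >= 10 * slow
        assert shoulder >= 10 * fast

    def test_ratio_in_bounds_and_offset_scale_invariant(self):
        tpl = fig_shapes_triplet()[2]
        trace, _ = simulate_trace(tpl, duration=20.0, dt=0.1)
        tr, cycles = analyzed(trace)
        base = [(m.shoulder_position, m.shoulder_tail_ratio)
                for m in measure_cycles(tr, cycles)]
        for m in measure_cycles(tr, cycles):
            assert 0.0 <= m.shoulder_tail_ratio <= 2.5
        # vertical offset and uniform scaling leave the normalized ratio alone
        for f in (lambda v: v + 300.0, lambda v: v * 3.5):
            tr2 = Trace(tr.times, f(tr.values))
            _, cycles2 = detect_cycles(tr2)
            got = [(m.shoulder_position, m.shoulder_tail_ratio)
                   for m in measure_cycles(tr2, cycles2)]
            for (p1, r1), (p2, r2) in zip(base, got):
                assert r1 == pytest.approx(r2, abs=1e-9)
                if p1 is None:
                    assert p2 is None
                else:
                    assert p1 == pytest.approx(p2, abs=1e-9)

    def test_degenerate_decay_returns_zero(self):
        v = np.array(([200.0] + [50.0] * 10) * 3)
        tr = make_trace(v)
        _, cycles = detect_cycles(tr)
        full = [c for c in cycles if not c.is_partial]
        pos, ratio = shoulder_analysis(full[0], tr)
        assert (pos, ratio) == (None, 0.0)


class TestKDE:
    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.uniform(0, 1, int(rng.integers(5, 40)))
            grid, dens = kde_decay_density(x)
            assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_matches_statsmodels_biweight(self):
        from statsmodels.nonparametric.kde import KDEUnivariate

        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 30)
        grid, dens = kde_decay_density(x)
        kde = KDEUnivariate(x)
        kde.fit(kernel="biw", bw=0.2, fft=False)
        ref = np.empty(grid.size)
        for i, g in enumerate(grid):
            v = np.asarray(kde.evaluate(np.array([g])), float).ravel()
            ref[i] = 0.0 if v.size == 0 or np.isnan(v[0]) else v[0]
        ref /= np.trapezoid(ref, grid)
        np.testing.assert_allclose(dens, ref, atol=1e-12)

    def test_mode_detection_with_plateau_midpoint(self):
        grid = np.arange(10.0)
        dens = np.array([0, 1, 2, 3, 3, 3, 2, 1, 0, 0], dtype=float)
        modes = density_modes(grid, dens)
        assert modes == [(4.0, 3.0)]

    def test_two_separated_modes_found(self):
        x = np.array([0.3] * 8 + [0.95] * 5)
        grid, dens = kde_decay_density(x)
        modes = density_modes(grid, dens)
        locs = sorted(m[0] for m in modes)
        assert len(locs) == 2
        assert locs[0] == pytest.approx(0.3, abs=0.03)
        assert locs[1] == pytest.approx(0.95, abs=0.03)
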