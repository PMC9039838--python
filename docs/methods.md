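# Methods

## Signal model and preprocessing

A well's readout is a uniformly sampled fluorescence trace (RFU) at ~100 ms
resolution; two table dialects are supported (an 800-read/100 s layout with a
350-read pre-compound baseline, and a 600-read/65.5 s layout without one).
Preprocessing is fixed: a 5-point quadratic Savitzky–Golay filter (boundary
samples filled from the edge-window polynomial so traces keep their length),
then a per-well shift so the minimum RFU is zero. Smoothing precedes
rescaling so that the zero-minimum postcondition holds for everything
downstream. Savitzky–Golay with a quadratic basis reproduces locally
quadratic (indeed cubic) signal exactly and attenuates features narrower than
its window; at 10 samples per beat this biases sharp peaks slightly, which is
inherent to the sampling rate rather than to the implementation.

## Peak, subpeak, and cycle detection

All strict local maxima are found with prominences. Prominence follows the
standard definition (height above the higher of the two flanking bases, each
base the minimum before the nearest strictly higher ground), except that the
first and last peaks of a record use only their inner side, so boundary peaks
are not penalized by truncation. Peaks with prominence below 20% of the
trace's maximum amplitude (MA = max − min) are false peaks; if fewer than two
peaks survive, the filter retries once at 10%, preserving weak-but-regular
beats. Both fractions are configurable (`DetectionConfig`).

Two subpeak (double-peak) rules follow. *Prominence rule*: a peak whose
prominence is below 50% of the maximum prominence (MP) when MA < 250 RFU
(70% when MA ≥ 250) and whose height lies within 10% of MA of the previous
real peak's height. *Tail rule*: each wave cycle ends with a dwell near
baseline before the next upstroke, but the segment preceding a double peak
does not; a peak whose preceding near-baseline dwell (samples below the 5th
percentile of the trace + 10% of MA) is shorter than 25% of the longest such
dwell in the trace is a subpeak. The 5th-percentile floor (rather than the
minimum) keeps the band robust to single-sample noise excursions; the 25%
threshold is configurable, chosen as a large margin between full tails and
the essentially zero dwell before an injected double peak. The first peak is
exempt (its preceding group is partial). All rules use MA-, MP-, and
percentile-relative quantities, so flags are invariant to vertical offset.

Real peaks partition samples into groups: leading partial, peak-to-peak full
cycles, trailing partial; partial groups yield no parameters. Within a full
cycle the valley is the minimum (earliest on ties), the tail start is the
first sample after the peak below valley + 10% of the cycle amplitude, and
the rising point is the last sample before the next peak below that same
level (it belongs to this group but starts the next cycle's upstroke). A
cycle where these crossings cannot be located — possible only for degenerate
flat-top or two-sample cycles, since the valley itself is below the level
whenever amplitude > 0 — is flagged as a key-point failure and feeds the QC
cascade instead of the parameter table.

## Per-cycle measures

Time parameters are differences of key-point times: rise time (previous
rising point → peak), decay time (peak → tail start), peak-to-end (peak →
valley), tail duration (tail start → rising point), peak space (peak → next
peak); decay + tail + next rise equals the peak space to within one sampling
interval. Peak widths PWf are the durations above `intensity − f·amplitude`
(f ∈ {0.10, 0.25, 0.50, 0.80, 0.90}) with linear interpolation at crossings;
the left flank is searched into the preceding group, bounded by the previous
peak, and widths clip (with a flag) at unresolvable bounds. Amplitude =
intensity − valley exactly.

### Shoulder/tail density ratio

Decay-segment samples (peak through rising point) are mapped to prominence
fractions p = (intensity − y)/amplitude ∈ [0, 1]. Their density is estimated
with a biweight kernel, bandwidth 0.2 on the fraction axis, on a 256-point
grid over [−0.1, 1.1] (padded so boundary modes remain detectable) and
renormalized to unit trapezoid integral. The kernel sum is evaluated in
closed form (the biweight kernel has compact support; the implementation is
checked against statsmodels' `KDEUnivariate` to 1e-12 in the test suite).
Strict local maxima of the gridded density (plateau midpoints on ties) are
classified: a mode at p ∈ [0.15, 0.8] is a shoulder (the highest one wins if
several), a mode in (0.8, 1.0] is the tail. The ratio of shoulder to tail
mode density is capped at 2.5; the cap applies exactly when a shoulder exists
but tail density is absent or below 1e-6. No shoulder mode gives ratio 0 and
no position. The decay segment alone is used — shoulders and baseline dwell
are decay-phase features; including the upstroke would add spurious mass at
intermediate fractions. With ~10 samples per 1 Hz beat the per-cycle density
is coarse; isolated decay samples can create small spurious shoulder modes
(ratios of order 0.1–0.3 on shoulder-free beats), which is why the ratio is
interpreted relatively: the bundled template triplet (equal period and
amplitude; short-tail, long-tail, and shouldered decays) separates the
shouldered shape from the others by more than an order of magnitude.

## The 38-parameter registry

Aggregation over full cycles yields a fixed, ordered registry of 38 named
parameters: 16 value-class (frequency, counts, mean times and widths,
amplitudes, RMS of the signal), 5 ratio-class (rise/decay, tail proportion,
shoulder position, mean and max shoulder/tail), 14 deviation-class (ten
sample-SD aggregates plus mean valley, inner peak space, and the multi-peak
count/max — grouped here because their vehicle-plate level is structurally
near zero after rescaling, making division-based normalization degenerate),
and 3 binary normality flags (`zero_beat`, `has_multi_peak`,
`keypoint_failure`). The 35 non-binary parameters enter correlation analysis
and modeling. Peak frequency is real-peak count over record duration
(1/mean(peak space) would ignore partial groups); SDs use n−1 and are 0 for
single-cycle traces. A trace with no real peak (or no usable full cycle)
yields the zero-frequency convention: all non-binary slots 0, `zero_beat`
set — beat-stop wells remain representable as maximal-effect observations
even though the QC default removes them. The registry serializes to YAML and
is the single source of truth for names, classes, and analysis inclusion.

## Quality control and normalization

Per sample (reasons accumulate; never short-circuited): `zero_frequency`;
with a linked baseline, `baseline_multipeak` (any subpeak; a strict
"count > 1" reading is a config switch) and `baseline_low_MA` (< 100 RFU);
`keypoint_failure`; `frequency_outlier` (outside ±20% of the plate's
vehicle-median frequency; skipped with a warning on plates without vehicles,
and not added to zero-frequency samples, which carry the more specific
reason). Per plate: the robust coefficient of variation
RCV = 1.4826·MAD/|median| (the constant makes the MAD normal-consistent;
plain MAD/median is a config option) of the vehicle wells' peak frequency and
mean amplitude; strictly above 20% on either excludes the plate.

Normalization is plate-local: value-class parameters become
(x − vehicle mean)/vehicle median (a vehicle median within 1e-12 of zero is a
hard error naming the parameter), ratio- and deviation-class parameters are
shifted by the vehicle mean only, binary flags pass through. Vehicle
value-class parameters therefore average to exactly 0 per plate, and
shift-only classes keep their variance.

Concentrations snap to {0.01, 0.03, 0.1, 0.3, 1, 3, 10, 30, 100} µM by
nearest log10 distance, exact midpoints mapping to the higher concentration.
Modeling uses each compound's samples at 100 µM, falling back to its highest
gridded concentration; replicate multiplicity is preserved.

## Activity model

Point-biserial correlation (Pearson with 0/1 dummy coding) screens the 35
parameters against the compound activity label per concentration stratum.
Feature selection first prunes one member of each parameter pair with
|Pearson| > 0.95 (keeping the higher mean |r_pb|), then ranks survivors by
mean |r_pb| and keeps the top 25. The classifier is a scikit-learn random
forest (100 trees, Gini splits, other defaults) under leave-one-compound-out
cross-validation: all samples of one compound are held out together, and by
default feature selection is re-run inside each training fold so the held-out
compound influences neither training nor selection (a global-selection mode
reproduces selecting once on the full data). Metrics (accuracy, precision,
recall, F1 at probability 0.5; ROC AUC) are computed sample-wise and
compound-wise, the latter on per-compound mean probabilities. The
`CardiacActivityModel` / `CardiacActivityResults` pair packages this as a
fit/results interface with a text `summary()`. The baseline model uses
2,048-bit radius-2 Morgan fingerprints (ECFP4) over the same folds.
Secondary analyses: Euclidean replicate/non-replicate distance distributions
over the selected-feature space (label-pure pairs only), 2-D PCA projection
of column-centered features, and a one-sided exact binomial test of a
compound's multi-peak count against the vehicle-control background rate
(Fisher's exact test being an equally defensible, unimplemented alternative).

## Synthetic plates

The generator is phenomenological (no electrophysiological ODEs). One beat
cycle is piecewise: a quadratic cap at the peak, exponential decay (optional
shoulder plateau at a prominence fraction, optional Gaussian double-peak bump
of width 0.12 s), a quadratic valley cap at the trace minimum, a flat
inter-beat dwell at 5% of amplitude, and a smooth foot plus C1 cubic upstroke
re-entering the next peak cap. Cap widths scale with samples per cycle so
that, for slow enough beats, the 5-point filter sees a single polynomial
across the peak and valley windows and reproduces them exactly; the
grid-aligned `recovery_template()` (2.5 s period) exploits this for the
exact-recovery checks, while the plate control template beats at 0.8 Hz
(period 1.25 s, amplitude 200 RFU, 35% rise fraction, 50 ms decay constant),
matching the ~1 Hz regime of commercial hiPSC-CM batches at ~100 ms sampling,
where sub-sample bias is unavoidable and noise dominates. Ground-truth
annotations (peak/subpeak indices, amplitude, time parameters) are measured
from the smoothed clean samples by independent linear scans — exactly what an
ideal detector would see on a noiseless trace — so detector tests never
compare the pipeline against itself.

Plates draw each well's template from the control with 3% amplitude and 1.5%
period jitter, add Gaussian noise (default 4 RFU ≈ 2% of amplitude; optional
sinusoidal drift, off by default), and lay out 6 vehicle wells per plate
(plus near-flat positive controls, 95% amplitude suppression, on
baseline-carrying plates). Active compounds perturb the template through
Hill curves e(c) = emax·c^h/(c^h + EC50^h) (default EC50 2 µM, h 1.5) in one
of four modes: amplitude suppression (emax 0.7 — deep enough to dominate the
noise floor without collapsing detection into beat-stop), beat slowing
(period +18% at saturation, inside the ±20% QC frequency band), shoulder
induction (plateau at fraction 0.5, dwell up to 0.27 s, with slowed decay),
and double-peak injection (92%-of-amplitude bump mid-decay). Inactive
compounds draw from the control distribution at every concentration, and
SMILES are assigned randomly from a bundled pool, so structures carry no
activity signal by construction. The bundled benchmark uses 40 compounds
(20/20), {10, 100} µM × 3 replicates (6 wells per compound), 32 s traces.

What passing tests on these plates shows — and does not. The generator
produces regular beats with well-to-well jitter and additive noise; it does
not emulate slow baseline drift beyond a sinusoid, photobleaching,
arrhythmic beat-to-beat variability, missing wells, or instrument artifacts.
The benchmark is separable by construction, so its perfect LOCO-CV AUC
demonstrates pipeline correctness and leakage-free evaluation, not expected
performance on laboratory data.

## Numerical choices and limitations

- Ties in valley argmin break to the earliest index; density-mode plateaus
  take the midpoint; multiple shoulder modes keep the highest.
- The subpeak closeness test compares raw heights by default; a cycle-local
  amplitude comparison is a config switch.
- Degenerate inputs: flat traces give zero peaks (not an error); constant
  decay segments give ratio 0; fewer than two vehicle wells exclude a plate.
- Reported headline quantities average over seeds where they are stochastic
  (100 seeds for noisy recovery; the permutation null is the mean over 5
  label permutations, since a single 40-compound permutation AUC has a
  standard error near 0.09).
- With a fixed seed the full pipeline is bit-reproducible; all randomness
  flows through `numpy.random.default_rng` seeds derived from the run seed.
- The ±20% frequency QC band and the effect-mode magnitudes interact: a
  simulated compound that slows beating beyond the band loses its samples to
  QC, exactly as a strongly chronotropic compound would on a real plate.
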