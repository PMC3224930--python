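# Methods

This note documents the models, estimators and numerical choices in
`tonoscan`, and what the synthetic-data generator does and does not
emulate.

## Signal model and acquisition geometry

A two-axis scan is an ordered sequence of *step segments*. Each segment
is a 4 s capture (2000 samples at 500 Hz) of pressure (mmHg), ADCW
(arbitrary strain-gauge units) and contact pressure (mmHg). Positions
label the *start* of a segment (the 3.50–3.75 mm segment is stored as
3.50). X-axis steps are 0.25 mm, Z-axis steps 0.125 mm; these are
structural invariants of the `ScanRecording` container, checked on
construction and on file read. The HDF5 container is written with
object-time tracking disabled so that identical recordings produce
byte-identical files; the CSV dialect stores floats by `repr` and is
read back with round-trip float parsing, so both dialects are lossless.

## Beat segmentation

Pulse cycles are delimited by systolic upstroke onsets on the pressure
channel. The first difference of the signal is smoothed with a 25 ms
moving average — matching the 40 Hz upper edge of the analog
acquisition band, so broadband sensor noise cannot outrun the systolic
slope — and onsets are maxima of the smoothed derivative above an
adaptive threshold (0.5 × its 99th percentile; genuine upstrokes occupy
only a few percent of samples, so this percentile tracks the systolic
slope) with a 0.33 s refractory period. Three guards make the
segmentation conservative:

* onsets within twice the smoothing window of a capture edge are
  discarded (a truncated upstroke cannot be anchored, so the adjoining
  cycle is treated as partial);
* onset spacing must be regular (coefficient of variation ≤ 0.25) and
  the signal must actually repeat at the median onset interval
  (lagged autocorrelation ≥ 0.3), otherwise no beats are returned —
  this rejects flat and noise-only captures;
* with three or more candidate cycles, cycles whose length deviates
  from the median by more than 15 % are dropped (they arise when a
  noise-boosted dicrotic rise crosses the threshold).

Cycle lengths are restricted to 0.33–2.0 s (30–180 BPM). The ADCW
channel is never segmented independently: the pressure-channel beat
windows are applied to it directly, because the two channels come from
the same sensor and the ADCW may be near-zero off-artery. A segment
with no detectable beats keeps its row in all tables with an invalid
flag; it is excluded from fits and cohort statistics, never fabricated.

The peak-to-peak amplitude of a step is the mean over complete beats of
(max − min) within the cycle. Under additive noise of SD σ this
estimator carries a small positive extreme-value bias (≈ 3–4 σ); at the
generator's default 1 % waveform noise the bias is ≈ 0.04 % of the
amplitude and is ignored.

## Template matching

The sliding correlation of a reference cycle *x* (length *N*) against a
signal *y* computes, at every lag *k*, the Pearson correlation between
*x* and `y[k:k+N]`; the implementation is a vectorised windowed Pearson
statistic and is verified in the tests against a literal per-lag loop to
1e-12. Windows with zero variance are scored 0 and flagged — never NaN —
so profiles stay total. Scores are clipped to [−1, 1]; values within
1e-12 of ±1 are snapped to exactly ±1, because a window that is an exact
(anti-)copy of the template can miss unit magnitude by a few ulp through
the rounding of `sqrt(Σx²)·sqrt(Σw²)`.

The per-segment template correlation coefficient reduces the lag curve
to one number. The default reduction is the **maximum of r_xy over the
segment's complete-beat span** (lags from the first onset to the last
offset): the reference segment contains its own template, so it scores
exactly 1, which is what makes the cohort tables' relative-position-0
row exactly 1.00 ± 0.00 rather than approximately so. An alternative
reduction (`reduction="mean"`: the mean over beats of each beat's own
maximum) is provided; it uses every cycle but cannot score exactly 1 on
noisy data and is not the default. No reduction of this family can
reach −1 on a detectable periodic signal — shifted windows always raise
the maximum above the anti-phase value — so perfect anti-correlation is
a property of the lag curve (every window of an anti-affine signal
scores −1), not of the per-segment score.

Within the chosen reference segment, the "optimal" cycle is the beat
with the highest mean pairwise correlation to the other beats of that
segment (compared over their common leading length). This is an
objective, reproducible proxy for picking the most complete and
representative cycle. In X scans the reference segment is the one whose
interval contains the fitted arterial middle X0; in Z scans it is the
segment with maximal pressure amplitude, ties resolving to the earlier
(lower-pressure) step.

## Gaussian envelope and width estimation

The per-step ADCW amplitudes are fitted with
`ADCW(X) = ADCW_max · exp(−(X−X0)²/(2σ²))` by nonlinear least squares
(`scipy.optimize.curve_fit`), started from moment estimates
(amplitude-weighted mean and SD of the positions) with σ bounded below
by the grid spacing and above by ten times the scanned span. The fit
quality R is the Pearson correlation between fitted and observed
amplitudes, clipped to [0, 1]. Parameter standard errors come from the
fit covariance. At least 4 valid points with non-constant, positive
amplitude are required.

The arterial width is `(2 + Width_Index) · σ` with Width_Index 0.355 by
default. The factor is configurable: the coefficient 2.355 is
numerically indistinguishable from the Gaussian FWHM coefficient 2.3548,
and the published worked value (σ = 1.834 → width printed as 4.34 mm,
formula gives 4.319 mm) is reproduced only to printed rounding, so an
alternative definition can be swapped in without touching the pipeline.

Boundary segments snap **inward** (left boundary up, right boundary
down) to the nearest segment start, so the chosen segments lie within
the estimated artery; an ideal boundary already on a segment start stays
put, and a boundary outside the scanned range is clamped to the end
segment with a warning flag. Inward snapping moves a boundary by less
than one full step. If the artery is narrower than two motor steps the
segments flanking X0 are used so left < right always holds.

## Pipelines and cohort aggregation

`XScanModel.fit()` chains features → envelope fit → reference at X0 →
correlation profile → boundary snapping → boundary correlations, and
retains every intermediate on the result object. An envelope-fit
failure yields a partial result carrying the features and the error
string. `ZScanModel.fit()` chains features → maximum-amplitude
reference → profile → criterion contact pressure (the mean
contact-pressure of the reference segment) → excess-pressure table. Per
excess level Δ the segment whose mean contact pressure is closest to
(criterion + Δ) is selected, ties resolving to the lower-pressure
segment (less tissue deformation); a level is unavailable when the
target lies beyond the scanned pressure range by more than half the
median step-to-step pressure increment.

Cohort aggregation re-indexes each subject's profile so the alignment
anchor (reference segment, or an X-scan boundary segment) is at 0 mm;
relative positions are computed as integer multiples of the axis step —
no interpolation ever occurs. Per position the table reports n, mean
and sample SD (ddof = 1; 0 when n = 1) over the subjects covering that
position, so n shrinks toward the ragged scan edges. Subjects whose
analysis failed, or who lack the anchor, are excluded with a log entry.
The "before vs after base" summary pools the per-segment correlations
strictly below vs strictly above the base segment of each Z scan.
Sub-cohort views (e.g. hypertensive subjects) use a metadata filter; no
group-difference statistics are computed.

## Synthetic-data generator

The generator is the package's ground-truth source and defines the
study conditions:

* **Pulse morphology**: a sum of three Gaussian lobes on the unit cycle
  phase (systolic peak, reflected wave, dicrotic component). The
  distortion operator morphs the shape linearly toward a single broad
  hump (notch suppression + peak broadening); the correlation with the
  undistorted cycle is strictly decreasing in the distortion parameter,
  and the peak-to-peak amplitude is renormalised after morphing so the
  requested amplitude is exact.
* **X scan**: ADCW amplitude follows the Gaussian envelope of the
  subject's (X0, σ); the pressure amplitude follows a scaled copy of
  the envelope over a 30 % floor (the pulse stays detectable
  off-artery); distortion grows at 0.08 per mm of lateral offset;
  contact pressure is held at 80 mmHg with small jitter. 33 steps span
  0–8 mm.
* **Z scan**: mean contact pressure rises ~15 mmHg per step from
  `max(15, P_opt − 120)` mmHg; pulse amplitude is a Gaussian bell of
  contact pressure centred on the subject's P_opt (SD `amp_width`,
  default 60 mmHg) over an 8 % floor — near-occlusion and
  barely-touching contact both almost erase the pulse; distortion grows
  at 0.002 per mmHg of excess pressure above P_opt and at one fifth of
  that rate below it, which reproduces the observed asymmetry (lower
  contact pressure degrades the waveform less than excess pressure).
  24 steps.
* **Cohort**: subject parameters are drawn from clipped normal
  distributions matching the study population — arterial width
  3.64 ± 0.83 mm (σ = width / 2.355), optimal contact pressure
  161 ± 69 mmHg, SBP 140 ± 21 / DBP 84 ± 16 mmHg (MAP derived as
  DBP + PP/3), heart rate 72 ± 10 BPM, age 51 ± 11 years. Per-step
  amplitudes carry 2 % multiplicative noise; waveforms carry 1 %
  additive noise. Seeding uses `numpy.random.SeedSequence` spawning, so
  a cohort is fully determined by one integer seed and subjects are
  independent.

What the generator does **not** emulate: heart-rate variability and
ectopy, respiration and baseline wander, sensor drift and hysteresis,
the biomechanics of the artery–tissue–sensor contact, and any
quantitative distortion-vs-pressure law — the distortion rates are
chosen to reproduce orderings (fidelity falls with lateral offset and
with excess pressure), not published cohort correlation values. Tests
passing on this generator therefore demonstrate the correctness of the
estimators and the pipeline bookkeeping under the assumed structure,
not clinical performance on real recordings.

## Problem sizes and tolerances

The default test and acceptance runs use 42-subject cohorts with
full-size captures (2000 samples × 33 + 24 steps per subject), 200
seeded X-scan recoveries and 50 Z-scan recoveries; a full cohort
analysis takes a few seconds on one CPU. Envelope recovery under the
default 2 % amplitude noise achieves median |X̂0 − X0| well below
0.05 mm and median relative σ error below 5 %. Z-scan recovery of the
optimal contact pressure is asserted to land within one motor step of
the truth-closest segment in at least 95 % of seeds: subjects with a
very flat amplitude bell (large `amp_width`) can tie two adjacent
segments to within the amplitude noise, so occasional one-step (and,
rarely, two-step) selections are inherent to the conditions rather than
estimator error.

## Known limitations

* Beat detection assumes a dominant systolic upstroke; heavily
  distorted cycles (distortion near 1) can occasionally drop a cycle at
  a capture edge. The per-segment score is insensitive to this because
  it maximises over the remaining complete-beat span.
* The Width_Index relation is an empirical calibration; σ itself is the
  robust quantity, and the width (hence the boundary segments) inherits
  the calibration's uncertainty.
* The Pearson-based fit quality R is blind to heteroscedastic amplitude
  noise; it is reported because it is the conventional summary for this
  analysis, not because it is optimal.
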