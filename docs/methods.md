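# Methods

## The estimation model

A pulse waveform beat is delineated trough-to-trough and indexed by its
systolic peak. Two intra-beat features drive the estimator:

* **DTT(i)** — diastolic transit time, the interval from the systolic peak to
  the diastolic trough that terminates the beat;
* **C(i)** — contractility, the maximum of the first derivative of the
  systolic upstroke (onset trough to peak).

Both are timing/slope features of a single beat, so an additive offset that
is slowly varying on the beat timescale (baseline wander) leaves them
unchanged; this invariance is the foundation of the whole method and is
verified by a dedicated test.

Given one cuff reading SBP₀/DBP₀ (PP₀ = SBP₀ − DBP₀), the calibration factor

    m₀ = (1/5) Σ_{i=1..5} (PP₀/PPₛ(i)) · (SBPₛ(i) − DBPₛ(i+1)) / DTT(i)

is the cuff-scaled mean rate at which pressure falls from systole to the next
diastole. `DBPₛ(i+1)` is realized as the end trough of beat *i*: the trough
following peak *i* is simultaneously the last fiducial of beat *i* and the
onset of beat *i+1*, so the two possible readings of the subscript are the
same number; this implementation stores it per beat as `end_v`. Estimated
diastolic pressure is

    eDBP(i) = SBP₀ − m₀ · DTT(i) · (C(i)/C₀)⁻¹ ,

with C₀ the mean contractility of the calibration beats. The contractility
ratio adjusts for inotropic changes that shorten or lengthen relaxation at
fixed pressure. The ratio is computed per beat from the raw (unsmoothed)
contractility and clamped to [0.25, 4] so that derivative noise cannot
leverage eDBP arbitrarily; clamping events are counted on the calibration
state.

**Unit anchoring.** The raw→pressure map is affine: gain = PP₀ / mean(PPₛ)
over the calibration beats, offset chosen so the mean calibration end trough
maps to DBP₀. This choice closes the calibration loop exactly: on a
stationary drift-free recording the mean eDBP of the calibration beats
equals DBP₀ to float precision (tested at 10⁻⁶ mmHg).

**Baseline-wander correction.** Per beat, raw offset = (cuff-anchored raw
diastolic value) − eDBP. The offset series is smoothed with a 30-point
moving median (centered, shrinking at the edges; for even windows the extra
point lies to the right), linearly interpolated between beat anchor times
(step interpolation would put discontinuities inside beats), and subtracted
from the pressure-scaled signal. Corrected SBP/DBP are re-read from the
corrected waveform per beat; MAP = DBP + (SBP − DBP)/3; HR = 60/(trough-to-
trough span). Beats whose SBP or DBP deviates from its own 30-point moving
median by more than 10 mmHg are marked excluded — the median filter is the
stated outlier mechanism, the 10 mmHg threshold is this package's choice
(about twice the pooled residual SD observed in validation, small enough to
catch artifact transients, large enough to pass genuine swings).

## Beat delineation

Candidate systolic peaks are prominent maxima of a lightly bandpassed
(0.5–10 Hz Butterworth, zero-phase) copy of the signal — used only for
localization, so wander cannot defeat the prominence threshold — then
refined to the raw-signal argmax within ±100 ms (earliest sample wins on
ties). End troughs are raw-signal minima between consecutive peaks; the
dicrotic notch is the most prominent local minimum of the smoothed first
derivative between peak and end trough, reported as absent when none exists.
Derivatives use central differences after a ~25 ms moving average: raw
differences amplify sensor noise, and 25 ms is short relative to the
~100 ms systolic upstroke so the attenuation of the true maximum slope is
below 1% (tested against a dense finite-difference oracle at 2%). No
sub-sample refinement is attempted: at fs ≥ 100 Hz the fiducial resolution
of ≤ 10 ms is already an order of magnitude below typical DTT values, and
the 10 ms tolerance is asserted in tests.

## Quality control

1. **Continuity rule** — only beats inside a maximal run of valid,
   temporally contiguous beats spanning ≥ 30 s are retained; shorter
   fragments are dropped entirely.
2. **Applanation-deviation detection** — contact-pressure drift of a
   tonometric sensor rescales its waveform amplitude, hence its
   contractility trend, without a counterpart on a simultaneous reference
   channel. In 30-s windows sliding by 5 s (the step is this package's
   choice; smaller steps exclude less data at more computation), each
   channel's contractility is normalized by its own window mean — making the
   test invariant to static channel gain — and regressed on time. Slopes are
   compared by a pooled-variance t-test on the slope difference (the ANCOVA
   interaction test); the window is flagged at p < 0.05 and its beats are
   excluded. "Change in normalized contractility" is realized as the level
   of the normalized series regressed on time, not first differences —
   differencing destroys the slope information the comparison needs. The
   test is intrinsically pairwise; in single-sensor runs the pipeline
   reports the stage as skipped rather than inventing a one-channel variant.
   Under a shared trend with independent noise the empirical flag rate
   matches the nominal α (Monte-Carlo tested within ±2 SE over 200 windows).

## The pulse simulator

The simulator is the validation instrument: it produces recordings whose
per-beat SBP/DBP/MAP/HR are known exactly, with the corruption mechanisms
the estimator claims to survive.

* **Beat morphology.** Each beat spans two upstroke onsets. A piecewise-
  linear diastolic baseline decays from the onset value to a strict
  V-shaped minimum (the trough) and then rises by 10% of the reference
  pulse pressure into the next onset; two Gaussian lobes (systolic and
  dicrotic), minus their node interpolant and feathered to zero around the
  trough, are superimposed and scaled so the realized peak equals the true
  SBP. The V-kink matters: the detected trough position must be stable
  under wander, which a flat diastolic tail cannot provide. Lobe widths are
  fractions of the *nominal* beat period, not each beat's own length —
  systolic ejection time does not stretch with the diastolic pause, so
  inter-beat jitter leaves the contractility of otherwise-equal beats
  unchanged.
* **Ground-truth coupling.** The trough is placed at
  DTT = (SBP_anchor − DBP_end)/m_sim · (PP/PP_ref), with m_sim fixed by the
  initial pulse pressure and a baseline DTT fraction (0.55 of the nominal
  beat period). This makes the synthetic physiology satisfy the estimation
  model's own assumption by construction. That is deliberate, and it
  delimits what the validation shows: the tests demonstrate that the
  *pipeline machinery* — delineation, calibration, unit anchoring, wander
  estimation and subtraction, outlier exclusion — recovers the truth under
  heavy wander, artifacts, jitter and noise when the physiological premise
  holds. They cannot, and do not claim to, validate the premise itself
  (that DTT tracks DBP in humans); that is an empirical clinical question.
* **Hemodynamics.** SBP/DBP/HR follow constant/ramp/step/sinusoid
  trajectories plus an AR(1) per-beat fluctuation (SD 2 mmHg, lag-1
  correlation 0.8) and a respiratory oscillation (1.5 mmHg at 0.25 Hz) —
  realistic short-term BP variability, which also gives the variability
  metrics something genuine to measure. Inter-beat intervals get Gaussian
  jitter (SD 20 ms).
* **Noise.** Baseline wander is a Gaussian random walk updated every
  1/(2·f_corner) seconds (default corner 0.2 Hz), smoothly interpolated and
  rescaled so the realized trace SD equals the requested amplitude (default
  5 sensor units ≈ 11% of pulse amplitude, a decent-quality recording); a
  sum-of-sinusoids model is available. The spectrum of real capacitive-sensor
  wander is not well characterized in the literature, so these are stated
  model assumptions, with the spectral concentration below the corner
  verified by periodogram. Motion artifacts are raised-cosine impulses, persistent
  steps, and additive sinusoidal bursts. The sensor applies gain/offset and
  white Gaussian noise (default SD 0.1 unit).
* **Determinism.** All randomness flows from one integer seed through
  per-stage child seeds; identical configs give bit-identical recordings.

## Comparator methods

* **Bandpass (BF):** 4th-order Chebyshev-II, applied forward–backward so BP
  timing is not shifted. The stated 0.5/10 Hz cutoffs are treated as
  passband corners; the Chebyshev-II stopband edges (where the 40 dB
  attenuation is reached — the attenuation value is this package's choice)
  are placed one octave outside. Designing with stopband edges *at*
  0.5/10 Hz would attenuate a 1 Hz pulse fundamental by ~19% after
  zero-phase application, which no practitioner would accept as a
  "0.5–10 Hz bandpass". Note Chebyshev-II places no transfer zero at DC, so
  a constant input is suppressed to the squared ripple floor (~10⁻⁴), not
  to machine zero.
* **DWT:** db4 wavelet, symmetric padding, decomposition to level 7; the
  approximation band (below fs/2⁸ ≈ 0.49 Hz at 250 Hz) is multiplied by a
  reduction factor, default 0 (removal). Factor 1 reconstructs the input to
  < 10⁻⁸ relative error.
* **STT:** slope transit time PPₛ/C — the time the upstroke would need to
  traverse the pulse amplitude at maximum slope. It is mapped to BP with
  exactly the DTT engine's single-point calibration (STT substituted for
  DTT; SBP rebuilt from the cuff-anchored pulse amplitude), an interpretive
  choice that isolates the timing feature as the only difference between
  the two methods.
* BF/DWT signals are affine-rescaled by the same cuff anchoring as the DTT
  path before peaks/troughs are read, so all four methods share identical
  calibration information.

Both filters remove energy below ~0.5 Hz — which is where sustained
hemodynamic trends live. On recordings with a pressure ramp they track the
waveform but not the trend, which is precisely the failure mode the DTT
comparison study quantifies.

## Variability and agreement

SD (sample, n−1), COV = SD/mean (reported as a fraction), and ARV (mean
absolute successive difference) are computed per series (SBP and DBP
separately) over non-overlapping, complete 30-beat windows of non-excluded
beats; windows whose range exceeds 10 mmHg are flagged labile and omitted
from recording-level means (the labile rule is applied per series — the
ambiguity of which series the threshold refers to is resolved as "each
judges its own"). Windows are non-overlapping because an overlap
specification is not part of the method's definition and overlapping
windows would correlate the summary statistics.

Agreement: beats are paired nearest-in-time within 0.5 s (half the
one-second device-synchronization precision, avoiding cross-beat matches
above 60 bpm); differences are estimate − reference (swapping inputs
negates the bias and nothing else); limits of agreement are reported at
1 SD (68%) and 1.96 SD (95%); the AAMI/ISO 81060-2 rule is
|mean bias| ≤ 5 mmHg and SD < 8 mmHg. The Brown–Forsythe test is Levene's
test with median centering (scipy); two all-equal groups are reported as
not different with p = 1.

## Validation studies and problem sizes

`dttbp.studies` defines the standard experiments; `tests/test_acceptance.py`
asserts their bounds and `scripts/acceptance.py` re-runs the first from
scratch.

* **Accuracy stress test:** 20 recordings × 20 min at 250 Hz (~23,000 paired
  beats), HR drawn from 55–90 bpm, ramps (+12%/+11% of baseline SBP/DBP over
  3–5 min) and opposite-sign steps (−10%/−9.5%), random-walk wander with SD
  equal to the pulse pressure, one calibration. Pooled |bias| ≲ 0.7 mmHg and
  difference SD ≈ 4–5 mmHg across seeds, against bounds of 5 and 8. The
  residual SD is dominated by the wander's within-window fluctuation that a
  30-beat median cannot follow (a random walk's variance over 30 s is ~2.5%
  of its 20-min variance; at wander SD = pulse amplitude that leaves a few
  mmHg), plus ~1 mmHg of calibration sampling noise from estimating m₀ on
  five fluctuating beats.
* **Comparator study:** 20 replicates of a 5-min recording with a +20 mmHg
  ramp over 2 min on both pressures plus default wander; mean percent errors
  of DTT vs BF/DWT (SBP and DBP) and vs STT (DBP), required lower in ≥ 18 of
  20.
* **BPV preservation:** 20 stationary-default 20-min recordings; per
  recording and series, Brown–Forsythe on 30-beat window SDs
  (corrected vs truth) with rejection rate required ≤ 2α, and mean window-SD
  difference required < 0.2 mmHg. Measured ΔSD ≈ +0.08 mmHg — the wander
  residual adds a small variance on top of the genuine ~2 mmHg per-window
  variability. This study deliberately uses the generator-default wander
  (11% of pulse amplitude): under the stress-test wander (100% of pulse
  amplitude) the 30-beat-median correction mathematically must leave a
  multi-mmHg residual in every window, so variability preservation is a
  property of ordinary recordings, not of the worst case.
* **Step-artifact recovery:** a persistent step of twice the pulse
  amplitude; corrected DBP must return within 5 mmHg of truth within 30
  beats (the median filter's catch-up horizon is 15 beats).

These problem sizes keep the full suite under a minute of compute while
leaving thousands of beats per pooled estimate.

## Degenerate inputs and numerical choices

Constant signals yield an empty beat table with a warning; recordings
shorter than 2 s, non-finite samples, non-monotonic or jittery timestamps
(> 0.1/fs) and NaN runs longer than 1 s are rejected; NaN runs ≤ 1 s are
interpolated with a warning. Fewer than five valid calibration beats, a
calibration beat with non-positive DTT or pulse amplitude, and cuff readings
with SBP₀ ≤ DBP₀ are rejected. Beats with non-positive contractility get
NaN eDBP and are excluded. Empty BP series and sub-window BPV inputs return
empty reports with warnings rather than raising. Ties in peak height resolve
to the earliest sample. The moving median uses shrinking edge windows so the
output length always equals the input length.

## Known limitations

* The simulator's DTT–DBP coupling builds the estimator's premise into the
  data (see above); real-world accuracy depends on that premise holding.
* Single-sensor runs cannot evaluate the applanation QC test.
* WFDB input is not supported; recordings travel as CSV.
* The estimator's SBP is read from the corrected waveform, so SBP accuracy
  is bounded by the wander correction, not by an independent systolic model.
* Recalibration is not automatic: one cuff reading anchors the whole
  recording (mirroring the single-calibration design), and slow gain drift
  between cuff readings is only caught by the QC stage, not corrected.
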