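# Methods

This note documents the models, conventions and numerical choices behind
`oculopulse`, in the order data flows through the package.

## 1. The measurement model

One air-puff measurement consists of (a) a Scheimpflug frame stack
(I = 140 frames, M × N = 200 × 576 px, Δt = 231 µs, ≈20 µm/px), (b) a finger
pulse-oximeter (PPG) trace with the tonometer trigger time recorded inside
it, and (c) the device's own IOP reading. The analysis assumes the ocular
pulse modulates IOP as a single cosine of cardiac phase θ:

    IOP(θ) = b + a·cos(θ − θ_peak) + ε,   ε ~ N(0, σ²)

— the simplest law consistent with a dominant first harmonic of the ocular
pulse. All higher harmonics, respiratory modulation and autoregulation are
deliberately out of model.

### Phase conventions

Cardiac phase is 0° at the systolic peak of the finger PPG and grows linearly
to 360° at the next peak (interpolation between the *bracketing* peaks, so
beat-rate jitter does not accumulate). The phase at trigger is binned to the
12 × 30° grid (nearest bin; exact midpoints round down), giving feature w6.
The origin choice is a pure convention: any other fixed origin translates the
recovered shift by a constant, which the scan estimates anyway.

### The scan and the shift/peak relation

The coupling is quantified by correlating a feature against the *wrapped
linear* shifted phase s(φ) = (w6 + φ) mod 360 over a 10° shift grid. For a
cosine-modulated feature and quasi-uniform phases this objective is, in the
continuous limit, proportional to −sin(θ_peak + φ): the scan's maximum falls
at

    φ_max = (270° − θ_peak) mod 360,

*not* at θ_peak itself. The package therefore distinguishes the cosine-peak
phase (`SyntheticTruth.phase_offset_deg`) from the optimum shift the scan
recovers; `shift_to_peak_phase` / `peak_phase_to_shift` convert between them,
and the cohort generator is parameterized directly by the group optimum shift
(default 60°, spread 40°) so that recovery tests compare like with like.

A circular-aware alternative mode (correlate against cos of the shifted
phase) is available (`circular=True`) but off by default: the linear mode is
what produces the characteristic min = −max structure 180° apart seen in the
reference extrema table.

### Plateaus and the extremum estimator

r(φ) only changes when some shifted phase wraps past 360°, so it is piecewise
constant. With 30°-binned phases the wrap events coincide with grid points
and plateaus are typically 30–60° wide. The reported extremum shift is the
midpoint of the continuous plateau interval [first grid shift, last grid
shift + step): Monte Carlo on synthetic cohorts shows this is the unbiased
location estimate (taking the smallest qualifying shift instead biases the
recovered lag by roughly half a plateau, ≈ −30° under default conditions).
Among distinct plateaus tying at the extremum, the one starting at the
smallest shift wins.

A related caveat: the identity r(φ+180°) = −r(φ) for uniformly spaced phases
holds exactly for first-harmonic features (any a·cosθ + b·sinθ + c) but *not*
for arbitrary feature vectors — counterexamples are easy to generate. The
property tests assert it on the sinusoidal class, which is the generative
class the analysis assumes.

### Rejection, pooling, significance

Subjects whose scan maximum |r| stays below a threshold are rejected before
pooling: preset `thick` (0.3) drops only grossly aberrant subjects, `strict`
(0.55) additionally drops weak couplings. Feature tables use the sample
(N−1) std; the pooled max-correlation summary uses the population (N) std by
default — the two conventions the reference tables mix — and both are always
carried in the results. Significance is two-sided Student's t with K−2
degrees of freedom; only the IOP–phase coupling (w5 vs w6) is asserted
significant, correlations for w1–w4 are reported without a claim.

## 2. Imaging chain

* **Median filter**: 3 × 3, edge replication — sized to the ≤4 px artefacts
  such sequences show.
* **Edge detection**: Canny with hysteresis thresholds expressed as fractions
  of the per-frame gradient-magnitude maximum (defaults 0.1/0.3, σ = 1.4 px),
  making the detector exposure-invariant. Per column, the uppermost
  dark→bright transition is the anterior surface; sub-pixel refinement by
  parabolic interpolation of the gradient peak. Row 0 is the top of the
  image; displacements into the eye count positive.
* **Continuity guards**: detected points deviating >4 px from the rolling
  column-median (interior columns, full 31-column windows only) or >5 px from
  the previous frame's completed contour are invalidated. Inter-frame corneal
  motion is bounded well below 5 px, so the temporal guard only removes
  detector glitches (an occasional noise ridge that survives hysteresis can
  otherwise displace a block of border columns by >100 px for one frame and
  corrupt the whole-eye-motion estimate).
* **Completion**: least-squares 5th-degree polynomial over the detected
  columns (a degree consistent with anthropometric corneal curvature) fills
  invalid spans; ≥12 valid columns spanning at least half the window are
  required, otherwise the frame is rejected. Completion is idempotent.
* **Decomposition**: frame 0 (pre-puff) is the resting shape. The whole-eye
  displacement of frame i is the mean contour displacement over the outermost
  10 % of columns per side — the air puff indents the centre while the
  periphery tracks the rigid retraction of the globe. The corneal reaction is
  the remainder, in mm. The whole-eye term is a per-frame scalar; a
  column-resolved alternative was considered and rejected as
  under-constrained at this noise level.

## 3. Feature extraction

* **Flatness / applanation**: the central region (default 150 columns ≈ 3 mm
  around the deformation apex) is fitted with a quadratic; flatness is the
  RMS deviation of that fit from its own best straight line, i.e.
  |a₂|·rms(x²−line). Using the quadratic fit rather than the raw point-wise
  RMS removes the contour-noise floor, which would otherwise sit at the
  5 µm default threshold. The signed curvature series is low-pass filtered
  (moving average, default 2.5 ms ≈ one vibration period) and each
  applanation time is the midpoint of a below-threshold episode (first
  episode → w1, last → w2), with entry/exit located by linear interpolation.
  The midpoint convention is unbiased for the locally symmetric V-shaped
  flatness curve, whereas first-crossing/last-crossing conventions are biased
  outward by threshold/slope (≈0.3 ms at default geometry).
* **Peak deformation (w3)**: moving-average filtered apex series, discrete
  maximum, parabolic vertex refinement, plus the exact correction
  a₂·var(window) for the attenuation a moving average inflicts on a locally
  quadratic peak — a clean parabola is recovered exactly.
* **Vibration frequency (w4)**: the slow deformation is removed by
  subtracting a best-fit line and the 2.5 ms moving average (a high-pass
  whose passband comfortably contains >100 Hz; a low-order polynomial
  detrend was tried first and leaves broadband leakage from the
  compact-support deformation bump that can swamp the tone). The residual is
  Hann-windowed, zero-padded ≥4×, and the strongest local spectral peak above
  100 Hz is refined by parabolic log-magnitude interpolation. Detection
  requires the peak to exceed 15× the median magnitude in a 65–150 Hz annulus
  around it (outside the windowing main lobe): a genuine line stands on a
  quiet background, while any local maximum of the bump continuum sits at the
  level of its surroundings (measured separation: ≥49× for a 10 µm tone
  vs ≤8× for no tone).
* w5 is always the device reading, never image-derived; w6 comes from the
  pulse module.

## 4. Synthetic data generator

The generator emulates the study conditions and is the ground-truth oracle
for every stage.

* **Pulse traces**: two-harmonic beat shape cosθ + 0.25·cos2θ +
  0.18·(sin2θ − 2sinθ) — fast systolic upstroke, slow decay, derivative zero
  (and global maximum) exactly at phase 0. Defaults: 84 beats/min, 4 %
  per-beat period jitter (uniform ±½·jitter, so successive periods differ by
  at most the jitter fraction), 250 Hz sampling, amplitudes in [15, 85] %.
  Only the phase, not the morphology, enters the analysis. The emulated
  oximeter's 1 % amplitude quantization is available (`quantize_pct`) but off
  by default — quantized flat-topped peaks defeat sub-sample peak refinement
  and the ±1° trigger-phase placement contract.
* **Rendering**: parabolic resting cornea (R = 7.8 mm, apex at row 40),
  bright band of 550 µm thickness over dark background, sigmoid edge profile
  (0.7 px), optional Gaussian blur (0.8 px) and additive pixel noise
  (default sd 3 of 255). The indentation is a quartic bell (half-width 3 mm)
  whose apex follows a raised-cosine rise–peak–recovery profile; the profile
  is solved so the central region passes through zero curvature — measured
  with the same flatness helper the extractor uses — exactly at the requested
  applanation times. Whole-eye retraction ramps up (smoothstep) after the
  deformation peak; a Hann-windowed sinusoid at the vibration frequency rides
  on the apex. A zero-deformation truth renders a static scene. Geometry that
  would leave the frame is rejected before rendering.
* **Cohorts**: per subject, a baseline IOP ~ N(11.9, 2.4) mmHg (clipped to
  the device range), an optimum shift ~ N(60°, 40°), and 6 measurement phases
  spread quasi-evenly over the circle (even grid + N(0, 10°) jitter, random
  start). Modulation amplitude 0.75 mmHg and reading noise 0.25 mmHg by
  default; readings are rounded to the device's 0.1 mmHg. Fast mode emits
  feature vectors directly (w1–w4 drawn from per-subject means around
  population values taken from the reference cohort statistics) so
  statistical tests run in seconds; render mode produces the full image
  sequences and pulse traces and exercises the imaging stages. Identical
  seeds reproduce cohorts bit for bit.

What the generator does *not* emulate: real corneal biomechanics (the bell
indentation is geometric, not mechanical), eyelid/eyelash occlusions,
specular reflexes, tear-film artefacts, PPG baseline wander and motion
artefacts, or any physiological IOP dynamics beyond the first harmonic.
Passing recovery tests therefore demonstrates the correctness and internal
consistency of the algorithms under the stated model, not clinical
performance on real recordings.

## 5. Problem sizes in the test suite

Statistical recovery tests pool ten replicate 10 × 6 fast-mode cohorts
(seeds 1–10); the acceptance script pools fifty replicates, because the 40°
between-subject spread leaves a single cohort's circular-mean shift with
~13° sampling error — the pooled estimate isolates the estimator's accuracy
from cohort-to-cohort luck. Rendered-mode checks use 2 subjects × 6
measurements (12 full sequences) at default noise, which keeps the imaging
tests around two minutes on one CPU while covering every stage.

## 6. Known limitations

* The scan grid (10°) and the 30° phase bins quantize the recovered shift;
  the plateau-midpoint estimator removes the systematic part but a residual
  ±5° ambiguity per subject is irreducible at K = 6.
* The whole-eye response is modelled and estimated as a vertical rigid
  shift; rotations and lateral motion are not represented.
* `pearson_r` requires K ≥ 3 and non-constant vectors; subjects measured at
  fewer than three distinct phases are rejected upstream.
* The vibration detector assumes a single dominant line above 100 Hz;
  closely spaced multiple lines are reported as their strongest member only.
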