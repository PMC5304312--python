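# oculopulse

Quantifying how the cardiac (blood-pulsation) phase at the instant an air-puff
tonometer fires modulates the measured intraocular pressure (IOP) and corneal
deformation features.

Non-contact tonometers deform the cornea with an air pulse while an
ultra-high-speed Scheimpflug camera films the cross-section (here: 140 frames
of 200 × 576 px, one every 231 µs, ≈20 µm/pixel). Because the ocular pulse —
the cardiac-synchronous variation of IOP driven by choroidal blood volume —
is not synchronized with the trigger, repeated measurements of the same eye
scatter with the cardiac phase. This package provides the full analysis chain
to measure that coupling, plus a synthetic-data generator with known ground
truth so that every stage is testable without clinical recordings.

## What it computes

Per measurement, six features are extracted:

| feature | meaning | units |
| --- | --- | --- |
| w1 | first applanation time (central cornea passes through flatness on indentation) | ms |
| w2 | second applanation time (on recovery) | ms |
| w3 | maximum corneal deformation (apex reaction amplitude) | mm |
| w4 | corneal vibration frequency above 100 Hz | Hz |
| w5 | IOP as reported by the tonometer | mmHg |
| w6 | cardiac phase at the trigger, from a finger pulse-oximeter trace, binned to 30° | deg |

w1–w4 come from the imaging chain: 3×3 median filtering, Canny edge detection
with per-frame-relative hysteresis thresholds, sub-pixel anterior-edge
localization, 5th-degree polynomial gap completion, and decomposition of the
contour motion into resting shape, whole-eye retraction and corneal reaction.
w6 comes from systolic-peak detection on the pulse trace (phase 0° at the
peak, linear interpolation between peaks).

The coupling itself is measured with a **phase-shift Pearson correlation
scan**: for each subject *v*, feature *j* and artificial shift φ on a 10° grid,

    r_v(j; φ) = Σ_k (w_kv(j) − w̄_v(j)) (s_kv(φ) − s̄_v(φ))
                / sqrt( Σ_k (w_kv(j) − w̄_v(j))² · Σ_k (s_kv(φ) − s̄_v(φ))² ),

with s_kv(φ) = (w_kv(6) + φ) mod 360 the shifted, wrapped phase and
k = 1…K the subject's measurements. The shift maximizing r locates the
physiological lag between the finger pulse and the ocular pulse. Subjects
whose scan never reaches a usable |r| are rejected as thick errors
(presets: 0.3 "thick", 0.55 "strict"); the retained maximum correlations and
optimum shifts are pooled into the cohort summary. Significance per subject
uses Student's t with K−2 degrees of freedom.

## Worked example

```python
from oculopulse import PhaseCouplingScan, generate_cohort, records_to_dataframe

records, truths = generate_cohort(n_subjects=10, n_meas_per_subject=6,
                                  seed=1, mode="fast")
results = PhaseCouplingScan(records_to_dataframe(records)).fit()
print(results.summary())
```

prints (abridged):

```
Phase-coupling scan summary
===========================
subjects: 10   measurements: 60   coupling feature: w5_mmHg
outlier preset: thick   retained: 10/10
...
Per-subject correlation extrema (coupling feature):
 subject  r_min  phi_min_deg  r_max  phi_max_deg  p_max
       1 -0.674      240.000  0.713       60.000  0.112
       2 -0.826      180.000  0.729       60.000  0.101
       3 -0.853      270.000  0.813       90.000  0.049
...
Pooled over retained subjects:
  max correlation: 0.78 +/- 0.06 (population std; sample std 0.07)
  circular mean optimum shift: 78.0 deg
  max per-subject IOP std: 0.79 mmHg
```

Each subject's IOP readings correlate strongly with the shifted cardiac phase
(r_max ≈ 0.7–0.9) and the optimum shifts cluster near the injected group lag
of 60° (any single 10-subject cohort scatters around it — the generator's
between-subject spread is 40°). The minimum correlations mirror the maxima
roughly 180° away, the signature of correlating a sinusoidally modulated
quantity against the wrapped linear phase.

The same analysis runs from the shell:

```bash
oculopulse synth --subjects 10 --seed 1 --out cohort/       # features.csv
oculopulse scan --features cohort/features.csv              # summary table
oculopulse run --render --out results/                      # full imaging chain
```

Rendered mode writes per-frame JPEG stacks and pulse CSVs and pushes them
through contour extraction instead of emitting features directly; a manifest
CSV (`subject, measurement, eye, frames_path, pulse_path, trigger_time_s,
iop_mmHg`) feeds externally recorded data through `oculopulse extract`.

Three small reference tables from a 10-subject healthy-cohort study ship with
the package (`oculopulse.datasets`): one subject's six feature vectors, the
per-subject feature statistics, and the per-subject correlation extrema. They
anchor the aggregate checks in the test suite, e.g. the pooled maximum
correlation after thick-error rejection, 0.78 ± 0.19 over 9 subjects.

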