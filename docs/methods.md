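# Methods

`apneascreen` screens for moderate-to-severe sleep apnea syndrome (SAS,
apnea–hypopnea index AHI ≥ 15) from a single channel of beat-to-beat R-R
intervals (RRI). This note documents the model, its assumptions, the
tunable parameters, the synthetic data the package is validated on, and
the numerical choices where the design was genuinely open.

## Screening procedure

For a subject with raw RRI series `z = [z_1, …, z_T]` (seconds):

1. **Standardize per subject.** `z̃ = (z − mean(z)) / sd(z)` with the
   sample (n−1) standard deviation, computed over the whole recording
   before segmentation. This removes between-subject differences in
   resting heart rate and overall variability; a zero-variance or
   length-<2 series is rejected.
2. **Segment by cumulative elapsed time.** Window *n* (width *w* = 60 s
   by default) receives the standardized intervals whose cumulative raw
   sum `c_i = z_1 + … + z_i` satisfies `(n−1)·w < c_i ≤ n·w`: an
   interval belongs to the window in which it *ends*, and an interval
   landing exactly on a boundary closes the earlier window. The
   trailing partial window is discarded so all segments span the same
   nominal duration. Segments are variable-length in beats (a 60-s
   window holds ~50–120 beats).
3. **Classify each segment** apnea (A) / normal (N) with a trained
   sequence model `m(·)` (below).
4. **Aggregate into the apnea/sleep (AS) ratio** `A = T_a / T_s`, where
   `T_a` is the summed duration of A-classified windows and `T_s` the
   duration of all analyzed windows. The ratio is kept as a fraction in
   [0, 1]; percent display is presentational. `T_s` is analyzed ECG
   time, not an EEG-derived total sleep time — this pipeline has no EEG
   channel, a deliberate divergence documented here.
5. **Decide.** The subject is flagged a *potential patient* when
   `A ≥ Ā`. The threshold `Ā` comes from the borderline-case rule: it
   is the AS ratio of the training patient with the smallest AHI among
   those with AHI ≥ 15 (AHI ties break toward the smaller AS ratio).
   The boundary is inclusive so the borderline patient classifies as a
   patient.

## Segment classifier

A single LSTM layer (standard cell: input/forget/output gates, tanh
candidate) with a final-hidden-state read-out through one sigmoid unit.
Defaults: 32 hidden units, 150 epochs, Adam with learning rate 0.01.
Since no deep-learning framework is a dependency, the LSTM (forward,
backpropagation through time, masking, Adam) is implemented directly in
numpy (`lstm.py`); it runs in float32 and is bit-reproducible for a
fixed seed on one machine.

Choices the headline configuration leaves open, fixed here:

- **Loss / batch / read-out:** binary cross-entropy, batch 64, final
  hidden state → one sigmoid output; A is predicted when the score
  exceeds 0.5.
- **Variable-length segments:** pre-padded with zeros and masked to
  `max_beats = 2·w` (120 for 60-s windows; RRI ≥ 0.5 s physiologically
  bounds beats per window). At a masked step the hidden and cell states
  carry over unchanged, so padding cannot alter the result; leading
  all-masked columns are trimmed per batch, which is exact and saves
  most of the padded work.
- **Gradient clipping** at global norm 5: a learning rate of 0.01 is
  large for an LSTM, and clipping keeps occasional exploding minibatch
  gradients from derailing training without changing the configuration.
- **No class rebalancing;** class counts are logged on the fitted model.
- **Initialization:** Glorot-uniform weights, zero biases except a +1
  forget-gate bias, seeded.

### HRV-feature mode

The feature-based baseline replaces each segment's beat sequence with
the 11 guideline HRV features: meanNN, SDNN, RMSSD, NN50, pNN50 (time
domain, ms/count/%) and TotalPower, LF, HF, LF/HF, LFnu, HFnu
(frequency domain, ms²/ratio/%). Features are computed on raw
(unstandardized) intervals in guideline units, then standardized
per-feature across the training set; undefined values (LF/HF with zero
HF power) are imputed to the training mean. Each standardized
11-vector enters the same LSTM as a single-timestep sequence — the
representation is not dictated by the configuration above, and this is
the minimal choice that keeps one code path for both modes.

Frequency-domain estimation: cubic-spline interpolation of the
tachogram onto a 4-Hz grid, mean removal, Welch PSD (64-s segments, 50%
overlap), band powers by disjoint half-open rectangle bins over
VLF 0.0033–0.04 Hz, LF 0.04–0.15 Hz, HF 0.15–0.40 Hz (TotalPower is
their sum, so LFnu + HFnu = 100 exactly whenever LF + HF > 0). The
guideline's 2-minute minimum for spectral analysis is *not* enforced by
default because the screening baseline computes features on 60-s
windows; `enforce_guideline=True` restores the check.

## R-wave detection

`ecg.detect_r_peaks` implements the Pan–Tompkins stages with the
original constants: band-pass 5–15 Hz (3rd-order Butterworth), five-point
derivative, squaring, 150-ms moving-window integration, adaptive
signal/noise thresholds with search-back (factor 1.66 of the running RR
average) and a 200-ms refractory period. Filtering and integration are
zero-phase here, so the integrated fiducial sits on the QRS; the final R
time is the band-passed maximum within ±50 ms. All thresholds are
relative, making detection invariant to positive rescaling of the
trace. No ectopic or artifact rejection is performed — the screening
model deliberately consumes the raw beat sequence.

## Synthetic cohort generator

The generator emulates one night of RRI per subject with ground-truth
apnea annotations, so every pipeline stage is testable without clinical
data. The instantaneous R-R interval is

    r(t) = base + a_RSA·sin(2π·0.25·t) + a_LF·sin(2π·0.10·t + φ)
           [+ a_CVHR·sin(2π·(t−t₀)/P) during apnea spans]

and beats fire when the phase integral ∫dt/r(t) crosses integers
(integrate-and-fire on a 10-ms grid, crossings linearly interpolated),
giving exact ground-truth beat times. Per-interval Gaussian jitter
(default SD 10 ms) stands in for unmodeled variability.

Defaults and what they represent:

| parameter | default | meaning |
|---|---|---|
| `record_duration_s` | 21600 (6 h) | one night's recording |
| `base_rri_s` | 0.9 | resting RRI (~67 bpm) |
| `rsa_amp_s` / `rsa_freq_hz` | 0.03 / 0.25 | respiratory sinus arrhythmia |
| `lf_amp_s` / `lf_freq_hz` | 0.02 / 0.10 | baroreflex-band oscillation |
| `cvhr_period_s` | 60 | period of cyclical variation of heart rate |
| `cvhr_amp_s` | 0.15 | CVHR amplitude during apnea |
| `event_rate_per_h` | 40 | apnea episodes/hour for patients |
| `event_duration_s` | (20, 60) | per-episode duration, uniform |
| `pre_post_extension_s` | 10 | CVHR starts before onset, outlasts offset |
| `noise_sd_s` | 0.01 | per-interval jitter |

Episodes are placed sequentially with exponential gaps calibrated so the
realized rate matches `event_rate_per_h`; extended CVHR spans never
overlap. The recorded AHI is the realized episode count per hour, so
group membership (patient ⇔ AHI ≥ 15) derives from what was actually
generated. The RSA and LF amplitudes are ordinary resting-HRV
magnitudes; the CVHR amplitude and 60-s period give apnea windows a
bradycardia–tachycardia oscillation an order of magnitude larger than
normal-breathing variability, which is the feature the classifier must
learn.

Ground-truth segment labels use an overlap rule: a window is A when the
union of apnea/hypopnea episodes covers ≥ 10 s of it (10 s being the
minimum scoreable event duration; configurable via `label_overlap_s`).

**What the generator does not emulate** — and therefore what passing
tests do not show about real data: no sleep-stage structure, no
obstructive-vs-central CVHR morphology difference, no apnea-induced
LF/HF shifts beyond the pure CVHR sinusoid, no movement artifacts, no
inter-patient severity spectrum (a cohort has a single event rate, so
between-patient AHI variation is only Poisson counting noise), and no
baroreflex physiology. Synthetic ECG is a Gaussian-template QRS train
over baseline wander and white noise — adequate for exercising a QRS
detector, not a morphology model. Ectopic-beat injection replaces an
interval pair with a 0.6/1.4 premature/compensatory split (pair sum
conserved exactly) to probe arrhythmia-driven false positives.

### A known consequence of uniform severity

On a synthetic cohort where every patient shares one event rate, the
group separation is essentially perfect (healthy AS ≈ 0, patient AS
clustered ≈ 0.8, subject-level AUC 1.0), but the borderline-case
threshold rule degrades: with no severity spread, the minimum-AHI
patient is an arbitrary member of a tight AS cluster, so roughly half
the patients can fall below their own cohort's threshold. The rule is
designed for cohorts whose AHI spans mild to severe, where the
borderline patient's AS sits far below the rest. Screening studies
using this package on synthetic cohorts should either include mild
patients (lower event rates) or report AUC alongside
sensitivity/specificity; the test suite documents the effect.

## Numerical and procedural choices

- Boundary ties in segmentation (cumulative sum exactly `n·w`) assign
  the interval to the earlier window; with uniform 1.0-s intervals and
  `w = 60`, windows are beats 1–60, 61–120, … exactly.
- A window entirely covered by a single interval (interval > `w`) is
  degenerate and rejected rather than emitted empty.
- Standardization uses the sample (n−1) SD, pinned by test; either
  denominator is defensible and the difference is O(1/n).
- The raw-RRI model warns at predict time when the incoming segments'
  mean exceeds 0.5 in absolute value — a symptom of skipped
  standardization.
- Subject-level (never segment-level) train/test splitting throughout;
  one global seed fans out to per-stage seeds through
  `numpy.random.SeedSequence`.
- Welch's t-test (unequal variances) compares patient vs healthy AS
  ratios; ROC AUC uses the AS ratio as score; both are reported as
  missing (None) when only one group is present.
- CSV floats are written with `repr` and read with pandas'
  round-trip parser so file round-trips are bit-exact.

## Problem sizes used in validation

The test suite and the reproduction script run the full pipeline on
2-hour records, 10 patients + 10 healthy subjects per cohort, training
on half the cohort split by subject — about 1,200 training segments for
the default 60-s window, which one CPU trains in one to three minutes
at the default 150 epochs. Window-width comparisons (30/60/120 s) reuse
one cohort. Unit-level checks use minutes-long records and reduced
epochs; classifier hyperparameter defaults are never reduced in the
acceptance-level checks.

## Limitations

- The package screens; it does not grade severity (no AHI estimation),
  and the AS ratio saturates on very severe, densely apneic nights.
- The borderline threshold rule assumes a severity-heterogeneous
  training cohort (see above).
- Spectral HRV features on 60-s windows violate the 2-minute guideline
  by construction; they exist for the baseline comparison, not as
  reference HRV measurements.
- No artifact or arrhythmia rejection: ectopy inflates apnea calls, by
  design mirroring the raw-RRI input contract.
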