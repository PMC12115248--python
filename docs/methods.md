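# Methods

This note records the modelling choices behind `hiegrade`: what each stage
computes, the parameters that matter and their defaults, what the
synthetic data generator does and does not emulate, and the numerical
decisions taken where the design was genuinely open.

## Signal model and sonification chain

Neonatal background EEG relevant to HIE grading is dominated by
delta/theta rhythms (≈0.5–8 Hz) whose continuity degrades with severity:
continuous activity (grade 1), progressively longer low-amplitude
inter-burst suppressions (grades 2–3), and near-isoelectric traces
(grade 4). The sonification chain renders an hour of one channel as a
3-minute audio clip that preserves exactly these two cues — rhythm
(via FM) and amplitude structure (via AM).

Stages and defaults (`SonifyConfig`):

- **Notch** at 50 Hz (Q = 30), configurable to 60 Hz; zero-phase.
- **Band-pass** 0.5–7.5 Hz, 4th-order Butterworth applied
  forward-backward. The upper edge leaves an anti-alias margin below the
  working Nyquist. Note the 0.5 Hz pole rings for several seconds at the
  record edges; on hour-long records this is negligible, and attenuation
  figures should be measured mid-record.
- **Decimation** to a 64 Hz working rate (`eeg_work_rate`): comfortably
  above twice the 7.5 Hz band edge, cheap to process.
- **Envelope**: magnitude of the analytic (Hilbert) signal smoothed by a
  0.25 s moving average.
- **Dynamic-range compression**: amplitudes above −20 dB relative to a
  fixed 50 μV full-scale reference (`ref_amplitude`, the clinical display
  range) are mapped v → T·(v/T)^(1/4) (threshold T = 5 μV, 4:1 ratio).
  Sub-threshold values pass unchanged; the map is continuous and
  monotone. Using a *fixed* physical reference rather than a per-record
  maximum is deliberate: it keeps near-isoelectric recordings quiet
  instead of renormalizing them up to full scale, so absolute amplitude —
  the key grade-4 cue — survives into the audio.
- **FM**: the modulator is the filtered EEG divided pointwise by its own
  raw envelope (floored at 10⁻³ of the envelope peak), clipped to
  [−1, 1]. This whitening makes the FM content exactly invariant to an
  overall amplitude rescaling of the input; amplitude information travels
  through the AM stage only. The instantaneous frequency is
  f(t) = 500 Hz · 2^(s(t)/12) with s(t) = (span/2)·m(t) and a default
  span of 24 semitones (full swing = ±1 octave). Phase is accumulated by
  cumulative summation at a 4096 Hz intermediate rate, keeping it
  continuous.
- **AM**: the FM tone is multiplied by the compressed envelope scaled so
  full scale maps to 1; the product is only scaled down (to a 0.99 peak)
  when it would clip.
- **Time compression**: a ×20 playback speed-up implemented as a
  relabelling of the nominal rate, followed by Fourier (FFT-based)
  resampling to 512 Hz. The ordering matters: a 500 Hz carrier cannot be
  carried by 512 Hz audio at the original time base, so resampling
  happens after the speed-up, where the carrier sits at 25 Hz equivalent.
  One hour at any input rate becomes exactly 180 s / 92,160 samples.

## Spectrogram representation

Per channel: STFT with a 128-sample Hann window and 64-sample hop, frames
fully inside the signal, magnitude → 20·log₁₀(|X| + 10⁻¹⁰). At 512 Hz
this gives 65 frequency rows of 4 Hz and a 125 ms column step; 180 s of
audio yields ⌊(92160 − 128)/64⌋ + 1 = 1439 columns. The 8 channel images
are stacked vertically (520 rows) in montage order; channel order is an
augmentation axis, not information, so training may shuffle the blocks.

For model input the log-magnitudes are mapped by the fixed affine
(v + 100)/50. A per-image standardization (`normalize_image`) is
available but is not used in the default pipeline, because zero-mean
scaling would erase the absolute energy differences that separate
grade 4 from grade 1. A log-Mel spectrogram of the band-passed raw EEG
(64 slaney-normalized bands) is provided purely as the comparison
baseline representation.

## Grading model

The grader is a CNN regressor: backbone → global average pooling → one
linear unit, trained with MSE on targets 1.0–4.0. Regression (rather
than 4-way classification) encodes the ordinal structure of the grades;
a softmax classification head is available on the same backbone for
comparison, and its continuous prediction is taken as the
probability-weighted expected grade so both modes feed the same
post-processing.

The desk-scale backbone `tiny_test_cnn` is three 3×3 stride-2 conv/ReLU
blocks (8, 16, 32 channels, ≈6k parameters) implemented directly on
numpy with hand-written backpropagation — small enough to train inside a
test suite on one CPU, large enough to learn the burst-suppression
signal. The training regimen implements:

- **Adam** (lr 3·10⁻³ default, β = 0.9/0.999);
- **cosine annealing with warm restarts** (first cycle 10 epochs,
  period multiplier 2, floor at 1% of base lr);
- **SWA**: parameters averaged over the last 25% of epochs;
- **channel-block shuffle** augmentation (per sample, per epoch);
- an **AMP** flag that runs the forward pass in float16 — an efficiency
  aid that is off by default so runs are bit-reproducible per seed.

The `convnext_nano_pretrained` backbone name routes to the full-scale
path and raises with instructions when the optional torch/timm
dependencies are absent. Its theoretical receptive field, computed by
`receptive_field` via r ← r + (k−1)·j, j ← j·s over the layer sequence,
is 1328 input samples — wide enough to span the highly rectangular
stacked spectrogram and capture hour-scale context.

## Optimized rounding

`fit_thresholds` searches the three cut points that maximize an
agreement objective (Cohen's kappa default; accuracy selectable) on
out-of-fold validation predictions. The objective is piecewise constant
in the cuts, which defeats a single Nelder–Mead simplex, so the search
runs Nelder–Mead from several starts (default cuts at 1.5/2.5/3.5,
prediction quantiles, and 4 seeded random starts) and refines each
iterate with a deterministic coordinate snap: each cut (and each pair of
cuts jointly) is scanned over the midpoints between consecutive sorted
predictions, which visits every achievable objective level. On 20-point
sets this reliably attains the exhaustive-search optimum. Candidate cut
vectors are sorted before evaluation, enforcing monotonicity without
constraints; a prediction exactly at a cut takes the lower grade.

## Evaluation protocol

`make_nested_folds` builds a 5-outer × 4-inner stratified group K-fold
plan (scikit-learn's `StratifiedGroupKFold`, shuffled, seeded): all
recordings of a patient stay on one side of every split, and grade
frequencies are balanced across folds as far as group atomicity allows.
`FoldPlan.validate()` checks partitioning and patient independence
exhaustively and runs at construction.

Per outer fold, `run_nested_cv` trains one model per inner fold, pools
the four inner folds' out-of-fold validation predictions (each
outer-train sample appears exactly once), fits the rounder on the pool,
averages the four members' continuous test predictions per sample, and
rounds with the fitted cuts. Outer-fold predictions are pooled into:
overall accuracy (pooled correct / N, equal to the fold-size-weighted
mean of per-fold accuracies), per-grade accuracy, a 4×4 confusion
matrix, support-weighted precision/recall/F1 (weighted recall coincides
with accuracy by construction), Cohen's kappa, MSE and R² of the
continuous predictions, a tolerance accuracy (|error| ≤ 1), and the
distance-based one-vs-rest AUC per grade from the score
1 − |ŷ − class| with Mann–Whitney ½-credit for ties. Predictors are
injected as index-based factories, so a perfect oracle (prediction =
truth) can replace the CNN to verify the framework itself is lossless —
it returns accuracy exactly 1.0 and unit AUCs.

Paired pipeline comparisons use the two-sided Wilcoxon signed-rank test
on per-fold accuracies (exact null for ≤25 folds). Embedding quality
(e.g. of UMAP projections of feature maps) is scored by Davies–Bouldin,
Calinski–Harabasz and silhouette via scikit-learn; the projection itself
is external to this package.

## Synthetic data generator

`hiegrade.synth` emulates the statistical structure the grader must
read, not the biophysics. Per grade (defaults; all configurable):

| grade | mean IBI (s) | burst dur. (s) | burst amp (μV RMS) | suppression amp |
|---|---|---|---|---|
| 1 | 0 (continuous) | — | 18 | — |
| 2 | 4 | 7 | 16 | 2.5 μV |
| 3 | 20 | 5 | 14 | 2.0 μV |
| 4 | 0 (continuous) | — | 1.8 | (isoelectric, < 10 μV peak) |

Bursts and suppressions alternate as a two-state semi-Markov process
with lognormal durations (σ = 0.4 on the log scale); the long-run
suppressed fraction has the closed form IBI/(IBI + burst), which tests
use as a counting oracle. The background inside each state is
1/f^1.5-shaped noise band-limited to 0.5–13 Hz with 3× delta-band gain,
scaled to the ±50 μV clinical display range; 60% of each channel is a
shared cortical source and 40% independent, so cross-channel structure
exists. Records are deterministic per seed, and dataset generation
spawns per-record seeds from one master seed. Grade shares default to
the emulated cohort's 61.5/18.3/13.0/7.1%, apportioned to patients by
largest remainder; each patient keeps one grade across epochs.

What the generator does **not** emulate: artifacts (ECG, movement, eye
blinks), seizures, sleep–wake cycling, electrode-specific topography, or
inter-patient variability beyond the seeded noise. Passing tests on this
data therefore demonstrate that the pipeline's machinery is correct and
that a planted continuity/amplitude signal is recovered
patient-independently — not clinical-grade performance; on the synthetic
defaults even a mean-energy threshold separates the grades, by design,
so the CNN's job is easy relative to real EEG.

## Problem sizes and numerical choices

The shipped end-to-end evaluation uses 20 patients × 4 records of
2 minutes at 256 Hz (80 recordings, 520×47 images), 15 epochs per inner
model, 5×4 nested folds — chosen so the complete suite runs in a few
minutes on a single CPU while exercising every moving part at full
fidelity. Scaling to hour-long records changes only image width
(47 → 1439 columns) and compute.

Other numerical decisions: polyphase resampling for rate conversion
(rational factor, limit denominator 1000); log floor ε = 10⁻¹⁰ before
dB conversion; EDF export quantizes to 16 bits over the per-channel
physical range (flat channels padded to a ±1 μV range); Fourier
resampling assumes the resampled segment is approximately periodic,
acceptable for long noise-like records; degenerate inputs (zero-variance
truths, single-class labels, absent AUC classes, identical paired
vectors) raise explicit errors rather than returning silent NaNs; the
threshold search falls back to the default cuts if the OOF pool is
degenerate.

## Known limitations

- The numpy backbone is intentionally small; results on real cohorts
  require the full-scale ConvNeXt path (optional torch/timm) and
  substantial training.
- The FM/AM chain processes channels independently; cross-channel phase
  relationships enter only through the stacked image.
- The EDF writer covers the subset of EDF+ needed for round-tripping and
  fixtures (continuous records, integer sampling rates, one-second data
  records).
- Rounding thresholds fitted on small out-of-fold pools can overfit the
  pool's kappa; the nested protocol measures exactly this effect on the
  outer test folds.
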