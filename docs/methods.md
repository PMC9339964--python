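# Methods

`ppgdetect` detects episodes of extreme bradycardia (< 40 bpm) and
ventricular tachycardia (> 120 bpm) in the photoplethysmogram (PPG),
following a train-on-simulated / test-on-real strategy: annotated PPG
databases with these arrhythmias are essentially nonexistent, so the
convolutional detector is trained entirely on simulated pulse waves
generated from RR-interval series, and real recordings (when available)
are only used for evaluation.  This note records the model, the
assumptions, and every numerical choice that is not forced by the
published operating values.

## 1. RR-interval synthesis

A training series has the structure *sinus | episode | sinus*:

* **Sinus rhythm.**  Instantaneous heart rate HR ~ N(mean, sd) with a
  sinusoidal respiratory modulation (default ±2 bpm at 0.25 Hz), truncated
  at 61 bpm; RR = 60/HR.  Defaults: mean 75 bpm, sd 3 bpm.  The hard
  constraint is HR > 60 bpm for every sinus beat; the distributional shape
  is a stand-in for real normal-sinus-rhythm series and makes no claim to
  HRV realism (no 1/f structure, no ectopy).
* **Episode placement.**  50–100 sinus beats precede the episode and
  1–100 follow, both uniform.
* **Episode length** is drawn from a log-normal with the target median
  (bradycardia 23 beats, tachycardia 14), resampled into the admissible
  range ([8, 51] and [4, 528] beats respectively); log-sd 0.45 (brady) and
  0.80 (tachy) spread the draws over those ranges.
* **Episode rate.**  One per-series level ~ N(median, 4 bpm) truncated to
  the rhythm's band (brady [25, 40] bpm, median 36; tachy ≥ 120 bpm,
  median 164), plus per-beat variability (sd 1.5/2.0 bpm, clipped to stay
  inside the band).  Within-episode variability of real episodes is not
  documented in the emulated statistics, so it is an exposed parameter
  rather than an asserted value.
* Subseries are concatenated directly, with no interpolation at the
  boundaries.

## 2. Pulse-wave synthesis

Each beat contributes one pulse: a linear combination of a log-normal and
two Gaussian waveforms in normalized beat time τ ∈ [0, 1], so the pulse
time-scales with its own RR interval.  Defaults (fractions of RR): systolic
log-normal peak at τ = 0.20 (shape 0.4), a shoulder Gaussian at τ = 0.34
(width 0.11, relative amplitude 0.55) and a dicrotic Gaussian at τ = 0.48
(width 0.10, amplitude 0.30); the combined pulse is unimodal with a
dicrotic shoulder, peak-normalized to 1.  All pulse parameters live in
`PulseShapeConfig`, not in code: the upstream pulse simulator's exact
numbers are not published, so these are package defaults chosen to give a
physiological wrist-PPG morphology (fast upstroke, peak at ~20 % of RR,
secondary wave below half the primary amplitude).

Pulses are overlap-added at cumulative RR onsets with start index
`round(onset × fs)` (cumulative placement avoids rounding drift) at
fs = 100 Hz.  An optional amplitude attenuation inside tachycardia
episodes (default off) emulates the reduced pulsations of compromised
hemodynamics and is used only for robustness experiments.

**Noise.**  Stationary colored noise: white Gaussian shaped by a one-pole
low-pass with a 4 Hz corner (≈ 6 dB/octave roll-off), scaled so that
10·log₁₀(P_signal/P_noise) equals the requested SNR over the full record.
This is a stand-in for the simulator's published noise model, whose
spectrum is not reproduced here; the corner is configurable.

## 3. Preprocessing

* Bandpass 0.5–40 Hz, 4th-order Butterworth applied forward–backward
  (zero phase, so segment boundaries stay aligned with annotations).
* Baseline removal: single-coefficient NLMS with constant reference
  input 1 — the adaptive weight tracks the slowly varying mean and is
  subtracted.  Because the reference is constant the recursion is exactly
  a one-pole low-pass, evaluated vectorized; step 0.02, regularization
  1e-6, weight initialized to the first sample.  Filter order and step are
  package assumptions (unstated upstream).
* Segmentation into non-overlapping 5-s windows; the trailing remainder is
  discarded (`floor(duration/5)` windows).

## 4. Signal quality

Per segment, the largest periodogram peak (mean removed, Hann window,
4× zero padding, DC excluded) must lie inside 0.6–3 Hz (inclusive), i.e.
3–15 beats per 5-s window; otherwise the segment is poor and excluded
from CNN detection.  The peak location is refined by parabolic
interpolation of the log-spectrum: the fundamental of a 36-bpm pulse train
sits exactly on the 0.6 Hz band edge, and without interpolation the
0.049 Hz grid of a 2048-point FFT would report 0.586 Hz and exclude the
median bradycardia rate purely through binning.

## 5. Scalograms

The continuous wavelet transform uses generalized Morse wavelets,
Ψ(ω) ∝ U(ω) ω^β e^(−ω^γ) with γ = 3 and time-bandwidth P² = βγ = 60, the
standard symmetric member.  61 scales at 10 voices per octave span exactly
six octaves up to 12 Hz (0.1875–12 Hz), covering the pulse fundamental
from 25 bpm (0.42 Hz) through fast tachycardia plus harmonics; each filter
is peak-normalized so a sinusoid at a scale's center frequency produces
the same magnitude at every scale.  A 5-s segment therefore yields a
500 × 61 (time × scale) magnitude image.

**Boundary handling is zero padding**, one segment length per side, after
mean removal.  A 0.5 Hz Morse wavelet at P² = 60 spans ~13 s — far beyond
the window — so any artificial extension (mirror, periodic) dominates the
low scales of the whole segment; with zero padding the scale whose total
energy is largest (the "ridge") tracks a constant heart rate to within one
scale step across 36–164 bpm.  The cone of influence is not masked: the
CNN consumes the full image.  Images are min–max normalized to [0, 1]
per segment before classification (configurable).

## 6. The dual-branch CNN

One independent binary network per arrhythmia:

| stage | bradycardia branch | tachycardia branch |
|---|---|---|
| conv 1 (stride 1, valid) | 32 kernels 13×13 | 32 kernels 5×5 |
| avg-pool | 2×2, stride 2 | 2×2, stride 2 |
| conv 2 | 32 kernels 13×13 | 32 kernels 5×5 |
| avg-pool | 2×2, stride 2 | 2×2, stride 2 |
| dense | 256 units | 256 units |
| output | 2-unit softmax | 2-unit softmax |

ReLU everywhere except the softmax output; dropout 0.5 after each pooling
stage and after the dense layer (the placement "after every layer except
the output" is ambiguous; this is the choice).  The larger bradycardia
kernel reflects its lower-frequency content.

Training: Adam, learning rate 0.01, cross-entropy, batch 32; the data are
balanced by under-sampling the majority class and split 70/30 (stratified)
into training/validation; training stops when validation accuracy stops
improving (patience 5 epochs, max 100 by default; the experiments in the
test-suite run with patience 2, max 6–8, since the clean-data task
converges in 1–3 epochs) and the best-epoch weights are restored.
Segments are classified as arrhythmia when the softmax probability exceeds
the branch threshold (strict >; default 0.5, configurable — thresholds
trade sensitivity against specificity along the ROC).

The implementation is a compact numpy CNN.  Convolution dispatches between
two exact routes: per-image patch-matrix GEMM when the patch length
(k²·C_in) is small, and an FFT route otherwise — forward valid
correlation, the weight gradient, and the input gradient are all evaluated
as one small complex matrix product per frequency bin, with FFT sizes at
least the input size so no circular wrap-around occurs.  Both routes are
verified against finite differences.  The output layer is
zero-initialized (He initialization elsewhere): at learning rate 0.01 the
first Adam steps are large relative to He-scale weights, and starting the
logits at zero ramps gradient flow up gradually.  Even so, a session
occasionally collapses within the first epoch into a dead constant-class
state (every ReLU path inactive, gradients identically zero — recovery is
impossible).  The trainer therefore restarts a session whose best
validation accuracy stays at chance (≤ 0.55) with a fresh initialization
substream, up to two restarts; the stated optimizer settings are
untouched.  All randomness (initialization, shuffling, under-sampling,
dropout, restarts) flows from one seed through named substreams, so a
session is bit-reproducible.

## 7. Pulse-based reference detector

The comparator never sees the CNN: the signal is bandpassed 0.5–6 Hz,
pulses are detected by an adaptive threshold (candidate local maxima must
exceed 0.5 × an exponentially averaged recent peak amplitude, memory 0.9,
refractory 0.3 s), and each pulse's occurrence time is its **onset**
estimated by the intersecting-tangents method (tangent at the steepest
upstroke point intersected with the preceding valley level, sub-sample
refined).  Onset timing matters: the systolic peak lags the beat onset by
a fraction of RR, so peak-based episode boundaries shift by ~0.2–0.4 s at
rhythm transitions and misclassify episode-edge segments.

Pulse quality: each beat (onset to next onset, resampled to 100 samples)
is correlated against the running mean of the last 8 accepted beats,
maximized over ±5-sample lags; accepted iff r > 0.6 (strict).  The first
beat, and a final beat cut off by the record end, keep a provisional
acceptance (correlation sentinel 1).  The template updates from accepted
beats only.

Episodes: instantaneous rate 60/interval, rounded to 0.1 bpm — at
fs = 100 Hz the residual timing error otherwise pushes records sitting
exactly on a boundary rate (e.g. a constant 40 bpm rhythm) across the
strict inequality.  A bradycardia (tachycardia) episode is a maximal run
of ≥ 3 consecutive intervals with rate < 40 (> 120) bpm whose pulses are
all accepted; rejected pulses break runs.  Rates within ~±0.3 bpm of a
boundary are genuinely ambiguous at this sampling rate — a known
limitation.  Episode output is mapped to 5-s segment labels with the same
overlap rules as the ground truth (below) so the comparison is symmetric.

## 8. Labelling and evaluation

Ground truth: a segment is bradycardia when episode annotations cover at
least 50 % of the window, tachycardia at 25 % (tachycardia packs more
beats into the same time), thresholds inclusive, overlap computed in
continuous time.  A segment is never both; overlapping brady+tachy
annotations are rejected.

The two CNN branches are evaluated separately — each branch's detection
is its own softmax output against its own threshold, never a merged
3-class label (the CLI's ``detect`` command does merge, picking the
larger output in the unlikely event both branches fire, but no reported
metric uses that rule).  A branch never sees the other arrhythmia during
training, so e.g. the bradycardia branch may fire on fast rhythms; that
cost appears, correctly, in its specificity.
Sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP) are computed over
**all** segments of a recording: segments excluded by quality assessment
carry the prediction "other", so an arrhythmia hidden in a poor-quality
window counts against sensitivity.  95 % CIs are Clopper–Pearson.
Detector agreement uses Cohen's kappa (p_o − p_e)/(1 − p_e) with a
bootstrap percentile CI (1000 resamples); the CI method for the published
intervals is unstated, so intervals are comparable only in spirit.

**SNR experiment.**  For each training SNR, one simulated dataset is
generated at that SNR and several models are trained on it from scratch
(fresh balancing, split and initialization per session), then evaluated
at threshold 0.5 on one clean test set shared across all conditions; the
mean sensitivity and specificity per SNR summarize the trade-off
(training with noise makes the detector more conservative: sensitivity
falls, specificity rises).  The package default is 5 sessions per SNR —
deliberately smaller than a full study (50 sessions), so per-SNR means
carry visible session-to-session variance.

## 9. Problem sizes in the shipped tests

The acceptance tests run the full pipeline at sizes chosen for a desktop
run: training pools with 300 arrhythmia segments per class and fixed
two-epoch sessions (the clean task converges within two epochs), held-out
test sets with 200 arrhythmia + 200 other segments, five training seeds
per branch, and the SNR comparison {clean, 10 dB} with five sessions each
(150 arrhythmia segments per pool, trained to the early-stopping rule —
under-converged sessions would otherwise swamp the noise effect with
convergence variance).  Two caveats about that comparison on a *clean*
synthetic test set: specificity of clean-trained models already sits at
the 1.0 ceiling, so "specificity rises with noisier training" can only
appear as a tie; and at these pool sizes mild training noise acts as data
augmentation, which can *raise* sensitivity on clean test data rather
than lower it.  The published trade-off was measured on real,
artifact-laden recordings with far larger training pools, where the
conservatism of noise-trained models dominates; the shipped experiment
reports whatever the desk-scale run produces.  What it shows: on clean
simulated data the two rhythms are separable from scalograms and both
detectors agree closely with ground truth.  What it does not show:
performance on real PPG with motion artifacts, pulseless tachycardia, or
arrhythmias outside the simulated grammar (ectopy, atrial fibrillation) —
the WFDB reader supports such studies but real annotated recordings must
be supplied by the user.

## 10. Known limitations

* The sinus and episode RR models are statistical stand-ins; they match
  the published summary statistics, not real RR dynamics.
* The pulse shape and noise spectrum are package defaults, not the
  original simulator's values.
* Rate rules at the exact 40/120 bpm boundaries are resolved to 0.1 bpm;
  finer distinctions are below the timing resolution at 100 Hz.
* Cohen's kappa on clean simulated records is near 1 by construction
  (both detectors are nearly perfect there); the published disagreement
  levels arise from real-data artifacts that the simulation does not
  reproduce.
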