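# ppgdetect

Detection of extreme bradycardia and ventricular tachycardia from the
photoplethysmogram (PPG), built for the wearable-monitoring setting where
annotated PPG databases with these arrhythmias barely exist.  The package
therefore trains on **simulated** PPG: RR-interval series with one
embedded episode (bradycardia < 40 bpm, ventricular tachycardia
> 120 bpm) are rendered into pulse waves, and a dual-branch convolutional
neural network classifies the Morse-wavelet scalogram of every 5-s
segment.  A classical pulse-based detector (adaptive pulse detection,
template-correlation quality, rate/duration rules) serves as the
reference comparator, and everything is evaluated segment-wise.

Who it is for: researchers in physiological signal processing who want a
fully reproducible, download-free pipeline for PPG arrhythmia detection —
every experiment below runs from synthetic data generated on the fly.

## Method at a glance

* **Simulation** — RR series `sinus | episode | sinus` (sinus HR > 60 bpm;
  episode statistics match the emulated datasets: bradycardia median
  36 bpm, 8–51 beats; tachycardia median 164 bpm, 4–528 beats).  Each beat
  becomes a pulse (log-normal + two Gaussians, time-scaled with RR),
  overlap-added at 100 Hz; stationary colored noise at any SNR.
* **Preprocessing** — 0.5–40 Hz zero-phase bandpass, single-tap NLMS
  baseline tracker (reference input 1), non-overlapping 5-s segments.
* **Quality** — a segment is usable iff its dominant spectral peak lies in
  0.6–3 Hz (3–15 beats / 5 s).
* **Detection** — per segment, the |CWT| under generalized Morse wavelets
  (γ=3, P²=60; 61 scales, 10 voices/octave) gives a 500×61 image; two
  independent binary CNNs (two conv layers of 32 kernels — 13×13 for the
  bradycardia branch, 5×5 for tachycardia — each with ReLU + 2×2 average
  pooling, then dense-256 and a 2-unit softmax, dropout 0.5) are trained
  with Adam (lr 0.01) on class-balanced 70/30 splits with early stopping.
  Segment → arrhythmia iff softmax output > threshold.
* **Reference detector** — 0.5–6 Hz band, onset-timed pulses, template
  correlation quality (accept iff r > η_c = 0.6), episode iff rate < 40
  (> 120) bpm for ≥ 3 consecutive high-quality beats.
* **Evaluation** — segment labels from episode overlap (≥ 50 % brady /
  ≥ 25 % tachy); sensitivity/specificity over entire recordings
  (poor-quality segments count as non-detections) with Clopper–Pearson
  CIs; Cohen's kappa between detectors; ROC by threshold sweep; an SNR
  study of the sensitivity/specificity trade-off.

See `docs/methods.md` for assumptions and every numerical choice.

## Worked example

```python
import numpy as np
from ppgdetect.pipeline import build_dataset, simulate_record, detect_record, ground_truth_labels
from ppgdetect.cnn import ModelSpec, TrainConfig, prepare_training_data, train
from ppgdetect.evaluation import sens_spec

# 1. training pool: simulated records until 300 bradycardia segments exist
pool = build_dataset("brady", 300, snr="clean", seed=11)
split = prepare_training_data(pool.images, pool.labels, seed=0)
model = train(ModelSpec("brady"), split, TrainConfig(max_epochs=8, patience=2, seed=0))
print("validation accuracy per epoch:", [round(a, 3) for a in model.history["val_accuracy"]])

# 2. detect on a fresh simulated record
ppg = simulate_record("brady", seed=42)
labels, probs, segs = detect_record(ppg, {"brady": model})
truth = ground_truth_labels(ppg, len(labels))
se, sp, _ = sens_spec(labels, truth, "brady")
print(f"record: {len(labels)} segments, Se={se:.3f} Sp={sp:.3f}")
```

Output:

```
validation accuracy per epoch: [0.861, 0.95, 1.0]
record: 20 segments, Se=1.000 Sp=1.000
```

The bradycardia branch separates clean simulated scalograms after 2–3
epochs (the 36-vs-75 bpm rate contrast makes the task nearly separable),
and on this record every 5-s segment is labelled in agreement with the
annotation-derived ground truth.  One behavior to be aware of: for
episodes slower than ~36 bpm the pulse fundamental falls below the
0.6 Hz quality band, the affected segments are excluded as poor quality,
and — because sensitivity is computed over entire recordings — those
segments count as misses for the CNN path (the reference detector does
not use the spectral quality check and is unaffected).

The same flow is available from the shell:

```bash
ppgdetect simulate --rhythm brady --seed 7 --out sim_out
ppgdetect train --branch tachy --n-positive 300 --out tachy.npz
ppgdetect detect --record sim_out/brady_7.csv --brady-model brady.npz --out det.csv
ppgdetect reference-detect --record sim_out/brady_7.csv --out ref.csv
ppgdetect evaluate --pred det.csv --truth truth.csv --rhythm brady
ppgdetect snr-study --snrs clean,20,10 --sessions 5
```

Real recordings can be supplied as CSV or WFDB (format 16) records with
JSON annotation sidecars (`[{"start_s": …, "end_s": …, "rhythm": "brady"}]`);
inputs at other sampling rates are resampled to 100 Hz.

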