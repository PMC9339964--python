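"""End-to-end glue: RR series -> PPG -> segments -> scalograms -> detection.

These helpers assemble the module-level operations into the full
processing chain used for training-set construction, detection on a
record, and the experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ppgdetect import quality as q
from ppgdetect.cnn import TrainedModel
from ppgdetect.config import RunConfig, derive_rng
from ppgdetect.ppg_sim import PulseModel, PPGSignal, add_noise, simulate_ppg
from ppgdetect.preprocess import Segment, bandpass, remove_baseline_nlms, segment
from ppgdetect.rr_synthesis import (
    generate_bradycardia_series,
    generate_tachycardia_series,
)
from ppgdetect.reference_detector import BRADY, OTHER, TACHY, _overlap_labels
from ppgdetect.scalogram import cwt_scalogram


def preprocess_record(ppg: PPGSignal, cfg: RunConfig | None = None) -> list[Segment]:
    """Bandpass + NLMS baseline removal + 5-s segmentation + quality flags."""
    cfg = cfg or RunConfig()
    filt = bandpass(ppg, cfg.filter.bandpass_low, cfg.filter.bandpass_high, cfg.filter.order)
    filt = remove_baseline_nlms(filt, cfg.filter.nlms_step, cfg.filter.nlms_reg)
    segs = segment(filt, cfg.segment.win_s)
    for s in segs:
        s.quality = q.assess_quality(
            s, (cfg.quality.band_low, cfg.quality.band_high), fs=ppg.fs
        )
    return segs


def ground_truth_labels(ppg: PPGSignal, n_segments: int, cfg: RunConfig | None = None) -> np.ndarray:
    cfg = cfg or RunConfig()
    return _overlap_labels(
        list(ppg.annotations), n_segments, cfg.segment.win_s,
        cfg.label.brady_overlap, cfg.label.tachy_overlap,
    )


def simulate_record(rhythm: str, seed: int, snr="clean", cfg: RunConfig | None = None) -> PPGSignal:
    """One annotated simulated record with a single embedded episode."""
    cfg = cfg or RunConfig()
    if rhythm == BRADY:
        rr = generate_bradycardia_series(seed=seed)
    elif rhythm == TACHY:
        rr = generate_tachycardia_series(seed=seed)
    else:
        raise ValueError(f"unknown rhythm {rhythm!r}")
    ppg = simulate_ppg(rr, PulseModel.from_config(cfg.pulse), fs=cfg.filter.fs)
    return add_noise(ppg, snr, seed=seed, cfg=cfg.noise)


@dataclass
class SegmentDataset:
    """Scalogram images with binary labels for one CNN branch."""

    images: np.ndarray    # (N, 500, 61) normalized to [0, 1]
    labels: np.ndarray    # 1 = arrhythmia segment of the branch rhythm


def build_dataset(
    branch: str,
    n_positive: int,
    snr="clean",
    seed: int = 0,
    cfg: RunConfig | None = None,
    max_records: int = 400,
    max_negatives: int | None = None,
) -> SegmentDataset:
    """Generate simulated records until ``n_positive`` arrhythmia segments exist.

    Only good-quality segments enter the dataset (poor segments never reach
    the CNN); labels follow the ground-truth overlap rules.  Simulated
    records contain far more non-arrhythmia than arrhythmia segments, so
    ``max_negatives`` can cap the negatives retained (segments are
    exchangeable across records; class balancing or a fixed negative count
    downstream would discard the surplus anyway).
    """
    cfg = cfg or RunConfig()
    rng = derive_rng(seed, 301)
    images, labels = [], []
    n_pos = n_neg = 0
    for _ in range(max_records):
        rec_seed = int(rng.integers(2**31))
        ppg = simulate_record(branch, rec_seed, snr=snr, cfg=cfg)
        segs = preprocess_record(ppg, cfg)
        truth = ground_truth_labels(ppg, len(segs), cfg)
        for s, lab in zip(segs, truth):
            if s.quality != q.GOOD:
                continue
            positive = lab == branch
            if not positive and max_negatives is not None and n_neg >= max_negatives:
                continue
            sc = cwt_scalogram(s, cfg.scalogram, fs=cfg.filter.fs)
            images.append(sc.normalized())
            labels.append(1 if positive else 0)
            n_pos += positive
            n_neg += not positive
        if n_pos >= n_positive:
            break
    if n_pos < n_positive:
        raise RuntimeError(
            f"only {n_pos}/{n_positive} positive segments after {max_records} records"
        )
    return SegmentDataset(np.array(images, dtype=np.float32), np.array(labels, dtype=int))


def detect_record(
    ppg: PPGSignal,
    models: dict[str, TrainedModel],
    thresholds: dict[str, float] | None = None,
    cfg: RunConfig | None = None,
):
    """Per-segment CNN detection on one record.

    Poor-quality segments are not classified and come out as "other".
    If both branches fire on one segment, the larger output wins.
    Returns (labels, probabilities-per-branch, segments).
    """
    cfg = cfg or RunConfig()
    thresholds = thresholds or {
        BRADY: cfg.cnn.brady_threshold, TACHY: cfg.cnn.tachy_threshold
    }
    segs = preprocess_record(ppg, cfg)
    labels = np.full(len(segs), OTHER, dtype="U5")
    probs = {b: np.zeros(len(segs)) for b in models}
    good_idx = [i for i, s in enumerate(segs) if s.quality == q.GOOD]
    if good_idx:
        images = np.stack([
            cwt_scalogram(segs[i], cfg.scalogram, fs=ppg.fs).normalized()
            for i in good_idx
        ])
        for b, model in models.items():
            probs[b][good_idx] = model.predict_proba(images)
        for i in good_idx:
            fired = {b: probs[b][i] for b in models if probs[b][i] > thresholds[b]}
            if fired:
                labels[i] = max(fired, key=fired.get)
    return labels, probs, segs
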