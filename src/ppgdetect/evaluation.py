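"""Segment-wise evaluation: labelling, sensitivity/specificity, kappa, ROC.

Ground-truth labels come from annotated episode intervals via the overlap
rules (an episode must cover >=50% of a 5-s window for bradycardia, >=25%
for tachycardia).  Sensitivity and specificity are computed over ALL
segments of a recording — segments excluded by quality assessment count as
"other" predictions, so missed arrhythmia in poor-quality windows costs
sensitivity.  Agreement between detectors uses Cohen's kappa.
Clopper–Pearson intervals are attached to Se/Sp; a bootstrap interval to
kappa.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ppgdetect.config import RunConfig, derive_rng
from ppgdetect.reference_detector import BRADY, OTHER, TACHY, _overlap_labels


@dataclass
class PerformanceReport:
    rhythm: str
    sensitivity: float | None
    specificity: float | None
    sensitivity_ci: tuple[float, float] | None
    specificity_ci: tuple[float, float] | None
    tp: int
    fp: int
    tn: int
    fn: int
    kappa: float | None = None
    kappa_ci: tuple[float, float] | None = None
    roc: list[tuple[float, float, float]] = field(default_factory=list)  # (thr, 1-Sp, Se)
    config: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=_jsonable)

    def summary(self) -> str:
        def fmt(v, ci):
            if v is None:
                return "undefined"
            s = f"{100 * v:5.1f}%"
            if ci:
                s += f" [{100 * ci[0]:.1f}, {100 * ci[1]:.1f}]"
            return s

        lines = [
            f"Rhythm: {self.rhythm}",
            f"  Sensitivity: {fmt(self.sensitivity, self.sensitivity_ci)}",
            f"  Specificity: {fmt(self.specificity, self.specificity_ci)}",
            f"  Counts: TP={self.tp} FP={self.fp} TN={self.tn} FN={self.fn}",
        ]
        if self.kappa is not None:
            k = f"  Cohen's kappa: {self.kappa:.2f}"
            if self.kappa_ci:
                k += f" [{self.kappa_ci[0]:.2f}, {self.kappa_ci[1]:.2f}]"
            lines.append(k)
        return "\n".join(lines)


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def label_segments(
    annotations: list[tuple[float, float, str]],
    n_segments: int,
    win_s: float = 5.0,
    brady_overlap: float = 0.50,
    tachy_overlap: float = 0.25,
) -> np.ndarray:
    """Ground-truth per-segment labels from episode intervals.

    Overlap fractions are computed in continuous time; thresholds are
    inclusive.  Bradycardia and tachycardia annotations may not overlap.
    """
    per_rhythm: dict[str, list[tuple[float, float]]] = {BRADY: [], TACHY: []}
    for start, end, rhythm in annotations:
        if rhythm in per_rhythm:
            per_rhythm[rhythm].append((float(start), float(end)))
    for b0, b1 in per_rhythm[BRADY]:
        for t0, t1 in per_rhythm[TACHY]:
            if max(b0, t0) < min(b1, t1):
                raise ValueError("bradycardia and tachycardia annotations overlap in time")
    return _overlap_labels(list(annotations), n_segments, win_s, brady_overlap, tachy_overlap)


def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def sens_spec(pred, truth, rhythm: str):
    """Sensitivity/specificity of ``rhythm`` detection with 95% CIs.

    Returns (sensitivity, specificity, (se_ci, sp_ci)); sensitivity is
    None when the truth contains no positive segment.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must have equal length")
    pos = truth == rhythm
    hit = pred == rhythm
    tp = int(np.sum(pos & hit))
    fn = int(np.sum(pos & ~hit))
    fp = int(np.sum(~pos & hit))
    tn = int(np.sum(~pos & ~hit))
    se = tp / (tp + fn) if (tp + fn) else None
    sp = tn / (tn + fp) if (tn + fp) else None
    se_ci = _clopper_pearson(tp, tp + fn) if (tp + fn) else None
    sp_ci = _clopper_pearson(tn, tn + fp) if (tn + fp) else None
    return se, sp, (se_ci, sp_ci)


def performance_report(pred, truth, rhythm: str, **extra) -> PerformanceReport:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    se, sp, (se_ci, sp_ci) = sens_spec(pred, truth, rhythm)
    pos = truth == rhythm
    hit = pred == rhythm
    return PerformanceReport(
        rhythm=rhythm,
        sensitivity=se, specificity=sp,
        sensitivity_ci=se_ci, specificity_ci=sp_ci,
        tp=int(np.sum(pos & hit)), fp=int(np.sum(~pos & hit)),
        tn=int(np.sum(~pos & ~hit)), fn=int(np.sum(pos & ~hit)),
        **extra,
    )


def cohens_kappa(labels_a, labels_b, ci: bool = False, n_boot: int = 1000, seed: int = 0):
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    Works on any label alphabet (the contingency table is built over the
    union of observed categories).  Returns kappa, or (kappa, (lo, hi))
    with a bootstrap percentile CI when ``ci`` is true.  Degenerate
    marginals (both raters constant and identical) give kappa None.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")

    def _kappa(a, b):
        cats = np.union1d(np.unique(a), np.unique(b))
        if len(cats) < 2:
            return None
        n = len(a)
        ai = np.searchsorted(cats, a)
        bi = np.searchsorted(cats, b)
        table = np.zeros((len(cats), len(cats)))
        np.add.at(table, (ai, bi), 1)
        p_o = np.trace(table) / n
        p_e = float(np.sum(table.sum(1) * table.sum(0))) / n**2
        if p_e == 1.0:
            return None
        return float((p_o - p_e) / (1 - p_e))

    k = _kappa(a, b)
    if not ci:
        return k
    rng = derive_rng(seed, 401)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(a), len(a))
        kb = _kappa(a[idx], b[idx])
        if kb is not None:
            boots.append(kb)
    if k is None or not boots:
        return k, None
    return k, (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))


def roc_sweep(probabilities, truth, thresholds, rhythm: str | None = None):
    """(threshold, 1-Sp, Se) per threshold; positives iff p > threshold.

    ``truth`` may be binary (1 = positive) or a rhythm-label vector with
    ``rhythm`` naming the positive class.
    """
    p = np.asarray(probabilities, dtype=float)
    truth = np.asarray(truth)
    pos = (truth == rhythm) if rhythm is not None else truth.astype(bool)
    out = []
    for thr in thresholds:
        if not 0 <= thr <= 1:
            raise ValueError("thresholds must lie in [0, 1]")
        hit = p > thr
        tp = np.sum(pos & hit)
        fn = np.sum(pos & ~hit)
        fp = np.sum(~pos & hit)
        tn = np.sum(~pos & ~hit)
        se = tp / (tp + fn) if (tp + fn) else np.nan
        sp = tn / (tn + fp) if (tn + fp) else np.nan
        out.append((float(thr), float(1 - sp), float(se)))
    return out


def subsample_negatives(dataset, n_neg: int, seed: int = 0):
    """Keep all positive segments and a random subset of the negatives."""
    from ppgdetect.pipeline import SegmentDataset

    rng = derive_rng(seed, 409)
    idx_pos = np.flatnonzero(dataset.labels == 1)
    idx_neg = np.flatnonzero(dataset.labels == 0)
    if len(idx_neg) > n_neg:
        idx_neg = rng.choice(idx_neg, n_neg, replace=False)
    keep = np.sort(np.concatenate([idx_pos, idx_neg]))
    return SegmentDataset(dataset.images[keep], dataset.labels[keep])


def snr_experiment(
    snr_list,
    n_sessions: int = 5,
    seed: int = 0,
    branch: str = TACHY,
    n_train_pos: int = 100,
    n_test_pos: int = 60,
    n_test_neg: int | None = None,
    cfg: RunConfig | None = None,
    train_cfg=None,
) -> pd.DataFrame:
    """Detection performance versus training SNR, on a fixed clean test set.

    For each SNR, one simulated dataset is generated at that SNR and
    ``n_sessions`` models are trained on it from scratch (fresh balancing,
    split and initialization per session), then evaluated (threshold 0.5)
    on one clean test set shared across all sessions and SNRs.  Returns a
    tidy frame with one row per (snr, session) plus per-SNR means in
    ``df.attrs``; training with noisier signals is expected to trade
    sensitivity for specificity.
    """
    from ppgdetect.cnn import ModelSpec, TrainConfig, prepare_training_data, train

    if n_sessions < 2:
        raise ValueError("n_sessions must be >= 2")
    cfg = cfg or RunConfig()
    train_cfg = train_cfg or TrainConfig()
    from ppgdetect.pipeline import build_dataset

    test = build_dataset(
        branch, n_test_pos, snr="clean", seed=seed + 77_000, cfg=cfg,
        max_negatives=None if n_test_neg is None else n_test_neg + 50,
    )
    if n_test_neg is not None:
        test = subsample_negatives(test, n_test_neg, seed=seed + 78_000)
    rows = []
    for snr in snr_list:
        pool_seed = seed + 10_000 + zlib.crc32(str(snr).encode()) % 997
        data = build_dataset(branch, n_train_pos, snr=snr, seed=pool_seed, cfg=cfg,
                             max_negatives=n_train_pos + 50)
        for sess in range(n_sessions):
            sess_seed = seed + 1000 * (sess + 1)
            split = prepare_training_data(
                data.images, data.labels, seed=sess_seed,
                train_fraction=train_cfg.train_fraction,
            )
            tc = TrainConfig(
                learning_rate=train_cfg.learning_rate,
                batch_size=train_cfg.batch_size,
                max_epochs=train_cfg.max_epochs,
                patience=train_cfg.patience,
                train_fraction=train_cfg.train_fraction,
                seed=sess_seed,
            )
            model = train(ModelSpec(branch), split, tc)
            p = model.predict_proba(test.images)
            pred = np.where(p > 0.5, branch, OTHER)
            truth = np.where(test.labels == 1, branch, OTHER)
            se, sp, _ = sens_spec(pred, truth, branch)
            rows.append({"snr": str(snr), "session": sess, "sensitivity": se, "specificity": sp})
    df = pd.DataFrame(rows)
    means = df.groupby("snr", sort=False)[["sensitivity", "specificity"]].mean()
    df.attrs["means"] = means
    df.attrs["trend"] = {
        "sensitivity_nonincreasing": bool(np.all(np.diff(means["sensitivity"].values) <= 1e-12)),
        "specificity_nondecreasing": bool(np.all(np.diff(means["specificity"].values) >= -1e-12)),
    }
    return df
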