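"""Pulse-based comparator: pulse detection, template quality, rate rules.

The signal is bandpass filtered to 0.5–6 Hz, pulses are found with an
adaptive-threshold peak detector (threshold = half the exponentially
averaged recent peak amplitude, 0.3-s refractory period), and each pulse is
quality-checked by correlating its resampled waveform against a running
template of recently accepted pulses; a pulse is accepted when the maximum
sample correlation coefficient over small lags exceeds eta_c = 0.6
(strictly).  An episode is declared when the instantaneous rate stays
below 40 bpm (bradycardia) or above 120 bpm (tachycardia) — strict
inequalities — for at least 3 consecutive high-quality beats; runs are
broken by rejected pulses.  Episode output is finally mapped onto 5-s
segments with the same overlap rules used for ground-truth labelling
(>=50% bradycardia, >=25% tachycardia) so the comparison is symmetric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from ppgdetect.config import ReferenceConfig
from ppgdetect.ppg_sim import PPGSignal
from ppgdetect.preprocess import bandpass

BRADY = "brady"
TACHY = "tachy"
OTHER = "other"


@dataclass
class PulseTrain:
    """Detected pulse occurrence times with per-pulse quality."""

    times: np.ndarray                      # seconds, strictly increasing
    correlations: np.ndarray | None = None  # max template correlation per pulse
    accepted: np.ndarray | None = None      # quality flag per pulse

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("pulse times must be strictly increasing")
        if self.accepted is not None:
            self.accepted = np.asarray(self.accepted, dtype=bool)
        if self.correlations is not None:
            self.correlations = np.asarray(self.correlations, dtype=float)

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class Episode:
    rhythm: str
    start_s: float
    end_s: float
    n_beats: int

    def __post_init__(self) -> None:
        if self.n_beats < 3:
            raise ValueError("an episode requires at least 3 beats")

    def to_dict(self) -> dict:
        return {"rhythm": self.rhythm, "start_s": self.start_s,
                "end_s": self.end_s, "n_beats": self.n_beats}


def episodes_to_json(episodes: list[Episode], path: str) -> None:
    with open(path, "w") as fh:
        json.dump([e.to_dict() for e in episodes], fh, indent=1)


def _refine_extremum(x: np.ndarray, idx: int) -> float:
    """Sub-sample extremum position by parabolic interpolation of 3 points."""
    if idx <= 0 or idx >= len(x) - 1:
        return float(idx)
    y0, y1, y2 = x[idx - 1], x[idx], x[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(idx)
    return idx + 0.5 * (y0 - y2) / denom


def _foot_index(x: np.ndarray, peak: int, max_back: int) -> int:
    """Walk back from a peak to the preceding local minimum (pulse onset)."""
    lo = max(0, peak - max_back)
    k = peak
    while k > lo and x[k - 1] <= x[k]:
        k -= 1
    return k


def _onset_time(x: np.ndarray, peak: int, max_back: int) -> float:
    """Pulse-onset sample position by the intersecting-tangents method.

    The tangent at the steepest point of the systolic upstroke is
    intersected with the horizontal through the preceding valley; this is
    far more stable than locating the valley minimum itself, which is a
    broad, flat feature during slow rhythms.
    """
    foot = _foot_index(x, peak, max_back)
    if foot >= peak:
        return float(foot)
    seg = x[foot : peak + 1]
    d = np.diff(seg)
    m = int(np.argmax(d))
    slope = d[m]
    if slope <= 0:
        return _refine_extremum(x, foot)
    base = seg.min()
    pos = foot + m + 0.5 - (x[foot + m] + 0.5 * slope - base) / slope
    return float(np.clip(pos, foot - 1.0, peak))


def detect_pulses(ppg: PPGSignal, cfg: ReferenceConfig | None = None) -> PulseTrain:
    """Adaptive-threshold pulse detection on the 0.5–6 Hz filtered signal.

    Candidate events are local maxima of the filtered signal; a candidate
    is kept when it exceeds ``amp_factor`` times the exponentially averaged
    amplitude of recent accepted peaks and falls outside the refractory
    period of the previous pulse.  The reported occurrence time is the
    pulse onset — the local minimum (foot) preceding the systolic peak —
    refined to sub-sample precision by parabolic interpolation, so that
    episode boundaries align with the underlying beat onsets.
    """
    cfg = cfg or ReferenceConfig()
    filt = bandpass(ppg, 0.5, 6.0)
    x = filt.samples
    if len(x) == 0 or not np.any(x):
        return PulseTrain(np.empty(0))
    peaks, _ = sps.find_peaks(x)
    if len(peaks) == 0:
        return PulseTrain(np.empty(0))

    # seed the amplitude tracker from the largest peak in the first 2 s
    lead = peaks[peaks < 2.0 * ppg.fs]
    amp = float(x[lead].max()) if len(lead) else float(x[peaks[0]])

    times = []
    last_peak_t = -np.inf
    max_back = int(0.6 * ppg.fs)  # onset search window before the peak
    for pk in peaks:
        h = x[pk]
        if h <= cfg.amp_factor * amp:
            continue
        peak_t = _refine_extremum(x, pk) / ppg.fs
        if peak_t - last_peak_t < cfg.refractory_s:
            continue
        t = _onset_time(x, pk, max_back) / ppg.fs
        if times and t <= times[-1]:
            continue
        times.append(t)
        last_peak_t = peak_t
        amp = cfg.amp_memory * amp + (1 - cfg.amp_memory) * h
    return PulseTrain(np.array(times))


def _extract_beat(x: np.ndarray, fs: float, t0: float, t1: float, n_out: int) -> np.ndarray | None:
    i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
    if i1 - i0 < 4 or i0 < 0 or i1 > len(x):
        return None
    beat = x[i0:i1]
    return np.interp(np.linspace(0, len(beat) - 1, n_out), np.arange(len(beat)), beat)


def _max_lag_corr(a: np.ndarray, b: np.ndarray, max_lag: int) -> float:
    """Maximum Pearson correlation over integer shifts of +-max_lag."""
    best = -1.0
    n = len(a)
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            u, v = a[lag:], b[: n - lag]
        else:
            u, v = a[: n + lag], b[-lag:]
        su, sv = u.std(), v.std()
        if su == 0 or sv == 0:
            continue
        r = float(np.corrcoef(u, v)[0, 1])
        best = max(best, r)
    return best


def assess_pulse_quality(
    train: PulseTrain, ppg: PPGSignal, cfg: ReferenceConfig | None = None
) -> PulseTrain:
    """Template-correlation quality: accepted iff max correlation > eta_c.

    Each beat (pulse-to-pulse waveform) is resampled to ``template_len``
    samples and correlated against the running mean of the last
    ``template_history`` accepted beats, maximized over +-``max_lag``
    sample shifts.  The template updates from accepted beats only.  Beats
    that cannot be assessed — the first beat (no template yet) and a final
    beat whose window is cut off by the record end — keep their
    provisional acceptance with correlation 1 as a sentinel.
    """
    cfg = cfg or ReferenceConfig()
    if len(train) == 0:
        raise ValueError("empty pulse train")
    filt = bandpass(ppg, 0.5, 6.0)
    x = filt.samples
    n = len(train)
    corrs = np.ones(n)
    accepted = np.ones(n, dtype=bool)
    history: list[np.ndarray] = []

    for k in range(n):
        t0 = train.times[k]
        t1 = train.times[k + 1] if k + 1 < n else t0 + (t0 - train.times[k - 1] if k else 1.0)
        beat = _extract_beat(x, ppg.fs, t0, t1, cfg.template_len)
        if beat is None:
            if round(t1 * ppg.fs) > len(x):
                continue        # record ends mid-beat: leave provisional
            accepted[k] = False  # implausibly short beat window
            corrs[k] = -1.0
            continue
        if not history:
            history.append(beat)   # provisional acceptance, seeds the template
            continue
        template = np.mean(history, axis=0)
        r = _max_lag_corr(beat, template, cfg.max_lag)
        corrs[k] = r
        accepted[k] = r > cfg.eta_c
        if accepted[k]:
            history.append(beat)
            if len(history) > cfg.template_history:
                history.pop(0)
    return PulseTrain(train.times, corrs, accepted)


def instantaneous_rates(train: PulseTrain, decimals: int = 1) -> np.ndarray:
    """Beat-to-beat rate (bpm) per interval, rounded to ``decimals``.

    Rounding before rule evaluation keeps records at exactly a boundary
    rate from being pushed across it by residual timing error.
    """
    if len(train) < 2:
        return np.empty(0)
    return np.round(60.0 / np.diff(train.times), decimals)


def detect_episodes(train: PulseTrain, cfg: ReferenceConfig | None = None) -> list[Episode]:
    """Rate/duration rules on high-quality beats.

    A bradycardia (tachycardia) episode is a maximal run of at least
    ``min_beats`` consecutive intervals with rate strictly below 40 bpm
    (strictly above 120 bpm) whose bounding pulses are all accepted.
    """
    cfg = cfg or ReferenceConfig()
    if len(train) < cfg.min_beats + 1:
        return []
    accepted = train.accepted if train.accepted is not None else np.ones(len(train), bool)
    rates = instantaneous_rates(train, cfg.rate_decimals)
    # interval k spans pulses k..k+1; it is usable only if both are accepted
    usable = accepted[:-1] & accepted[1:]

    episodes: list[Episode] = []
    for rhythm, cond in ((BRADY, rates < cfg.brady_bpm), (TACHY, rates > cfg.tachy_bpm)):
        flags = cond & usable
        k = 0
        n = len(flags)
        while k < n:
            if not flags[k]:
                k += 1
                continue
            j = k
            while j < n and flags[j]:
                j += 1
            run = j - k
            if run >= cfg.min_beats:
                episodes.append(
                    Episode(rhythm, float(train.times[k]), float(train.times[j]), run)
                )
            k = j
    episodes.sort(key=lambda e: e.start_s)
    return episodes


def episodes_to_segments(
    episodes: list[Episode],
    n_segments: int,
    win_s: float = 5.0,
    brady_overlap: float = 0.50,
    tachy_overlap: float = 0.25,
) -> np.ndarray:
    """Map episodes onto per-segment labels with the overlap rules.

    A segment is labelled bradycardia when episodes of that rhythm cover at
    least 50% of the window, tachycardia at 25%.  If both rules fire (not
    expected in practice) the rhythm with the larger overlap-to-threshold
    ratio wins.
    """
    intervals = [(e.start_s, e.end_s, e.rhythm) for e in episodes]
    return _overlap_labels(intervals, n_segments, win_s, brady_overlap, tachy_overlap)


def _overlap_labels(
    intervals: list[tuple[float, float, str]],
    n_segments: int,
    win_s: float,
    brady_overlap: float,
    tachy_overlap: float,
) -> np.ndarray:
    labels = np.full(n_segments, OTHER, dtype="U5")
    cover = {BRADY: np.zeros(n_segments), TACHY: np.zeros(n_segments)}
    for start, end, rhythm in intervals:
        if rhythm not in cover or end <= start:
            continue
        first = max(0, int(np.floor(start / win_s)))
        last = min(n_segments - 1, int(np.ceil(end / win_s)) - 1)
        for i in range(first, last + 1):
            lo, hi = i * win_s, (i + 1) * win_s
            cover[rhythm][i] += max(0.0, min(end, hi) - max(start, lo))
    thr = {BRADY: brady_overlap * win_s, TACHY: tachy_overlap * win_s}
    for i in range(n_segments):
        scores = {
            r: cover[r][i] / thr[r]
            for r in (BRADY, TACHY)
            if cover[r][i] >= thr[r] - 1e-9
        }
        if scores:
            labels[i] = max(scores, key=scores.get)
    return labels
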