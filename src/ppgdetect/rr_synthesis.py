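"""Synthetic RR-interval series with one embedded arrhythmia episode.

Series have the structure sinus | episode | sinus.  Sinus rhythm keeps the
instantaneous heart rate strictly above 60 bpm; a bradycardia episode sits
in 25–40 bpm (median ~36), a ventricular tachycardia episode at >=120 bpm
(median ~164).  Episode lengths follow truncated log-normal distributions
whose medians match the target statistics (brady: 8–51 beats, median 23;
tachy: 4–528 beats, median 14).  The number of sinus beats before an
episode is uniform in [50, 100] and after it uniform in [1, 100].
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np

from ppgdetect.config import derive_rng

SINUS = "sinus"
BRADY = "brady"
TACHY = "tachy"

# episode-length statistics (beats): (min, median, max)
_BRADY_LEN = (8, 23, 51)
_TACHY_LEN = (4, 14, 528)
_BRADY_HR_MEDIAN = 36.0
_TACHY_HR_MEDIAN = 164.0
_BRADY_HR_BAND = (25.0, 40.0)
_TACHY_HR_MIN = 120.0
_SINUS_HR_MIN = 60.0

# log-sd of the truncated log-normal episode-length draw
_BRADY_LEN_SIGMA = 0.45
_TACHY_LEN_SIGMA = 0.80


@dataclass
class RRSeries:
    """Ordered beat-to-beat intervals with per-interval rhythm labels.

    ``episode_bounds`` is a half-open beat-index range ``(start, end)``:
    exactly intervals ``start .. end-1`` carry the arrhythmia label.
    """

    intervals: np.ndarray          # seconds per beat
    labels: np.ndarray             # {"sinus", "brady", "tachy"} per interval
    episode_bounds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.labels = np.asarray(self.labels, dtype="U5")
        if self.intervals.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if len(self.labels) != len(self.intervals):
            raise ValueError("labels and intervals must have equal length")
        if len(self.intervals) and not (
            np.all(self.intervals > 0) and np.all(self.intervals < 10.0)
        ):
            raise ValueError("every RR interval must lie in (0, 10) s")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def duration_s(self) -> float:
        return float(self.intervals.sum())

    @property
    def onsets_s(self) -> np.ndarray:
        """Cumulative beat onset times; onset k starts interval k."""
        return np.concatenate([[0.0], np.cumsum(self.intervals)])[:-1]

    def episode_interval_s(self) -> tuple[float, float, str] | None:
        """The episode as a (start_s, end_s, rhythm) annotation, or None."""
        if self.episode_bounds is None:
            return None
        s, e = self.episode_bounds
        cum = np.concatenate([[0.0], np.cumsum(self.intervals)])
        return float(cum[s]), float(cum[e]), str(self.labels[s])

    def to_csv(self, path: str, bounds_path: str | None = None) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["interval_s", "label"])
            for rr, lab in zip(self.intervals, self.labels):
                w.writerow([f"{rr:.6f}", lab])
        if bounds_path is not None:
            with open(bounds_path, "w") as fh:
                json.dump({"episode_bounds": list(self.episode_bounds) if self.episode_bounds else None}, fh)

    @classmethod
    def from_csv(cls, path: str, bounds_path: str | None = None) -> "RRSeries":
        intervals, labels = [], []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                intervals.append(float(row["interval_s"]))
                labels.append(row["label"])
        bounds = None
        if bounds_path is not None:
            with open(bounds_path) as fh:
                raw = json.load(fh).get("episode_bounds")
            bounds = tuple(raw) if raw is not None else None
        return cls(np.array(intervals), np.array(labels), bounds)


def generate_sinus_rr(
    n_beats: int,
    mean_hr: float = 75.0,
    hr_sd: float = 3.0,
    seed: int = 0,
    resp_amp_bpm: float = 2.0,
    resp_hz: float = 0.25,
) -> RRSeries:
    """Sinus-rhythm RR intervals from a Gaussian heart-rate model.

    HR ~ N(mean_hr, hr_sd) plus an optional sinusoidal respiratory
    modulation (``resp_amp_bpm`` at ``resp_hz``), truncated at 61 bpm so
    every instantaneous rate stays strictly above 60 bpm.

    Parameters
    ----------
    n_beats : number of intervals to generate (>= 1).
    mean_hr : mean heart rate in bpm; must exceed 60.
    hr_sd : beat-to-beat heart-rate standard deviation in bpm.
    seed : master seed; the stream is private to this call.
    resp_amp_bpm : amplitude of the respiratory modulation (0 disables it).
    resp_hz : modulation frequency in Hz.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if mean_hr <= _SINUS_HR_MIN:
        raise ValueError(f"sinus mean_hr must exceed {_SINUS_HR_MIN} bpm, got {mean_hr}")
    rng = derive_rng(seed, 11)
    phase = rng.uniform(0, 2 * np.pi)
    hr_noise = rng.normal(0.0, hr_sd, size=n_beats)
    intervals = np.empty(n_beats)
    t = 0.0
    for k in range(n_beats):
        hr = mean_hr + hr_noise[k]
        if resp_amp_bpm:
            hr += resp_amp_bpm * np.sin(2 * np.pi * resp_hz * t + phase)
        hr = max(hr, _SINUS_HR_MIN + 1.0)
        intervals[k] = 60.0 / hr
        t += intervals[k]
    labels = np.full(n_beats, SINUS, dtype="U5")
    return RRSeries(intervals, labels, episode_bounds=None)


def _draw_episode_length(rng, lo: int, median: int, hi: int, sigma: float) -> int:
    """Truncated log-normal with the given median; resampled into [lo, hi]."""
    for _ in range(1000):
        n = int(round(np.exp(rng.normal(np.log(median), sigma))))
        if lo <= n <= hi:
            return n
    return median


def _episode_series(
    rhythm: str,
    seed: int,
    episode_beats,
    episode_hr,
    sinus_mean_hr: float,
    sinus_hr_sd: float,
    episode_hr_sd: float,
) -> RRSeries:
    rng = derive_rng(seed, 23 if rhythm == BRADY else 29)

    if rhythm == BRADY:
        lo, med, hi = _BRADY_LEN
        sigma = _BRADY_LEN_SIGMA
        hr_median = _BRADY_HR_MEDIAN
        band = _BRADY_HR_BAND
    else:
        lo, med, hi = _TACHY_LEN
        sigma = _TACHY_LEN_SIGMA
        hr_median = _TACHY_HR_MEDIAN
        band = (_TACHY_HR_MIN, 220.0)

    if episode_beats == "random":
        n_ep = _draw_episode_length(rng, lo, med, hi, sigma)
    else:
        n_ep = int(episode_beats)
        if not lo <= n_ep <= hi:
            raise ValueError(f"{rhythm} episode length must lie in [{lo}, {hi}] beats")

    if episode_hr == "random":
        hr_ep = float(np.clip(rng.normal(hr_median, 4.0), band[0], band[1]))
    else:
        hr_ep = float(episode_hr)
        if rhythm == BRADY and not band[0] <= hr_ep <= band[1]:
            raise ValueError(f"bradycardia episode HR must lie in [{band[0]}, {band[1]}] bpm")
        if rhythm == TACHY and hr_ep < _TACHY_HR_MIN:
            raise ValueError(f"tachycardia episode HR must be >= {_TACHY_HR_MIN} bpm")

    n_before = int(rng.integers(50, 101))
    n_after = int(rng.integers(1, 101))

    before = generate_sinus_rr(
        n_before, sinus_mean_hr, sinus_hr_sd, seed=int(rng.integers(2**31))
    )
    after = generate_sinus_rr(
        n_after, sinus_mean_hr, sinus_hr_sd, seed=int(rng.integers(2**31))
    )

    # within-episode beat-to-beat variability, clipped to the rhythm's band
    hr_beats = rng.normal(hr_ep, episode_hr_sd, size=n_ep)
    if rhythm == BRADY:
        hr_beats = np.clip(hr_beats, band[0], band[1] - 0.5)
    else:
        hr_beats = np.clip(hr_beats, _TACHY_HR_MIN + 0.5, band[1])
    ep_intervals = 60.0 / hr_beats

    intervals = np.concatenate([before.intervals, ep_intervals, after.intervals])
    labels = np.concatenate(
        [before.labels, np.full(n_ep, rhythm, dtype="U5"), after.labels]
    )
    bounds = (n_before, n_before + n_ep)
    return RRSeries(intervals, labels, episode_bounds=bounds)


def generate_bradycardia_series(
    seed: int = 0,
    episode_beats="random",
    episode_hr="random",
    sinus_mean_hr: float = 75.0,
    sinus_hr_sd: float = 3.0,
    episode_hr_sd: float = 1.5,
) -> RRSeries:
    """Sinus | bradycardia | sinus series with one embedded episode.

    When "random", the episode length is drawn so its median is ~23 beats
    within [8, 51] and the episode heart rate so its median is ~36 bpm
    within [25, 40].  ``episode_hr_sd`` sets within-episode variability
    (not pinned by the emulated statistics; exposed as a parameter).
    """
    return _episode_series(
        BRADY, seed, episode_beats, episode_hr, sinus_mean_hr, sinus_hr_sd, episode_hr_sd
    )


def generate_tachycardia_series(
    seed: int = 0,
    episode_beats="random",
    episode_hr="random",
    sinus_mean_hr: float = 75.0,
    sinus_hr_sd: float = 3.0,
    episode_hr_sd: float = 2.0,
) -> RRSeries:
    """Sinus | ventricular tachycardia | sinus series with one episode.

    Episode heart rate is >= 120 bpm for every beat (median ~164 when
    "random"); episode length median ~14 beats within [4, 528].
    """
    return _episode_series(
        TACHY, seed, episode_beats, episode_hr, sinus_mean_hr, sinus_hr_sd, episode_hr_sd
    )
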