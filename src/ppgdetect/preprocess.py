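"""Preprocessing: bandpass, adaptive baseline removal, 5-s segmentation.

The bandpass is a 4th-order Butterworth applied forward-backward (zero
phase) so segment boundaries stay aligned with annotations.  Baseline
wander is removed with a single-coefficient normalized LMS filter whose
reference input is the constant 1; the adaptive weight then tracks the
signal's slowly varying mean and is subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from ppgdetect.ppg_sim import PPGSignal

OTHER = "other"


@dataclass
class Segment:
    """One non-overlapping analysis window (win_s seconds of samples)."""

    samples: np.ndarray
    index: int
    start_s: float
    label: str = OTHER            # {"brady", "tachy", "other"}
    quality: str = "unassessed"   # {"good", "poor", "unassessed"}

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


def bandpass(ppg: PPGSignal, low_hz: float = 0.5, high_hz: float = 40.0, order: int = 4) -> PPGSignal:
    """Zero-phase Butterworth bandpass; passband gain ~1."""
    nyq = ppg.fs / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(f"cutoffs must satisfy 0 < {low_hz} < {high_hz} < {nyq}")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=ppg.fs, output="sos")
    return ppg.copy_with(sps.sosfiltfilt(sos, ppg.samples))


def remove_baseline_nlms(ppg: PPGSignal, step: float = 0.02, reg: float = 1e-6) -> PPGSignal:
    """Single-tap NLMS with constant reference input 1.

    The recursion w[n+1] = w[n] + step * e[n] / (reg + 1), e[n] = x[n] - w[n]
    is a first-order IIR in w, so it is evaluated with a vectorized linear
    filter.  The weight is initialized to the first sample to shorten the
    start-up transient; the output is the error signal e.
    """
    if not 0 < step < 2:
        raise ValueError("NLMS step must lie in (0, 2)")
    x = ppg.samples
    if len(x) == 0:
        return ppg.copy_with(x.copy())
    mu = step / (reg + 1.0)
    # w[n+1] = (1 - mu) w[n] + mu x[n]  ->  one-pole low-pass of x
    b, a = [0.0, mu], [1.0, -(1.0 - mu)]
    zi = sps.lfiltic(b, a, y=[x[0]], x=[x[0]])
    w, _ = sps.lfilter(b, a, x, zi=zi)
    return ppg.copy_with(x - w)


def segment(ppg: PPGSignal, win_s: float = 5.0) -> list[Segment]:
    """Cut into floor(duration / win_s) non-overlapping windows.

    The trailing remainder shorter than one window is discarded; labels
    and quality are left unassigned.
    """
    if win_s <= 0:
        raise ValueError("win_s must be positive")
    n_win = int(round(win_s * ppg.fs))
    n_seg = len(ppg.samples) // n_win
    return [
        Segment(ppg.samples[i * n_win : (i + 1) * n_win], index=i, start_s=i * win_s)
        for i in range(n_seg)
    ]
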