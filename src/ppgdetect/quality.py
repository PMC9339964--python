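"""Spectral signal-quality assessment of 5-s segments.

A segment is usable when its largest spectral peak falls inside
0.6–3 Hz — the band corresponding to 3–15 beats within 5 s.  Anything
outside (baseline drift below, artifact energy above) marks the segment
poor and excludes it from CNN detection.
"""

from __future__ import annotations

import numpy as np

from ppgdetect.preprocess import Segment

GOOD = "good"
POOR = "poor"


def dominant_frequency(
    seg: Segment, fs: float = 100.0, zero_pad_factor: int = 4
) -> float | None:
    """Frequency (Hz) of the largest spectral peak, or None for a flat segment.

    Periodogram with mean removal, a Hann window and zero padding (default
    4x, ~0.05 Hz resolution on a 5-s window); DC is excluded.  The peak
    location is refined by parabolic interpolation of the log spectrum so
    the estimate is not quantized to the frequency grid (a pulse
    fundamental sitting exactly on a band edge must not be pushed across
    it by binning).
    """
    x = seg.samples - seg.samples.mean()
    if not np.any(x):
        return None
    n = len(x)
    n_fft = int(2 ** np.ceil(np.log2(n * zero_pad_factor)))
    windowed = x * np.hanning(n)
    spec = np.abs(np.fft.rfft(windowed, n_fft)) ** 2
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    spec[0] = 0.0  # exclude DC
    k = int(np.argmax(spec))
    if 0 < k < len(spec) - 1 and spec[k - 1] > 0 and spec[k + 1] > 0:
        y0, y1, y2 = np.log(spec[k - 1 : k + 2])
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return float((k + delta) * fs / n_fft)


def assess_quality(
    seg: Segment,
    band: tuple[float, float] = (0.6, 3.0),
    fs: float = 100.0,
) -> str:
    """"good" iff the dominant peak lies inside ``band`` (inclusive)."""
    f = dominant_frequency(seg, fs=fs)
    if f is None:
        return POOR
    return GOOD if band[0] <= f <= band[1] else POOR
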