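"""Continuous wavelet transform scalograms with generalized Morse wavelets.

The analyzing wavelet is the analytic generalized Morse wavelet, defined in
the frequency domain as

    Psi(w) = U(w) * a_{beta,gamma} * w**beta * exp(-w**gamma),   w > 0,

with gamma = 3 and time-bandwidth product P^2 = beta * gamma = 60 by
default (the symmetric, Airy-like member commonly used for time-frequency
analysis).  Sixty-one logarithmically spaced scales at 10 voices per
octave span six octaves up to 12 Hz, which covers the pulse fundamental
from deep bradycardia (~0.4 Hz) through fast tachycardia (~3 Hz) plus
harmonics.  A 5-s segment at 100 Hz therefore yields a 500 x 61 magnitude
image (time x scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ppgdetect.config import ScalogramConfig
from ppgdetect.preprocess import Segment


@dataclass
class Scalogram:
    """CWT magnitude image: rows are time samples, columns are scales."""

    magnitudes: np.ndarray   # (n_samples, n_scales), non-negative
    freqs: np.ndarray        # (n_scales,) center frequencies, ascending

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.magnitudes.ndim != 2 or self.magnitudes.shape[1] != len(self.freqs):
            raise ValueError("magnitudes must be (n_samples, n_scales)")
        if not np.all(np.isfinite(self.magnitudes)) or np.any(self.magnitudes < 0):
            raise ValueError("magnitudes must be finite and non-negative")
        if not np.all(np.diff(self.freqs) > 0):
            raise ValueError("freqs must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.magnitudes.shape

    def ridge_frequency(self) -> float:
        """Frequency of the scale with the largest total energy."""
        energy = (self.magnitudes**2).sum(axis=0)
        return float(self.freqs[int(np.argmax(energy))])

    def normalized(self) -> np.ndarray:
        """Per-image min-max scaling to [0, 1] (CNN input convention)."""
        m = self.magnitudes
        lo, hi = m.min(), m.max()
        if hi == lo:
            return np.zeros_like(m)
        return (m - lo) / (hi - lo)


def morse_frequencies(cfg: ScalogramConfig | None = None) -> np.ndarray:
    """Center frequencies (Hz, ascending) of the configured scale bank."""
    cfg = cfg or ScalogramConfig()
    n_octaves = (cfg.n_scales - 1) / cfg.voices_per_octave
    exps = np.arange(cfg.n_scales) / cfg.voices_per_octave
    return cfg.freq_max * 2.0 ** (exps - n_octaves)  # ascending, freq_max/2^6 .. freq_max


def _morse_filters(n_fft: int, fs: float, cfg: ScalogramConfig) -> tuple[np.ndarray, np.ndarray]:
    gamma = cfg.morse_gamma
    beta = cfg.morse_time_bandwidth / gamma
    w_peak = (beta / gamma) ** (1.0 / gamma)  # radian peak frequency of the mother wavelet
    freqs = morse_frequencies(cfg)
    scales = w_peak * fs / (2 * np.pi * freqs)  # samples per radian

    w = 2 * np.pi * np.fft.fftfreq(n_fft)       # radian frequency per sample
    filters = np.zeros((len(scales), n_fft))
    pos = w > 0
    # peak-normalized: log-domain evaluation avoids overflow for large beta
    ln_peak = beta * np.log(w_peak) - w_peak**gamma
    for i, s in enumerate(scales):
        sw = s * w[pos]
        filters[i, pos] = 2.0 * np.exp(beta * np.log(sw) - sw**gamma - ln_peak)
    return filters, freqs


def cwt_scalogram(
    seg: Segment,
    cfg: ScalogramConfig | None = None,
    fs: float = 100.0,
    n_samples: int = 500,
) -> Scalogram:
    """Morse-wavelet scalogram of one segment.

    Zero padding of one segment length on each side isolates the segment
    from circular wrap-around: long low-frequency wavelets then see
    silence beyond the window instead of an artificial extension whose
    joins would dominate the low scales.  The cone of influence is kept
    (the CNN consumes the full image).  Deterministic for fixed input and
    configuration.
    """
    cfg = cfg or ScalogramConfig()
    x = np.asarray(seg.samples, dtype=float)
    if len(x) != n_samples:
        raise ValueError(f"expected {n_samples} samples, got {len(x)}")
    n = len(x)
    pad = np.zeros(n)
    padded = np.concatenate([pad, x - x.mean(), pad])
    n_fft = len(padded)
    filters, freqs = _filters_cached(n_fft, fs, cfg)
    spec = np.fft.fft(padded)
    coeffs = np.fft.ifft(spec[None, :] * filters, axis=1)[:, n : 2 * n]
    mags = np.abs(coeffs).T  # (time, scale), freqs ascending
    return Scalogram(mags, freqs)


_FILTER_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _filters_cached(n_fft: int, fs: float, cfg: ScalogramConfig):
    key = (
        n_fft, fs, cfg.n_scales, cfg.voices_per_octave, cfg.freq_max,
        cfg.morse_gamma, cfg.morse_time_bandwidth,
    )
    if key not in _FILTER_CACHE:
        _FILTER_CACHE[key] = _morse_filters(n_fft, fs, cfg)
    return _FILTER_CACHE[key]
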