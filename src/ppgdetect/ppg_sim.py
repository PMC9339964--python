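"""PPG waveform synthesis from RR-interval series.

Each beat contributes one pulse — a linear combination of a log-normal and
two Gaussian waveforms expressed in normalized beat time, so the pulse
shape time-scales with its RR interval (fast systolic upstroke, then a
dicrotic shoulder).  Pulses are placed at cumulative RR onsets and
overlap-added into a connected signal.  Stationary colored noise (white
Gaussian shaped by a one-pole low-pass) can be added at a requested SNR.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from ppgdetect.config import NoiseConfig, PulseShapeConfig, derive_rng
from ppgdetect.rr_synthesis import RRSeries, TACHY

CLEAN = "clean"


@dataclass
class PulseModel:
    """Log-normal + two-Gaussian pulse in normalized beat time tau in [0, 1]."""

    lognormal_amp: float = PulseShapeConfig.lognormal_amp
    lognormal_mode: float = PulseShapeConfig.lognormal_mode
    lognormal_shape: float = PulseShapeConfig.lognormal_shape
    gauss1_amp: float = PulseShapeConfig.gauss1_amp
    gauss1_center: float = PulseShapeConfig.gauss1_center
    gauss1_width: float = PulseShapeConfig.gauss1_width
    gauss2_amp: float = PulseShapeConfig.gauss2_amp
    gauss2_center: float = PulseShapeConfig.gauss2_center
    gauss2_width: float = PulseShapeConfig.gauss2_width
    tachy_attenuation: float = PulseShapeConfig.tachy_attenuation

    def __post_init__(self) -> None:
        if self.lognormal_shape <= 0 or self.gauss1_width <= 0 or self.gauss2_width <= 0:
            raise ValueError("pulse widths/shape must be positive")
        if self.lognormal_amp == 0 and self.gauss1_amp == 0 and self.gauss2_amp == 0:
            raise ValueError("all pulse component amplitudes are zero")

    @classmethod
    def from_config(cls, cfg: PulseShapeConfig) -> "PulseModel":
        return cls(
            cfg.lognormal_amp, cfg.lognormal_mode, cfg.lognormal_shape,
            cfg.gauss1_amp, cfg.gauss1_center, cfg.gauss1_width,
            cfg.gauss2_amp, cfg.gauss2_center, cfg.gauss2_width,
            cfg.tachy_attenuation,
        )


@dataclass
class PPGSignal:
    """Uniformly sampled PPG waveform with optional rhythm annotations.

    ``annotations`` is a list of (start_s, end_s, rhythm) intervals,
    half-open in seconds from record start.
    """

    samples: np.ndarray
    fs: float = 100.0
    annotations: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("PPG samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def copy_with(self, samples: np.ndarray) -> "PPGSignal":
        return PPGSignal(samples, self.fs, list(self.annotations))

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["value"])
            for v in self.samples:
                w.writerow([f"{v:.8g}"])

    def annotations_to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                [{"start_s": s, "end_s": e, "rhythm": r} for s, e, r in self.annotations],
                fh,
                indent=1,
            )


def _lognormal_pdf(tau: np.ndarray, mode: float, shape: float) -> np.ndarray:
    # parameterized by the mode so the systolic peak lands where configured
    scale = mode * np.exp(shape**2)
    out = np.zeros_like(tau)
    pos = tau > 0
    z = (np.log(tau[pos] / scale)) / shape
    out[pos] = np.exp(-0.5 * z**2) / tau[pos]
    return out


def render_pulse(model: PulseModel, rr: float, fs: float = 100.0) -> np.ndarray:
    """One pulse of duration ``rr`` seconds sampled at ``fs``, peak 1."""
    if rr <= 0:
        raise ValueError("rr must be positive")
    n = int(round(rr * fs))
    if n < 2:
        raise ValueError(f"rr={rr} s is below two samples at fs={fs} Hz")
    tau = np.arange(n) / n

    def _unit(x: np.ndarray) -> np.ndarray:
        m = x.max()
        return x / m if m > 0 else x

    wave = (
        model.lognormal_amp * _unit(_lognormal_pdf(tau, model.lognormal_mode, model.lognormal_shape))
        + model.gauss1_amp * np.exp(-0.5 * ((tau - model.gauss1_center) / model.gauss1_width) ** 2)
        + model.gauss2_amp * np.exp(-0.5 * ((tau - model.gauss2_center) / model.gauss2_width) ** 2)
    )
    peak = wave.max()
    if peak <= 0:
        raise ValueError("degenerate pulse model: non-positive peak")
    return wave / peak


def simulate_ppg(rr: RRSeries, model: PulseModel | None = None, fs: float = 100.0) -> PPGSignal:
    """Overlap-add one pulse per beat at cumulative RR onsets.

    Placement uses cumulative time (start index = round(onset * fs)) so
    rounding does not accumulate drift; each pulse's support equals its own
    RR interval.  Episode bounds on the RR series become half-open
    (start_s, end_s, rhythm) annotations on the signal.
    """
    if len(rr) == 0:
        raise ValueError("empty RRSeries")
    model = model or PulseModel()
    onsets = np.concatenate([[0.0], np.cumsum(rr.intervals)])
    total = int(round(onsets[-1] * fs))
    buf = np.zeros(total)
    for k, rr_k in enumerate(rr.intervals):
        start = int(round(onsets[k] * fs))
        pulse = render_pulse(model, rr_k, fs)
        if model.tachy_attenuation != 1.0 and rr.labels[k] == TACHY:
            pulse = pulse * model.tachy_attenuation
        stop = min(start + len(pulse), total)
        buf[start:stop] += pulse[: stop - start]
    annotations = []
    ep = rr.episode_interval_s()
    if ep is not None:
        annotations.append(ep)
    return PPGSignal(buf, fs, annotations)


def add_noise(ppg: PPGSignal, snr_db, seed: int = 0, cfg: NoiseConfig | None = None) -> PPGSignal:
    """Add stationary colored noise at the requested SNR (dB).

    SNR is total signal power over total noise power; ``snr_db="clean"``
    (or None) returns the signal unchanged.  The noise is white Gaussian
    shaped by a first-order low-pass (~6 dB/octave above the corner).
    """
    if snr_db is None or (isinstance(snr_db, str) and snr_db.lower() == CLEAN):
        return ppg.copy_with(ppg.samples.copy())
    snr_db = float(snr_db)
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite or 'clean'")
    cfg = cfg or NoiseConfig()
    rng = derive_rng(seed, 37)
    white = rng.standard_normal(len(ppg.samples))
    b, a = sps.butter(1, cfg.corner_hz, btype="low", fs=ppg.fs)
    noise = sps.lfilter(b, a, white)
    p_sig = np.mean(ppg.samples**2)
    p_noise = np.mean(noise**2)
    if p_noise == 0 or p_sig == 0:
        return ppg.copy_with(ppg.samples.copy())
    noise *= np.sqrt(p_sig / (p_noise * 10.0 ** (snr_db / 10.0)))
    return ppg.copy_with(ppg.samples + noise)
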