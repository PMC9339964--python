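"""Run-time configuration: every tunable of the pipeline in one document.

Defaults equal the method's published operating values wherever such a value
exists (filter bands, segment length, sampling rate, CNN architecture,
learning rate, data split, quality thresholds, rate/duration rules, overlap
labelling fractions).  Everything else — pulse-shape parameters, NLMS step,
Morse wavelet parameters, early-stopping policy — is an explicit assumption
and lives here rather than in code.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


@dataclass
class FilterConfig:
    """Preprocessing filter settings."""

    fs: float = 100.0               # Hz, working sampling rate
    bandpass_low: float = 0.5       # Hz, CNN path
    bandpass_high: float = 40.0     # Hz, CNN path
    reference_low: float = 0.5      # Hz, pulse-detector path
    reference_high: float = 6.0     # Hz, pulse-detector path
    order: int = 4                  # Butterworth order (applied forward-backward)
    nlms_step: float = 0.02         # NLMS step size, constant reference input 1
    nlms_reg: float = 1e-6          # NLMS regularization


@dataclass
class SegmentConfig:
    win_s: float = 5.0              # non-overlapping analysis window


@dataclass
class QualityConfig:
    band_low: float = 0.6           # Hz, inclusive
    band_high: float = 3.0          # Hz, inclusive
    zero_pad_factor: int = 4        # periodogram zero padding


@dataclass
class PulseShapeConfig:
    """Default parameters of the log-normal + two-Gaussian pulse model.

    Times are fractions of the beat's RR interval so the pulse always fits
    its beat; amplitudes are relative to the systolic (log-normal) peak.
    """

    lognormal_amp: float = 1.0
    lognormal_mode: float = 0.20    # systolic peak at ~20% of RR
    lognormal_shape: float = 0.40
    gauss1_amp: float = 0.55        # shoulder between peak and notch
    gauss1_center: float = 0.34
    gauss1_width: float = 0.11
    gauss2_amp: float = 0.30        # dicrotic wave
    gauss2_center: float = 0.48
    gauss2_width: float = 0.10
    tachy_attenuation: float = 1.0  # pulse amplitude factor within tachycardia (1 = off)


@dataclass
class NoiseConfig:
    """Stationary additive noise: Gaussian shaped by a one-pole low-pass."""

    corner_hz: float = 4.0          # ~6 dB/octave roll-off above this corner


@dataclass
class ScalogramConfig:
    n_scales: int = 61
    voices_per_octave: int = 10     # 61 scales at 10 v/o span exactly 6 octaves
    freq_max: float = 12.0          # Hz; freq_min = freq_max / 2**6
    morse_gamma: float = 3.0
    morse_time_bandwidth: float = 60.0  # P^2 = beta * gamma
    normalize: bool = True          # per-image min-max to [0, 1] for the CNN


@dataclass
class CNNConfig:
    brady_kernel: int = 13
    tachy_kernel: int = 5
    n_kernels: int = 32
    dense_units: int = 256
    dropout: float = 0.5
    learning_rate: float = 0.01
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 5               # epochs without validation-accuracy gain
    train_fraction: float = 0.70    # 70/30 train/validation
    brady_threshold: float = 0.5
    tachy_threshold: float = 0.5


@dataclass
class ReferenceConfig:
    eta_c: float = 0.6              # pulse-quality correlation threshold (strict >)
    brady_bpm: float = 40.0         # strict <
    tachy_bpm: float = 120.0        # strict >
    min_beats: int = 3
    refractory_s: float = 0.3
    amp_factor: float = 0.5         # detection threshold vs averaged peak amplitude
    amp_memory: float = 0.9         # exponential averaging of peak amplitudes
    template_len: int = 100         # samples per resampled pulse
    template_history: int = 8       # accepted pulses averaged into the template
    max_lag: int = 5                # +- lag range for the correlation maximum
    rate_decimals: int = 1          # instantaneous HR rounded before rule checks


@dataclass
class LabelConfig:
    brady_overlap: float = 0.50     # episode must cover >= 50% of the window
    tachy_overlap: float = 0.25     # episode must cover >= 25% of the window


@dataclass
class RunConfig:
    """Aggregate configuration; serializable to/from YAML."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    quality: QualityConfig = field(default_factory=QualityConfig)
    pulse: PulseShapeConfig = field(default_factory=PulseShapeConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    scalogram: ScalogramConfig = field(default_factory=ScalogramConfig)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    reference: ReferenceConfig = field(default_factory=ReferenceConfig)
    label: LabelConfig = field(default_factory=LabelConfig)
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        kwargs: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            val = raw[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in _SECTIONS:
                section_cls = _SECTIONS[f.name]
                unknown = set(val) - {sf.name for sf in dataclasses.fields(section_cls)}
                if unknown:
                    raise ValueError(f"unknown config fields {sorted(unknown)} in section '{f.name}'")
                kwargs[f.name] = section_cls(**val)
            else:
                kwargs[f.name] = val
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config sections {sorted(unknown)}")
        return cls(**kwargs)


_SECTIONS = {
    "filter": FilterConfig,
    "segment": SegmentConfig,
    "quality": QualityConfig,
    "pulse": PulseShapeConfig,
    "noise": NoiseConfig,
    "scalogram": ScalogramConfig,
    "cnn": CNNConfig,
    "reference": ReferenceConfig,
    "label": LabelConfig,
}


def derive_rng(seed: int, *salt: int) -> "np.random.Generator":  # noqa: F821
    """One master seed, one named stream per purpose."""
    import numpy as np

    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *salt])
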