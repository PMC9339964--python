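import numpy as np
import pytest

from ppgdetect.ppg_sim import PulseModel, simulate_ppg
from ppgdetect.rr_synthesis import RRSeries


@pytest.fixture(scope="session")
def pulse_model():
    return PulseModel()


def constant_rr_series(hr_bpm: float, n_beats: int, label: str = "sinus") -> RRSeries:
    rr = np.full(n_beats, 60.0 / hr_bpm)
    return RRSeries(rr, np.full(n_beats, label, dtype="U5"))


@pytest.fixture(scope="session")
def make_constant_ppg(pulse_model):
    """Clean simulated PPG at a constant heart rate."""

    def _make(hr_bpm: float, duration_s: float = 60.0):
        n = int(np.ceil(duration_s * hr_bpm / 60.0)) + 1
        return simulate_ppg(constant_rr_series(hr_bpm, n), pulse_model)

    return _make


@pytest.fixture
def tone_segment():
    """5-s pure-tone Segment at 100 Hz."""
    from ppgdetect.preprocess import Segment

    def _make(freq_hz: float, amp: float = 1.0, fs: float = 100.0):
        t = np.arange(500) / fs
        return Segment(amp * np.sin(2 * np.pi * freq_hz * t), index=0, start_s=0.0)

    return _make
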