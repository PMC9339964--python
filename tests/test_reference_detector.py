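import numpy as np
import pytest

from ppgdetect.evaluation import sens_spec
from ppgdetect.pipeline import ground_truth_labels, simulate_record
from ppgdetect.ppg_sim import PPGSignal, simulate_ppg
from ppgdetect.reference_detector import (
    Episode,
    PulseTrain,
    assess_pulse_quality,
    detect_episodes,
    detect_pulses,
    episodes_to_segments,
)

from conftest import constant_rr_series


def train_from_rates(rates_bpm, accepted=None):
    """Build a PulseTrain whose interval rates are exactly ``rates_bpm``."""
    times = np.concatenate([[0.0], np.cumsum([60.0 / r for r in rates_bpm])])
    acc = np.ones(len(times), bool) if accepted is None else np.asarray(accepted, bool)
    return PulseTrain(times, np.ones(len(times)), acc)


class TestPulseDetection:
    def test_counts_beats_at_60_bpm(self):
        ppg = simulate_ppg(constant_rr_series(60, 61))
        train = detect_pulses(ppg)
        assert abs(len(train) - 61) <= 1

    def test_slow_rhythm_intervals_accurate(self):
        ppg = simulate_ppg(constant_rr_series(30, 31))
        train = detect_pulses(ppg)
        intervals = np.diff(train.times)
        assert np.all(np.abs(intervals - 2.0) <= 0.05)

    def test_flat_signal_empty_train(self):
        assert len(detect_pulses(PPGSignal(np.zeros(3000), 100.0))) == 0

    def test_refractory_prevents_double_detections(self):
        ppg = simulate_ppg(constant_rr_series(75, 60))
        train = detect_pulses(ppg)
        assert np.all(np.diff(train.times) >= 0.3)


class TestPulseQuality:
    def test_identical_pulses_all_accepted(self):
        ppg = simulate_ppg(constant_rr_series(70, 50))
        train = assess_pulse_quality(detect_pulses(ppg), ppg)
        assert train.accepted.all()
        assert np.all(train.correlations[2:] > 0.99)

    def test_noise_burst_pulse_rejected(self):
        rng = np.random.default_rng(0)
        ppg = simulate_ppg(constant_rr_series(70, 50))
        x = ppg.samples.copy()
        # replace one mid-record beat with white noise
        x[2000:2086] = rng.standard_normal(86) * 0.5
        noisy = PPGSignal(x, 100.0)
        train = assess_pulse_quality(detect_pulses(noisy), noisy)
        bad = (train.times > 19.5) & (train.times < 21.5)
        assert (~train.accepted[bad]).any()

    def test_acceptance_flag_consistent_with_threshold(self):
        ppg = simulate_ppg(constant_rr_series(70, 40))
        train = assess_pulse_quality(detect_pulses(ppg), ppg)
        np.testing.assert_array_equal(train.accepted[1:], train.correlations[1:] > 0.6)

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            assess_pulse_quality(PulseTrain(np.empty(0)), PPGSignal(np.zeros(100), 100.0))


class TestEpisodeRules:
    def test_three_slow_beats_make_one_episode(self):
        eps = detect_episodes(train_from_rates([40, 35, 36, 38, 70]))
        assert len(eps) == 1
        assert eps[0].rhythm == "brady" and eps[0].n_beats == 3

    def test_two_fast_beats_are_not_an_episode(self):
        assert detect_episodes(train_from_rates([75, 150, 150, 75, 72, 70])) == []

    def test_exactly_40_bpm_is_not_bradycardia(self):
        assert detect_episodes(train_from_rates([40.0] * 10)) == []

    def test_exactly_120_bpm_is_not_tachycardia(self):
        assert detect_episodes(train_from_rates([120.0] * 10)) == []

    def test_sustained_fast_run_detected(self):
        eps = detect_episodes(train_from_rates([75, 160, 165, 158, 161, 80]))
        assert len(eps) == 1
        assert eps[0].rhythm == "tachy" and eps[0].n_beats == 4

    def test_rejected_pulse_breaks_run(self):
        acc = np.ones(8, bool)
        acc[3] = False  # pulse inside the slow run is low quality
        eps = detect_episodes(train_from_rates([35, 36, 35, 36, 35, 70, 70], acc))
        assert eps == []  # longest clean run is 2 intervals

    def test_no_episode_contains_rejected_pulse(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            rates = rng.uniform(30, 180, 30)
            acc = rng.random(31) > 0.2
            train = train_from_rates(rates, acc)
            for e in detect_episodes(train):
                inside = (train.times >= e.start_s) & (train.times <= e.end_s)
                assert train.accepted[inside].all()

    def test_minimum_episode_size_enforced(self):
        with pytest.raises(ValueError):
            Episode("brady", 0.0, 5.0, 2)


class TestSegmentMapping:
    def test_full_coverage_labels_segments(self):
        eps = [Episode("brady", 50.0, 65.0, 5)]
        labels = episodes_to_segments(eps, 20)
        assert list(np.flatnonzero(labels == "brady")) == [10, 11, 12]

    def test_partial_overlap_below_half_is_other(self):
        eps = [Episode("brady", 0.0, 2.0, 3)]  # 40% of segment 0
        labels = episodes_to_segments(eps, 2)
        assert list(labels) == ["other", "other"]

    def test_tachy_quarter_overlap_suffices(self):
        eps = [Episode("tachy", 0.0, 1.25, 4)]
        labels = episodes_to_segments(eps, 2)
        assert list(labels) == ["tachy", "other"]

    def test_no_episodes_all_other(self):
        assert np.all(episodes_to_segments([], 7) == "other")


class TestEndToEndCleanRecords:
    def test_bradycardia_segment_agreement_on_clean_records(self):
        """Pooled over seeds: boundary beats at the 40-bpm limit may cost a
        single edge segment on one record, so the bound is on aggregate
        performance across records."""
        preds, truths = [], []
        for seed in range(5):
            ppg = simulate_record("brady", seed=seed)
            train = assess_pulse_quality(detect_pulses(ppg), ppg)
            episodes = detect_episodes(train)
            n_seg = int(ppg.duration_s // 5)
            preds.append(episodes_to_segments(episodes, n_seg))
            truths.append(ground_truth_labels(ppg, n_seg))
        pred = np.concatenate(preds)
        truth = np.concatenate(truths)
        se, sp, _ = sens_spec(pred, truth, "brady")
        assert se >= 0.9
        assert sp >= 0.95
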