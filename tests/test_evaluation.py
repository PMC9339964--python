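import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppgdetect.evaluation import (
    cohens_kappa,
    label_segments,
    performance_report,
    roc_sweep,
    sens_spec,
)

LABELS = ["brady", "tachy", "other"]


class TestLabelSegments:
    def test_half_overlap_assigns_bradycardia(self):
        labels = label_segments([(0.0, 2.5, "brady")], 2)
        assert list(labels) == ["brady", "other"]

    def test_quarter_overlap_assigns_tachycardia(self):
        labels = label_segments([(3.75, 5.0, "tachy")], 2)
        assert list(labels) == ["tachy", "other"]

    def test_sub_half_bradycardia_overlap_is_other(self):
        labels = label_segments([(0.0, 2.0, "brady")], 1)
        assert list(labels) == ["other"]

    def test_overlapping_rhythm_annotations_rejected(self):
        with pytest.raises(ValueError):
            label_segments([(0.0, 10.0, "brady"), (8.0, 15.0, "tachy")], 3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(start=st.floats(0, 40), dur=st.floats(0.1, 30))
    def test_total_label_time_never_exceeds_episode(self, start, dur):
        labels = label_segments([(start, start + dur, "tachy")], 10)
        # an episode can label at most its own span plus one window on each side
        assert (labels == "tachy").sum() * 5.0 <= dur + 10.0


class TestSensSpec:
    def test_perfect_prediction(self):
        t = np.array(["brady", "other", "brady", "other"])
        se, sp, _ = sens_spec(t, t, "brady")
        assert se == 1.0 and sp == 1.0

    def test_worked_counts(self):
        truth = np.array(["brady"] * 4 + ["other"] * 6)
        pred = np.array(["brady"] * 3 + ["other"] + ["brady"] + ["other"] * 5)
        se, sp, (se_ci, sp_ci) = sens_spec(pred, truth, "brady")
        assert se == pytest.approx(0.75)
        assert sp == pytest.approx(5 / 6)
        assert se_ci[0] <= se <= se_ci[1]

    def test_all_other_predictions(self):
        truth = np.array(["brady"] * 3 + ["other"] * 7)
        pred = np.array(["other"] * 10)
        se, sp, _ = sens_spec(pred, truth, "brady")
        assert se == 0.0 and sp == 1.0

    def test_no_positives_gives_undefined_sensitivity(self):
        truth = np.array(["other"] * 5)
        se, sp, _ = sens_spec(truth, truth, "brady")
        assert se is None and sp == 1.0

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            truth = rng.choice(LABELS, n)
            pred = rng.choice(LABELS, n)
            rhythm = rng.choice(["brady", "tachy"])
            tp = fp = tn = fn = 0
            for p, t in zip(pred, truth):
                if t == rhythm:
                    tp, fn = tp + (p == rhythm), fn + (p != rhythm)
                else:
                    fp, tn = fp + (p == rhythm), tn + (p != rhythm)
            se, sp, _ = sens_spec(pred, truth, rhythm)
            assert se == (tp / (tp + fn) if tp + fn else None)
            assert sp == (tn / (tn + fp) if tn + fp else None)
            rep = performance_report(pred, truth, rhythm)
            assert (rep.tp, rep.fp, rep.tn, rep.fn) == (tp, fp, tn, fn)
            assert rep.tp + rep.fp + rep.tn + rep.fn == n


class TestCohensKappa:
    def test_identical_sequences(self):
        a = np.array(["brady", "other", "other", "tachy"] * 5)
        assert cohens_kappa(a, a) == pytest.approx(1.0)

    def test_independent_labels_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.choice(["x", "y"], 20000)
        b = rng.choice(["x", "y"], 20000)
        assert abs(cohens_kappa(a, b)) < 0.03

    def test_hand_computed_contingency(self):
        # contingency a=40, b=10, c=10, d=40 -> p_o=0.8, p_e=0.5, kappa=0.6
        a = np.array(["p"] * 50 + ["n"] * 50)
        b = np.array(["p"] * 40 + ["n"] * 10 + ["p"] * 10 + ["n"] * 40)
        assert cohens_kappa(a, b) == pytest.approx(0.6)

    def test_symmetry_and_label_renaming_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.choice(["brady", "other"], 300)
        b = rng.choice(["brady", "other"], 300)
        k = cohens_kappa(a, b)
        assert cohens_kappa(b, a) == pytest.approx(k)
        ren = {"brady": "B", "other": "O"}
        a2 = np.array([ren[x] for x in a])
        b2 = np.array([ren[x] for x in b])
        assert cohens_kappa(a2, b2) == pytest.approx(k)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(3)
        for _ in range(50):
            a = rng.choice(LABELS, 60)
            b = rng.choice(LABELS, 60)
            assert cohens_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))

    def test_degenerate_marginals_undefined(self):
        a = np.array(["x"] * 10)
        assert cohens_kappa(a, a) is None

    def test_bootstrap_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(4)
        a = rng.choice(["p", "n"], 200)
        flip = rng.random(200) < 0.15
        b = np.where(flip, np.where(a == "p", "n", "p"), a)
        k, (lo, hi) = cohens_kappa(a, b, ci=True, n_boot=200, seed=0)
        assert lo <= k <= hi


class TestROCSweep:
    def test_extreme_thresholds(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.99, 100)
        truth = rng.choice([0, 1], 100)
        pts = roc_sweep(p, truth, [0.0, 1.0])
        _, fpr0, se0 = pts[0]
        _, fpr1, se1 = pts[1]
        assert se0 == 1.0          # everything flagged
        assert se1 == 0.0 and fpr1 == 0.0

    def test_sensitivity_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        p = rng.random(500)
        truth = rng.choice([0, 1], 500)
        pts = roc_sweep(p, truth, np.linspace(0, 1, 21))
        ses = [se for _, _, se in pts]
        assert all(a >= b for a, b in zip(ses, ses[1:]))

    def test_perfect_separation_reaches_corner(self):
        p = np.array([0.1] * 50 + [0.9] * 50)
        truth = np.array([0] * 50 + [1] * 50)
        pts = roc_sweep(p, truth, [0.5])
        assert pts[0][1] == 0.0 and pts[0][2] == 1.0


class TestSNRExperiment:
    def test_minimal_clean_run_reports_valid_rates(self):
        from ppgdetect.cnn import TrainConfig
        from ppgdetect.evaluation import snr_experiment

        df = snr_experiment(
            ["clean"], n_sessions=2, seed=0, branch="tachy",
            n_train_pos=12, n_test_pos=8,
            train_cfg=TrainConfig(max_epochs=2, patience=1),
        )
        assert len(df) == 2
        assert df["sensitivity"].between(0, 1).all()
        assert df["specificity"].between(0, 1).all()
        assert "means" in df.attrs and "trend" in df.attrs

    def test_rejects_single_session(self):
        from ppgdetect.evaluation import snr_experiment

        with pytest.raises(ValueError):
            snr_experiment(["clean"], n_sessions=1, seed=0)
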