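"""Segment classifier: matrix building, training, prediction, persistence."""

import numpy as np
import pytest

from apneascreen import model, preprocessing, sequence_model
from apneascreen.io import ValidationError
from apneascreen.preprocessing import Segment, SegmentSet


def make_segset(sid, vectors, labels=None, w=60.0):
    segs = tuple(
        Segment(
            subject_id=sid,
            index=i + 1,
            values=np.asarray(v, dtype=float),
            start_s=i * w,
            end_s=(i + 1) * w,
            first_beat=1,
            last_beat=len(v),
            raw_values=np.abs(np.asarray(v, dtype=float)) + 0.5,
        )
        for i, v in enumerate(vectors)
    )
    out = SegmentSet(subject_id=sid, segments=segs, window_width_s=w)
    return out.with_labels(labels) if labels else out


def separable_data(n_per_class=40, seed=0, length=60):
    """Oscillating (A) vs flat-noise (N) standardized segments."""
    rng = np.random.default_rng(seed)
    t = np.arange(length)
    rows, labels = [], []
    for _ in range(n_per_class):
        rows.append(1.5 * np.sin(2 * np.pi * t / 30) + 0.1 * rng.normal(size=length))
        labels.append("A")
        rows.append(0.1 * rng.normal(size=length))
        labels.append("N")
    return rows, np.array(labels)


@pytest.fixture(scope="module")
def small_trained():
    rows, labels = separable_data()
    config = sequence_model.ModelConfig(epochs=30, seed=3, max_beats=60)
    return sequence_model.train(rows, labels, config), rows, labels


class TestConfig:
    def test_defaults_follow_the_tuned_configuration(self):
        cfg = sequence_model.ModelConfig()
        assert cfg.hidden_units == 32
        assert cfg.epochs == 150
        assert cfg.learning_rate == 0.01
        assert cfg.optimizer == "adam"

    def test_invalid_values_rejected(self):
        with pytest.raises(ValidationError):
            sequence_model.ModelConfig(hidden_units=0)
        with pytest.raises(ValidationError):
            sequence_model.ModelConfig(mode="cnn")


class TestBuildTrainingMatrix:
    def test_subject_then_segment_order(self):
        s1 = make_segset("s1", [[1.0] * 3, [2.0] * 4, [3.0] * 5], ["A", "N", "A"])
        s2 = make_segset("s2", [[4.0] * 3, [5.0] * 6], ["N", "N"])
        X, y = sequence_model.build_training_matrix([s1, s2])
        assert len(X) == 5
        assert list(y) == ["A", "N", "A", "N", "N"]
        assert [row[0] for row in X] == [1.0, 2.0, 3.0, 4.0, 5.0]

    def test_empty_subject_list_raises(self):
        with pytest.raises(ValidationError):
            sequence_model.build_training_matrix([])

    def test_unlabeled_segments_raise(self):
        with pytest.raises(ValidationError, match="unlabeled"):
            sequence_model.build_training_matrix([make_segset("s", [[1.0] * 3])])

    def test_mixed_window_widths_raise(self):
        a = make_segset("a", [[1.0] * 3], ["A"], w=60.0)
        b = make_segset("b", [[1.0] * 3], ["N"], w=30.0)
        with pytest.raises(ValidationError, match="window widths"):
            sequence_model.build_training_matrix([a, b])

    def test_permuting_subjects_permutes_row_blocks(self):
        s1 = make_segset("s1", [[1.0] * 3, [2.0] * 3], ["A", "N"])
        s2 = make_segset("s2", [[3.0] * 3], ["A"])
        X12, y12 = sequence_model.build_training_matrix([s1, s2])
        X21, y21 = sequence_model.build_training_matrix([s2, s1])
        assert [r[0] for r in X21] == [r[0] for r in X12[2:]] + [r[0] for r in X12[:2]]
        assert list(y21) == list(y12[2:]) + list(y12[:2])

    def test_hrv_mode_rows_are_11_features(self):
        segset = make_segset("s", [np.linspace(-1, 1, 70)], ["A"])
        X, _ = sequence_model.build_training_matrix([segset], mode="hrv_features")
        assert X[0].shape == (11,)


class TestTrain:
    def test_separable_task_high_training_accuracy(self, small_trained):
        trained, rows, labels = small_trained
        segset = make_segset("probe", rows)
        preds = sequence_model.predict(trained, segset)
        acc = np.mean(np.array(preds) == labels)
        assert acc > 0.95

    def test_single_class_raises(self):
        rows, _ = separable_data(n_per_class=5)
        with pytest.raises(ValidationError, match="single class"):
            sequence_model.train(
                rows, np.array(["A"] * len(rows)), sequence_model.ModelConfig(epochs=1)
            )

    def test_nan_input_raises(self):
        rows, labels = separable_data(n_per_class=3)
        rows[0] = np.array([np.nan] * 60)
        with pytest.raises(ValidationError, match="non-finite"):
            sequence_model.train(rows, labels, sequence_model.ModelConfig(epochs=1))

    def test_identical_seed_identical_predictions(self):
        rows, labels = separable_data(n_per_class=10)
        cfg = sequence_model.ModelConfig(epochs=5, seed=11, max_beats=60)
        m1 = sequence_model.train(rows, labels, cfg)
        m2 = sequence_model.train(rows, labels, cfg)
        probe = make_segset("p", rows)
        p1 = sequence_model.predict_proba(m1, probe)
        p2 = sequence_model.predict_proba(m2, probe)
        assert np.array_equal(p1, p2)

    def test_loss_curve_decreases(self, small_trained):
        trained, _, _ = small_trained
        assert trained.loss_curve[-1] < trained.loss_curve[0]

    def test_class_counts_logged(self, small_trained):
        trained, _, _ = small_trained
        assert trained.class_counts == {"A": 40, "N": 40}


class TestPredict:
    def test_empty_segmentset_gives_empty_labels(self, small_trained):
        trained, _, _ = small_trained
        empty = SegmentSet(subject_id="e", segments=(), window_width_s=60.0)
        assert sequence_model.predict(trained, empty) == []

    def test_duplicated_segment_same_label(self, small_trained):
        trained, rows, _ = small_trained
        twice = make_segset("d", [rows[0], rows[0]])
        labels = sequence_model.predict(trained, twice)
        assert labels[0] == labels[1]

    def test_unstandardized_input_warns(self, small_trained):
        trained, _, _ = small_trained
        shifted = make_segset("w", [np.full(60, 0.9)])  # raw seconds, mean 0.9
        with pytest.warns(UserWarning, match="standardiz"):
            sequence_model.predict(trained, shifted)

    def test_trimmed_and_untrimmed_padding_agree(self, small_trained):
        # prediction in small batches with per-batch trimming must match a
        # single full-width forward pass
        trained, rows, _ = small_trained
        from apneascreen import lstm

        segset = make_segset("p", rows[:7])
        probs = sequence_model.predict_proba(trained, segset)
        Xt, mask = sequence_model._pad_raw(rows[:7], trained.max_beats)
        direct = lstm.forward(trained.params, Xt, mask)
        assert np.allclose(probs, direct, atol=1e-6)


class TestPersistence:
    def test_save_load_round_trip(self, small_trained, tmp_path):
        trained, rows, _ = small_trained
        trained.save(tmp_path / "m.npz")
        loaded = sequence_model.TrainedModel.load(tmp_path / "m.npz")
        probe = make_segset("p", rows[:5])
        assert np.array_equal(
            sequence_model.predict_proba(trained, probe),
            sequence_model.predict_proba(loaded, probe),
        )
        assert loaded.config == trained.config


class TestRecoverability:
    def test_accuracy_nondecreasing_in_cvhr_amplitude(self):
        """Held-out accuracy grows with CVHR amplitude (majority of 3 seeds)."""
        from apneascreen import synthetic

        def heldout_accuracy(amp, seed):
            spec = synthetic.SyntheticCohortSpec(
                n_patients=3, n_healthy=2, record_duration_s=1800.0,
                cvhr_amp_s=amp, seed=seed,
            )
            cohort = synthetic.generate_cohort(spec)
            segsets = [
                preprocessing.label_segments(
                    model.prepare_segments(series, 60.0), events
                )
                for series, events, _ in cohort
            ]
            # subject-level split: P1 and H1 held out
            train_sets = [segsets[1], segsets[2], segsets[4]]
            test_sets = [segsets[0], segsets[3]]
            X, y = sequence_model.build_training_matrix(train_sets)
            cfg = sequence_model.ModelConfig(epochs=30, seed=seed)
            trained = sequence_model.train(X, y, cfg)
            correct = total = 0
            for t in test_sets:
                preds = np.array(sequence_model.predict(trained, t))
                correct += int(np.sum(preds == np.array(t.labels)))
                total += len(preds)
            return correct / total

        wins = 0
        for seed in (1, 2, 3):
            accs = [heldout_accuracy(a, seed) for a in (0.05, 0.15, 0.3)]
            if accs[0] <= accs[1] + 0.02 and accs[1] <= accs[2] + 0.02:
                wins += 1
        assert wins >= 2
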