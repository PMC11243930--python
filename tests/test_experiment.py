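"""Splits, MLP training, metric arithmetic, and the ablation harness."""
import warnings

import numpy as np
import pandas as pd
import pytest

import sleepderiv as sd
from sleepderiv import ValidationError
from sleepderiv.derivatives import FeatureMatrix
from sleepderiv.experiment import _metrics_from_confusion
from sleepderiv.series import AWAKE, SLEEP


def _toy_fm(n=1000, seed=0, n_windows=20):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "time_s": np.arange(n, dtype=float),
            "window_id": rng.integers(0, n_windows, size=n),
            "label": np.where(rng.random(n) < 0.5, SLEEP, AWAKE),
            "rri": rng.random(n),
        }
    )
    return FeatureMatrix(frame, ("rri",))


class TestSplits:
    def test_sample_mode_sizes_70_5_25(self):
        idx = sd.split_data(_toy_fm(1000), sd.SplitSpec(seed=1))
        assert len(idx["train"]) == 700
        assert len(idx["val"]) == 50
        assert len(idx["test"]) == 250

    def test_partition_disjoint_and_exhaustive(self):
        fm = _toy_fm(997)
        idx = sd.split_data(fm, sd.SplitSpec(seed=2))
        allidx = np.concatenate([idx["train"], idx["val"], idx["test"]])
        assert len(allidx) == 997
        assert len(np.unique(allidx)) == 997

    def test_grouped_mode_keeps_windows_whole(self):
        fm = _toy_fm(2000, n_windows=40)
        idx = sd.split_data(fm, sd.SplitSpec(mode="grouped", seed=3))
        wid = fm.window_ids
        seen = {}
        for name in idx:
            for w in np.unique(wid[idx[name]]):
                assert seen.setdefault(w, name) == name

    def test_same_seed_identical_splits(self):
        fm = _toy_fm(500)
        a = sd.split_data(fm, sd.SplitSpec(seed=9))
        b = sd.split_data(fm, sd.SplitSpec(seed=9))
        for k in a:
            assert np.array_equal(a[k], b[k])

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValidationError):
            sd.SplitSpec(train=0.8, val=0.1, test=0.2)


class TestTraining:
    def _clusters(self, n=600, sep=6.0, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 2)) * 0.3
        y = np.where(rng.random(n) < 0.5, SLEEP, AWAKE)
        X[y == SLEEP] += sep
        lo, hi = X.min(), X.max()
        return (X - lo) / (hi - lo), y

    def test_separable_clusters_reach_99_percent(self):
        X, y = self._clusters()
        cfg = sd.MLPConfig(epochs=30, seed=0)
        model = sd.train_classifier(X[:400], y[:400], X[400:500], y[400:500], cfg)
        m = sd.evaluate(model, X[500:], y[500:])
        assert m.accuracy >= 99.0

    def test_label_shuffle_gives_chance_accuracy(self):
        X, y = self._clusters(n=800, seed=1)
        rng = np.random.default_rng(2)
        y_shuf = y.copy()
        rng.shuffle(y_shuf[:600])
        cfg = sd.MLPConfig(epochs=20, seed=0)
        model = sd.train_classifier(X[:600], y_shuf[:600], X[600:650], y[600:650], cfg)
        m = sd.evaluate(model, X[650:], y[650:])
        majority = 100.0 * max(np.mean(y[650:] == SLEEP), np.mean(y[650:] == AWAKE))
        assert abs(m.accuracy - majority) <= 5.0

    def test_fixed_seed_reproduces_loss_trajectory(self):
        X, y = self._clusters(n=500, seed=3)
        cfg = sd.MLPConfig(epochs=8, seed=4)
        runs = [
            sd.train_classifier(X[:350], y[:350], X[350:400], y[350:400], cfg)
            for _ in range(2)
        ]
        assert runs[0].train_loss == runs[1].train_loss
        assert runs[0].val_loss == runs[1].val_loss

    def test_val_curve_mode_records_every_epoch(self):
        X, y = self._clusters(n=400, seed=5)
        cfg = sd.MLPConfig(epochs=5, seed=0)
        model = sd.train_classifier(
            X[:300], y[:300], X[300:350], y[300:350], cfg, val_curve=True
        )
        assert len(model.val_loss) == 5
        assert all(np.isfinite(model.val_loss))


class TestMetrics:
    def test_balanced_confusion_matrix_gives_80s(self):
        cm = np.array([[40, 10], [10, 40]])  # TP=TN=40, FP=FN=10
        m = _metrics_from_confusion(cm)
        assert m.accuracy == pytest.approx(80.0)
        assert m.precision == pytest.approx(80.0)
        assert m.recall == pytest.approx(80.0)
        assert m.f1 == pytest.approx(80.0)

    def test_perfect_predictions_score_100(self):
        y = np.array([AWAKE, SLEEP, SLEEP, AWAKE], dtype=object)
        m = sd.evaluate_predictions(y, np.array([0.1, 0.9, 0.8, 0.2]))
        assert (m.accuracy, m.precision, m.recall, m.f1) == (100.0, 100.0, 100.0, 100.0)

    def test_all_positive_predictor_on_balanced_set(self):
        y = np.array([AWAKE] * 50 + [SLEEP] * 50, dtype=object)
        m = sd.evaluate_predictions(y, np.ones(100), average="macro")
        assert m.accuracy == pytest.approx(50.0)
        assert m.confusion[1, 1] == 50 and m.confusion[1, 0] == 0  # sleep recall 100%

    def test_single_class_test_set_warns(self):
        y = np.array([SLEEP] * 10, dtype=object)
        with pytest.warns(UserWarning, match="single-class"):
            m = sd.evaluate_predictions(y, np.ones(10))
        assert m.accuracy == pytest.approx(100.0)

    def test_agrees_with_sklearn_on_random_vectors(self):
        from sklearn.metrics import accuracy_score, precision_recall_fscore_support

        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(20, 200))
            y = np.where(rng.random(n) < rng.uniform(0.2, 0.8), SLEEP, AWAKE)
            proba = rng.random(n)
            if len(np.unique(y)) < 2:
                continue
            m = sd.evaluate_predictions(y.astype(object), proba)
            yt = (y == SLEEP).astype(int)
            pred = (proba >= 0.5).astype(int)
            p, r, f, _ = precision_recall_fscore_support(
                yt, pred, average="weighted", zero_division=0
            )
            assert m.accuracy == pytest.approx(100 * accuracy_score(yt, pred), abs=1e-9)
            assert m.precision == pytest.approx(100 * p, abs=1e-9)
            assert m.recall == pytest.approx(100 * r, abs=1e-9)
            assert m.f1 == pytest.approx(100 * f, abs=1e-9)

    def test_window_majority_smoothing(self):
        y = np.array([SLEEP] * 6, dtype=object)
        proba = np.array([0.9, 0.9, 0.1, 0.1, 0.1, 0.9])
        wid = np.array([0, 0, 0, 1, 1, 1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            raw = sd.evaluate_predictions(y, proba)
            smoothed = sd.evaluate_predictions(y, proba, window_ids=wid, smooth=True)
        assert raw.accuracy == pytest.approx(50.0)
        assert smoothed.accuracy == pytest.approx(50.0)
        assert np.all(smoothed.confusion[1] == [3, 3])  # window votes 1-1


@pytest.fixture(scope="module")
def small_report(short_recording):
    rec = short_recording
    labels = sd.label_epochs(rec.events, rec.states.span)
    beats, beat_labels = sd.attach_labels(rec.beats, labels)
    return sd.run_ablation(
        beats, beat_labels, rec.resp,
        mlp_config=sd.MLPConfig(epochs=15),
        seeds=(0, 1),
    )


class TestAblation:
    def test_report_covers_exactly_the_four_arms(self, small_report):
        assert set(small_report.detail["arm"]) == set(sd.ARMS)
        assert list(small_report.summary().index) == list(sd.ARMS)

    def test_identical_splits_across_arms(self, small_report):
        counts = small_report.detail.groupby("seed")["n_test"].nunique()
        assert (counts == 1).all()

    def test_metrics_within_percent_range(self, small_report):
        vals = small_report.detail[["accuracy", "precision", "recall", "f1"]].to_numpy()
        assert (vals >= 0).all() and (vals <= 100).all()
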