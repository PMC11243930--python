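"""Feed-forward sleep/wake classifier and the feature-ablation experiment.

The classifier is a small multilayer perceptron — three hidden layers of
eight rectified-linear units and a sigmoid output — trained with Adam at a
constant learning rate of 0.01 on binary cross-entropy, on min–max
normalized per-beat features.  Data are split 70/5/25 into train /
validation / test, either by shuffling samples (the conventional protocol,
which lets beats from one session fall on both sides of the split) or by
assigning whole 30-min windows to a single split (``grouped`` mode, the
leakage-safe alternative).

The ablation runs four feature arms — RC alone, RRI alone, RRI plus its
first derivative, and RRI plus its second derivative — on identical splits
per seed, reporting accuracy and class-weighted precision/recall/F1 in
percent for each arm.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import log_loss
from sklearn.neural_network import MLPClassifier

from .derivatives import FeatureMatrix, build_features, normalize_features
from .series import AWAKE, SLEEP, BeatSeries, RespSeries, ValidationError

__all__ = [
    "ARMS",
    "MLPConfig",
    "SplitSpec",
    "Metrics",
    "TrainedClassifier",
    "AblationReport",
    "split_data",
    "train_classifier",
    "evaluate",
    "evaluate_predictions",
    "run_ablation",
]

#: the four ablation arms and the feature columns they use
ARMS: dict[str, tuple[str, ...]] = {
    "RC": ("rc",),
    "RRI": ("rri",),
    "RRI+dRRI": ("rri", "drri"),
    "RRI+d2RRI": ("rri", "d2rri"),
}

_LABEL_TO_INT = {AWAKE: 0, SLEEP: 1}


@dataclass(frozen=True)
class MLPConfig:
    """Architecture and optimization settings of the classifier."""

    hidden_layers: int = 3
    neurons_per_layer: int = 8
    learning_rate: float = 0.01
    epochs: int = 50
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_layers < 1:
            raise ValidationError("hidden_layers must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be positive")


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test split ratios and mode."""

    train: float = 0.70
    val: float = 0.05
    test: float = 0.25
    mode: str = "sample"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValidationError("split ratios must sum to 1")
        if self.mode not in ("sample", "grouped"):
            raise ValidationError("mode must be 'sample' or 'grouped'")


def split_data(fm: FeatureMatrix, spec: SplitSpec) -> dict[str, np.ndarray]:
    """Disjoint, exhaustive row-index sets for train/val/test.

    ``sample`` mode shuffles rows; ``grouped`` mode shuffles whole 30-min
    windows so no window contributes to two splits.
    """
    n = len(fm.frame)
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "sample":
        perm = rng.permutation(n)
        n_train = int(round(spec.train * n))
        n_val = int(round(spec.val * n))
        idx = {
            "train": perm[:n_train],
            "val": perm[n_train : n_train + n_val],
            "test": perm[n_train + n_val :],
        }
    else:
        wid = fm.window_ids
        windows = rng.permutation(np.unique(wid))
        counts = pd.Series(wid).value_counts()
        cum = np.cumsum([counts[w] for w in windows]) / n
        w_train = set(windows[cum <= spec.train])
        w_val = set(
            w for w, c in zip(windows, cum)
            if spec.train < c <= spec.train + spec.val
        )
        split_of = np.array(
            [
                "train" if w in w_train else ("val" if w in w_val else "test")
                for w in wid
            ]
        )
        idx = {name: np.nonzero(split_of == name)[0] for name in ("train", "val", "test")}
    for name, ids in idx.items():
        if len(ids) == 0:
            raise ValidationError(f"{name} split is empty; not enough samples")
    return idx


@dataclass
class TrainedClassifier:
    """A fitted MLP with its per-epoch loss history."""

    model: MLPClassifier
    train_loss: list[float]
    val_loss: list[float]

    def predict_proba_sleep(self, X: np.ndarray) -> np.ndarray:
        """P(sleep) per sample."""
        return self.model.predict_proba(X)[:, 1]


def _encode_labels(y: np.ndarray) -> np.ndarray:
    try:
        return np.array([_LABEL_TO_INT[v] for v in y], dtype=int)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValidationError(f"unknown label {exc.args[0]!r}") from exc


def train_classifier(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: MLPConfig = MLPConfig(),
    val_curve: bool = False,
) -> TrainedClassifier:
    """Train the MLP by mini-batch Adam, recording losses per epoch.

    Expects normalized features and awake/sleep labels.  Training is
    deterministic for a fixed config seed.  Aborts with diagnostics if the
    loss turns non-finite.

    With ``val_curve=False`` (default) all epochs run in one optimized
    pass; the per-epoch training losses come from the fitted loss curve and
    the validation loss is evaluated after the final epoch.  With
    ``val_curve=True`` the epochs are driven one mini-batch at a time so
    the validation loss is recorded after every epoch (slower).
    """
    yt = _encode_labels(np.asarray(y_train, dtype=object))
    yv = _encode_labels(np.asarray(y_val, dtype=object))
    classes = np.array([0, 1])
    common = dict(
        hidden_layer_sizes=(config.neurons_per_layer,) * config.hidden_layers,
        activation="relu",
        solver="adam",
        learning_rate_init=config.learning_rate,
        batch_size=min(config.batch_size, len(yt)),
        random_state=config.seed,
    )
    if not val_curve:
        clf = MLPClassifier(
            **common, max_iter=config.epochs, shuffle=True,
            n_iter_no_change=config.epochs + 1, tol=0.0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # max_iter convergence warning
            clf.fit(X_train, yt)
        train_loss = [float(v) for v in clf.loss_curve_]
        val_loss = [float(log_loss(yv, clf.predict_proba(X_val), labels=classes))]
    else:
        clf = MLPClassifier(**common, max_iter=1)
        rng = np.random.default_rng(config.seed)
        n = len(yt)
        train_loss, val_loss = [], []
        for epoch in range(config.epochs):
            order = rng.permutation(n)
            for start in range(0, n, config.batch_size):
                batch = order[start : start + config.batch_size]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    clf.partial_fit(X_train[batch], yt[batch], classes=classes)
            vl = log_loss(yv, clf.predict_proba(X_val), labels=classes)
            if not np.isfinite(vl):
                raise RuntimeError(
                    f"non-finite validation loss at epoch {epoch}; "
                    "lower the learning rate"
                )
            train_loss.append(float(clf.loss_))
            val_loss.append(float(vl))
    if not all(np.isfinite(train_loss)) or not all(np.isfinite(val_loss)):
        raise RuntimeError("non-finite loss during training; lower the learning rate")
    return TrainedClassifier(clf, train_loss, val_loss)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class Metrics:
    """Accuracy and class-weighted precision/recall/F1, in percent."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray  # rows: true awake/sleep; cols: predicted
    n: int

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def _metrics_from_confusion(cm: np.ndarray, average: str = "weighted") -> Metrics:
    n = int(cm.sum())
    accuracy = float(np.trace(cm)) / n
    precisions, recalls, f1s, support = [], [], [], []
    for k in (0, 1):
        tp = cm[k, k]
        fp = cm[1 - k, k]
        fn = cm[k, 1 - k]
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        f = 2 * p * r / (p + r) if p + r > 0 else 0.0
        precisions.append(p)
        recalls.append(r)
        f1s.append(f)
        support.append(cm[k, :].sum())
    support = np.asarray(support, dtype=float)
    if average == "weighted":
        w = support / n
    elif average == "macro":
        w = np.array([0.5, 0.5])
    else:
        raise ValueError("average must be 'weighted' or 'macro'")
    return Metrics(
        accuracy=100.0 * accuracy,
        precision=100.0 * float(w @ precisions),
        recall=100.0 * float(w @ recalls),
        f1=100.0 * float(w @ f1s),
        confusion=cm,
        n=n,
    )


def evaluate_predictions(
    y_true: np.ndarray,
    proba_sleep: np.ndarray,
    threshold: float = 0.5,
    window_ids: np.ndarray | None = None,
    smooth: bool = False,
    average: str = "weighted",
) -> Metrics:
    """Score sleep-probability predictions against awake/sleep labels.

    With ``smooth=True`` (requires ``window_ids``) each 30-min window's
    thresholded predictions are replaced by their majority vote before
    scoring.  A test set containing a single class yields precision/recall
    0 for the absent class, with a warning.
    """
    yt = _encode_labels(np.asarray(y_true, dtype=object))
    pred = (np.asarray(proba_sleep, dtype=float) >= threshold).astype(int)
    if smooth:
        if window_ids is None:
            raise ValidationError("smoothing requires window_ids")
        pred = pred.copy()
        for w in np.unique(window_ids):
            sel = window_ids == w
            pred[sel] = 1 if pred[sel].mean() > 0.5 else 0
    if len(np.unique(yt)) < 2:
        warnings.warn("single-class test set; metrics for the absent class are 0")
    cm = np.zeros((2, 2), dtype=int)
    np.add.at(cm, (yt, pred), 1)
    return _metrics_from_confusion(cm, average=average)


def evaluate(
    model: TrainedClassifier | MLPClassifier,
    X: np.ndarray,
    y: np.ndarray,
    threshold: float = 0.5,
    window_ids: np.ndarray | None = None,
    smooth: bool = False,
    average: str = "weighted",
) -> Metrics:
    """Score a trained classifier on a held-out set (see
    :func:`evaluate_predictions` for the scoring rules)."""
    clf = model.model if isinstance(model, TrainedClassifier) else model
    proba = clf.predict_proba(X)[:, 1]
    return evaluate_predictions(
        y, proba, threshold=threshold, window_ids=window_ids,
        smooth=smooth, average=average,
    )


# ---------------------------------------------------------------------------
# ablation
# ---------------------------------------------------------------------------


@dataclass
class AblationReport:
    """Per-seed, per-arm metrics of the four-arm feature ablation."""

    detail: pd.DataFrame  # columns: seed, arm, accuracy, precision, recall, f1, n_test
    seeds: tuple[int, ...]
    split_mode: str

    def summary(self) -> pd.DataFrame:
        """Mean metrics per arm across seeds, in the four-arm table shape."""
        s = (
            self.detail.groupby("arm")[["accuracy", "precision", "recall", "f1"]]
            .mean()
            .reindex(list(ARMS))
        )
        return s

    def accuracy_deltas(self) -> pd.DataFrame:
        """Per-seed test-accuracy difference of each arm over the RRI arm."""
        pivot = self.detail.pivot(index="seed", columns="arm", values="accuracy")
        return pivot.sub(pivot["RRI"], axis=0)


def run_ablation(
    beats: BeatSeries,
    beat_labels: np.ndarray,
    resp: RespSeries,
    mlp_config: MLPConfig = MLPConfig(),
    split_spec: SplitSpec = SplitSpec(),
    seeds: tuple[int, ...] = tuple(range(10)),
    window_min: float = 30.0,
    method: str = "central",
    smooth: bool = False,
) -> AblationReport:
    """Run the four-arm feature ablation on one labeled recording.

    For each seed, a single split of the full feature matrix is shared by
    all arms (a controlled comparison); normalization bounds are fitted on
    the training split of each arm and reused on validation/test.
    """
    full = build_features(
        beats, beat_labels, set(f for cols in ARMS.values() for f in cols),
        resp=resp, window_min=window_min, method=method,
    )
    rows = []
    for seed in seeds:
        idx = split_data(full, replace_seed(split_spec, seed))
        for arm, cols in ARMS.items():
            fm = full.select(cols)
            train_fm = FeatureMatrix(fm.frame.iloc[idx["train"]], fm.feature_names)
            _, bounds = normalize_features(train_fm)

            def take(which: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
                sub = FeatureMatrix(fm.frame.iloc[idx[which]], fm.feature_names)
                norm, _ = normalize_features(sub, bounds)
                return norm.X, norm.y, norm.window_ids

            Xtr, ytr, _ = take("train")
            Xva, yva, _ = take("val")
            Xte, yte, wte = take("test")
            model = train_classifier(
                Xtr, ytr, Xva, yva, replace_seed(mlp_config, seed)
            )
            m = evaluate(model, Xte, yte, window_ids=wte, smooth=smooth)
            rows.append({"seed": seed, "arm": arm, **m.as_dict(), "n_test": m.n})
    return AblationReport(pd.DataFrame(rows), tuple(seeds), split_spec.mode)


def replace_seed(spec, seed: int):
    """Copy of a frozen config dataclass with its seed replaced."""
    import dataclasses

    return dataclasses.replace(spec, seed=int(seed))
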