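"""Per-session anticipation classifiers.

Five families, all binary (anticipation = 1, idle = 0), all taking epochs of
shape ``(n_epochs, channels, samples)``:

* ``MlpEpochClassifier`` — Dense(128, ReLU) x2 + sigmoid output on the
  flattened epoch;
* ``CnnEpochClassifier`` — two [Conv2D 16 @ 9x9 ReLU, MaxPool 2x2] stages,
  then Dense(64, ReLU) x2 + sigmoid;
* ``ShallowCnnEpochClassifier`` — Conv2D 8 @ 2x2 ReLU, MaxPool 10x10,
  sigmoid output;
* ``CnnLstmEpochClassifier`` — Conv2D 8 @ 2x2, MaxPool 2x2, Conv2D 1 @ 2x2,
  MaxPool 2x2, LSTM(8, ReLU), sigmoid output;
* ``MatchedFilterLDA`` — effect-matched spatial filter collapsing the montage
  to one surrogate channel, a matched-filter template averaged from positive
  training trials, and an LDA on the template-correlation feature.

Network families train with Adam on binary cross-entropy, a stratified 20%
validation split, per-channel z-scoring with training statistics, and early
stopping; everything is seeded through ``random_state``. Estimators follow
the scikit-learn fit/predict API and compose with its model selection tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import precision_score, recall_score
from sklearn.model_selection import train_test_split

from . import _nn
from .simulate import ConfigurationError

__all__ = [
    "FAMILIES",
    "ArchitectureSpec",
    "MetricSet",
    "architecture_spec",
    "build_network",
    "make_classifier",
    "fit_classifier",
    "predict_proba",
    "evaluate_metrics",
    "emsf_fit",
    "MlpEpochClassifier",
    "CnnEpochClassifier",
    "ShallowCnnEpochClassifier",
    "CnnLstmEpochClassifier",
    "MatchedFilterLDA",
    "save_classifier",
    "load_classifier",
]

FAMILIES = ("mlp", "cnn", "cnn_shallow", "cnn_lstm", "mf_lda")


@dataclass(frozen=True)
class ArchitectureSpec:
    """A family name plus its ordered layer descriptors."""

    family: str
    layers: tuple[tuple[str, dict], ...]


def architecture_spec(family: str, units: int = 128, filters: int = 16,
                      kernel: int = 9, dense_units: int = 64,
                      shallow_filters: int = 8, lstm_units: int = 8
                      ) -> ArchitectureSpec:
    """The reference layer stack for each network family."""
    if family == "mlp":
        layers = (
            ("dense", {"units": units, "activation": "relu"}),
            ("dense", {"units": units, "activation": "relu"}),
            ("dense", {"units": 1, "activation": "sigmoid"}),
        )
    elif family == "cnn":
        conv = {"filters": filters, "kernel": (kernel, kernel),
                "stride": (1, 1), "activation": "relu"}
        layers = (
            ("conv2d", dict(conv)),
            ("maxpool2d", {"pool": (2, 2)}),
            ("conv2d", dict(conv)),
            ("maxpool2d", {"pool": (2, 2)}),
            ("flatten", {}),
            ("dense", {"units": dense_units, "activation": "relu"}),
            ("dense", {"units": dense_units, "activation": "relu"}),
            ("dense", {"units": 1, "activation": "sigmoid"}),
        )
    elif family == "cnn_shallow":
        layers = (
            ("conv2d", {"filters": shallow_filters, "kernel": (2, 2),
                        "stride": (1, 1), "activation": "relu"}),
            ("maxpool2d", {"pool": (10, 10)}),
            ("flatten", {}),
            ("dense", {"units": 1, "activation": "sigmoid"}),
        )
    elif family == "cnn_lstm":
        layers = (
            ("conv2d", {"filters": 8, "kernel": (2, 2), "stride": (1, 1),
                        "activation": "relu"}),
            ("maxpool2d", {"pool": (2, 2)}),
            ("conv2d", {"filters": 1, "kernel": (2, 2), "stride": (1, 1),
                        "activation": "relu"}),
            ("maxpool2d", {"pool": (2, 2)}),
            # ReLU is a deliberate override of the customary tanh
            ("lstm", {"units": lstm_units, "activation": "relu"}),
            ("dense", {"units": 1, "activation": "sigmoid"}),
        )
    else:
        raise ConfigurationError(f"unknown network family {family!r}")
    return ArchitectureSpec(family, layers)


def build_network(spec: ArchitectureSpec, input_shape: tuple[int, int],
                  rng: np.random.Generator) -> _nn.Network:
    """Instantiate a seeded, untrained network for channels x samples input.

    Raises a configuration error naming the offending layer if a kernel or
    pool no longer fits the running feature-map shape.
    """
    n_ch, n_samp = input_shape
    if spec.family == "mlp":
        shape: tuple = (n_ch * n_samp,)
    else:
        shape = (n_ch, n_samp, 1)

    layers: list[_nn.Layer] = []
    for pos, (kind, kw) in enumerate(spec.layers):
        if kind == "dense":
            if len(shape) != 1:
                layers.append(_nn.Flatten())
                shape = (int(np.prod(shape)),)
            layers.append(_nn.Dense(shape[0], kw["units"],
                                    kw["activation"], rng))
            shape = (kw["units"],)
        elif kind == "conv2d":
            kh, kw_ = kw["kernel"]
            H, W, C = shape
            if kh > H or kw_ > W:
                raise ConfigurationError(
                    f"layer {pos} (conv2d {kh}x{kw_}) exceeds feature map "
                    f"{H}x{W}")
            layers.append(_nn.Conv2D(C, kw["filters"], (kh, kw_),
                                     kw["activation"], rng))
            shape = (H - kh + 1, W - kw_ + 1, kw["filters"])
        elif kind == "maxpool2d":
            ph, pw = kw["pool"]
            H, W, C = shape
            if ph > H or pw > W:
                raise ConfigurationError(
                    f"layer {pos} (maxpool {ph}x{pw}) exceeds feature map "
                    f"{H}x{W}")
            layers.append(_nn.MaxPool2D((ph, pw)))
            shape = (H // ph, W // pw, C)
        elif kind == "lstm":
            H, W, C = shape
            layers.append(_nn.LSTM(H * C, kw["units"], kw["activation"],
                                   rng))
            shape = (kw["units"],)
        elif kind == "flatten":
            layers.append(_nn.Flatten())
            shape = (int(np.prod(shape)),)
        else:
            raise ConfigurationError(f"unknown layer kind {kind!r}")
    return _nn.Network(layers)


@dataclass(frozen=True)
class MetricSet:
    """Validation metrics; ``degenerate`` flags precision/F1 forced to 0
    because no positives were predicted."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    degenerate: bool = False


def evaluate_metrics(y_true, y_pred) -> MetricSet:
    """Accuracy, precision, recall and F1 with anticipation as positive.

    With zero predicted positives, precision (and hence F1) is undefined;
    both are reported as 0 with the ``degenerate`` flag set.
    """
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    acc = float((y_true == y_pred).mean())
    degenerate = y_pred.sum() == 0
    prec = float(precision_score(y_true, y_pred, zero_division=0))
    rec = float(recall_score(y_true, y_pred, zero_division=0))
    f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
    return MetricSet(acc, prec, rec, f1, bool(degenerate))


def _check_epochs(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 3:
        raise ValueError("X must be (n_epochs, channels, samples)")
    return X


class _NetworkClassifierBase(BaseEstimator, ClassifierMixin):
    """Shared fit/predict machinery for the network families."""

    family: str = ""

    def __init__(self, learning_rate=1e-3, max_epochs=100, batch_size=8,
                 validation_split=0.2, patience=10, random_state=0):
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.validation_split = validation_split
        self.patience = patience
        self.random_state = random_state

    def _spec(self) -> ArchitectureSpec:
        raise NotImplementedError

    def _prepare(self, X):
        Xs = (X - self.mean_) / self.scale_
        if self.family == "mlp":
            return Xs.reshape(len(Xs), -1)
        return Xs[..., None]

    def fit(self, X, y):
        X = _check_epochs(X)
        y = np.asarray(y, int)
        if not 0 < self.validation_split < 1:
            raise ConfigurationError("validation_split must be in (0, 1)")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data contains a single class")
        self.classes_ = np.array([0, 1])
        self.input_shape_ = X.shape[1:]

        rng = np.random.default_rng(self.random_state)
        Xtr, Xval, ytr, yval = train_test_split(
            X, y, test_size=self.validation_split, stratify=y,
            random_state=self.random_state)
        # per-channel standardization with training statistics
        self.mean_ = Xtr.mean(axis=(0, 2), keepdims=True)
        self.scale_ = Xtr.std(axis=(0, 2), keepdims=True)
        self.scale_[self.scale_ == 0] = 1.0

        self.spec_ = self._spec()
        self.net_ = build_network(self.spec_, self.input_shape_, rng)
        self.history_ = self.net_.fit(
            self._prepare(Xtr), ytr, self._prepare(Xval), yval,
            max_epochs=self.max_epochs, batch_size=self.batch_size,
            lr=self.learning_rate, patience=self.patience, rng=rng)
        yhat = (self.net_.predict_proba(self._prepare(Xval)) > 0.5).astype(
            int)
        self.validation_metrics_ = evaluate_metrics(yval, yhat)
        return self

    def predict_proba(self, X):
        X = _check_epochs(X)
        if X.shape[1:] != self.input_shape_:
            raise ValueError(
                f"epoch shape {X.shape[1:]} differs from training shape "
                f"{self.input_shape_}")
        p = self.net_.predict_proba(self._prepare(X))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


class MlpEpochClassifier(_NetworkClassifierBase):
    family = "mlp"

    def __init__(self, units=128, learning_rate=1e-3, max_epochs=100,
                 batch_size=8, validation_split=0.2, patience=10,
                 random_state=0):
        super().__init__(learning_rate, max_epochs, batch_size,
                         validation_split, patience, random_state)
        self.units = units

    def _spec(self):
        return architecture_spec("mlp", units=self.units)


class CnnEpochClassifier(_NetworkClassifierBase):
    family = "cnn"

    def __init__(self, filters=16, kernel=9, dense_units=64,
                 learning_rate=1e-3, max_epochs=100, batch_size=8,
                 validation_split=0.2, patience=10, random_state=0):
        super().__init__(learning_rate, max_epochs, batch_size,
                         validation_split, patience, random_state)
        self.filters = filters
        self.kernel = kernel
        self.dense_units = dense_units

    def _spec(self):
        return architecture_spec("cnn", filters=self.filters,
                                 kernel=self.kernel,
                                 dense_units=self.dense_units)


class ShallowCnnEpochClassifier(_NetworkClassifierBase):
    family = "cnn_shallow"

    def __init__(self, filters=8, learning_rate=1e-3, max_epochs=100,
                 batch_size=8, validation_split=0.2, patience=10,
                 random_state=0):
        super().__init__(learning_rate, max_epochs, batch_size,
                         validation_split, patience, random_state)
        self.filters = filters

    def _spec(self):
        return architecture_spec("cnn_shallow", shallow_filters=self.filters)


class CnnLstmEpochClassifier(_NetworkClassifierBase):
    family = "cnn_lstm"

    def __init__(self, lstm_units=8, learning_rate=1e-3, max_epochs=100,
                 batch_size=8, validation_split=0.2, patience=10,
                 random_state=0):
        super().__init__(learning_rate, max_epochs, batch_size,
                         validation_split, patience, random_state)
        self.lstm_units = lstm_units

    def _spec(self):
        return architecture_spec("cnn_lstm", lstm_units=self.lstm_units)


def emsf_fit(X, y, weighting: str = "svd") -> np.ndarray:
    """Effect-matched spatial filter weights (unit L2 norm, one per channel).

    The class effect is ``D = mean(positive epochs) - mean(negative epochs)``
    (channels x samples). With ``weighting='svd'`` each channel's weight is
    the inner product of its effect waveform with the first principal
    time-course of ``D``; with ``'rms'`` it is the RMS of the effect waveform
    (sign from the waveform mean). The surrogate channel is
    ``s(t) = sum_c w_c x_c(t)``.
    """
    X = _check_epochs(X)
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes are required to fit the EMSF")
    D = X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0)
    norm_D = np.linalg.norm(D)
    if norm_D < 1e-12 * max(1.0, np.abs(X).max()):
        raise ValueError("zero class effect: positive and negative means "
                         "coincide")
    if weighting == "svd":
        _, _, Vt = np.linalg.svd(D, full_matrices=False)
        w = D @ Vt[0]
    elif weighting == "rms":
        w = np.sqrt((D ** 2).mean(axis=1)) * np.sign(D.mean(axis=1))
    else:
        raise ConfigurationError(f"unknown EMSF weighting {weighting!r}")
    return w / np.linalg.norm(w)


def _template_correlation(surrogate: np.ndarray,
                          template: np.ndarray) -> np.ndarray:
    s = surrogate - surrogate.mean(axis=1, keepdims=True)
    t = template - template.mean()
    denom = np.linalg.norm(s, axis=1) * np.linalg.norm(t)
    if np.any(denom == 0):
        raise ValueError("zero-variance surrogate or template")
    return (s @ t) / denom


class MatchedFilterLDA(BaseEstimator, ClassifierMixin):
    """EMSF surrogate channel -> matched-filter correlation -> LDA.

    The matched-filter template is the average positive-class surrogate
    waveform from the training split; each epoch's single feature is the
    Pearson correlation between its surrogate waveform and the template, and
    a linear discriminant on that feature makes the call.
    """

    family = "mf_lda"

    def __init__(self, weighting="svd", validation_split=0.2,
                 random_state=0):
        self.weighting = weighting
        self.validation_split = validation_split
        self.random_state = random_state

    def fit(self, X, y):
        X = _check_epochs(X)
        y = np.asarray(y, int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data contains a single class")
        self.classes_ = np.array([0, 1])
        self.input_shape_ = X.shape[1:]
        Xtr, Xval, ytr, yval = train_test_split(
            X, y, test_size=self.validation_split, stratify=y,
            random_state=self.random_state)
        self.emsf_weights_ = emsf_fit(Xtr, ytr, self.weighting)
        surrogate = np.tensordot(Xtr, self.emsf_weights_, axes=([1], [0]))
        self.template_ = surrogate[ytr == 1].mean(axis=0)
        feat = _template_correlation(surrogate, self.template_)
        if feat.std() == 0:
            raise ValueError("zero-variance matched-filter feature")
        self.lda_ = LinearDiscriminantAnalysis()
        self.lda_.fit(feat[:, None], ytr)
        self.validation_metrics_ = evaluate_metrics(
            yval, self.predict(Xval))
        return self

    def _features(self, X):
        X = _check_epochs(X)
        if X.shape[1:] != self.input_shape_:
            raise ValueError(
                f"epoch shape {X.shape[1:]} differs from training shape "
                f"{self.input_shape_}")
        surrogate = np.tensordot(X, self.emsf_weights_, axes=([1], [0]))
        return _template_correlation(surrogate, self.template_)[:, None]

    def predict_proba(self, X):
        return self.lda_.predict_proba(self._features(X))

    def predict(self, X):
        return self.lda_.predict(self._features(X))


_FAMILY_CLASSES = {
    "mlp": MlpEpochClassifier,
    "cnn": CnnEpochClassifier,
    "cnn_shallow": ShallowCnnEpochClassifier,
    "cnn_lstm": CnnLstmEpochClassifier,
    "mf_lda": MatchedFilterLDA,
}


def make_classifier(family: str, **overrides):
    """Instantiate a family by name with its reference defaults."""
    try:
        cls = _FAMILY_CLASSES[family]
    except KeyError:
        raise ConfigurationError(f"unknown family {family!r}; choose from "
                                 f"{FAMILIES}") from None
    return cls(**overrides)


def fit_classifier(clf, epoch_set):
    """Fit an estimator on an :class:`~eegdta.preprocessing.EpochSet`.

    Returns ``(fitted_estimator, validation MetricSet)``.
    """
    clf.fit(epoch_set.epochs, epoch_set.labels)
    return clf, clf.validation_metrics_


def predict_proba(clf, epoch_set) -> np.ndarray:
    """Positive-class (anticipation) probability for every epoch."""
    return clf.predict_proba(epoch_set.epochs)[:, 1]


def save_classifier(clf, path) -> None:
    """Persist a fitted estimator as NPZ weights + a JSON manifest."""
    path = Path(path)
    manifest = {"family": clf.family, "params": clf.get_params(),
                "input_shape": [int(v) for v in clf.input_shape_]}
    arrays = {}
    if isinstance(clf, MatchedFilterLDA):
        arrays.update(
            emsf_weights=clf.emsf_weights_, template=clf.template_,
            lda_coef=clf.lda_.coef_, lda_intercept=clf.lda_.intercept_,
            lda_xbar=clf.lda_.xbar_, lda_means=clf.lda_.means_,
            lda_priors=clf.lda_.priors_)
    else:
        arrays.update(mean=clf.mean_, scale=clf.scale_)
        for i, w in enumerate(clf.net_.get_weights()):
            arrays[f"w{i}"] = w
    np.savez(path, **arrays)
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_classifier(path):
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    clf = make_classifier(manifest["family"], **manifest["params"])
    clf.classes_ = np.array([0, 1])
    clf.input_shape_ = tuple(manifest["input_shape"])
    with np.load(path, allow_pickle=False) as z:
        if manifest["family"] == "mf_lda":
            clf.emsf_weights_ = z["emsf_weights"]
            clf.template_ = z["template"]
            lda = LinearDiscriminantAnalysis()
            lda.classes_ = np.array([0, 1])
            lda.coef_ = z["lda_coef"]
            lda.intercept_ = z["lda_intercept"]
            lda.xbar_ = z["lda_xbar"]
            lda.means_ = z["lda_means"]
            lda.priors_ = z["lda_priors"]
            clf.lda_ = lda
        else:
            clf.mean_ = z["mean"]
            clf.scale_ = z["scale"]
            rng = np.random.default_rng(0)
            clf.spec_ = clf._spec()
            clf.net_ = build_network(clf.spec_, clf.input_shape_, rng)
            clf.net_.set_weights(
                [z[f"w{i}"] for i in range(len(clf.net_.params()))])
    return clf
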