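"""Neural-network discriminator for decoy vs. non-decoy PSMs.

The scorer is a feed-forward network with one hidden layer and two sigmoid
output nodes (one per class), trained by classical per-example
backpropagation with momentum on a squared-error loss against one-hot
targets.  The discriminant probability of a PSM being a genuine (non-decoy)
hit is the non-decoy output activation normalised by the sum of the two
output activations, which preserves the 0.5 symmetry of the usual
sigmoid-output-to-probability mapping.

Training is deterministic given the data and a seed: initial weights are
drawn uniformly from [-0.5, 0.5] and the per-epoch example order is
shuffled, both from the same seeded generator.

The reference protocol runs six independent trainings per stratum with
(hidden nodes, learning rate, epochs) =
(4, 0.1, 1000), (4, 0.2, 1000), (4, 0.3, 1000),
(5, 0.1, 2000), (5, 0.2, 2000), (5, 0.3, 2000)
and momentum 0.2 throughout; downstream calibration picks or merges the
most sensitive run.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .psm import FEATURE_NAMES, PSMRecord

__all__ = [
    "TrainingConfig",
    "NormalizationParams",
    "NetworkModel",
    "ScoredPSM",
    "PSMNetClassifier",
    "PROTOCOL_RUNS",
    "normalize_features",
    "train_network",
    "train_scorer",
    "score",
    "run_protocol",
]

#: (n_hidden, learning_rate, epochs) of the six protocol runs; momentum 0.2.
PROTOCOL_RUNS = (
    (4, 0.1, 1000),
    (4, 0.2, 1000),
    (4, 0.3, 1000),
    (5, 0.1, 2000),
    (5, 0.2, 2000),
    (5, 0.3, 2000),
)

PROTOCOL_MOMENTUM = 0.2


def _train_loop(X, Y, w1, b1, w2, b2, orders, lr, momentum):  # pragma: no cover
    """Per-example backpropagation with momentum; mutates the weight arrays.

    Weight changes use the classical rule dW(t) = lr * delta * input +
    momentum * dW(t-1); output-layer weights are updated before the hidden
    layer, with hidden deltas computed from the pre-update output weights.
    """
    n, f = X.shape
    h = w1.shape[1]
    hid = np.zeros(h)
    out = np.zeros(2)
    dout = np.zeros(2)
    dhid = np.zeros(h)
    pw1 = np.zeros_like(w1)
    pb1 = np.zeros_like(b1)
    pw2 = np.zeros_like(w2)
    pb2 = np.zeros_like(b2)
    old_w2 = np.zeros_like(w2)
    epochs = orders.shape[0]
    for e in range(epochs):
        for t in range(n):
            k = orders[e, t]
            for a in range(h):
                s = b1[a]
                for b in range(f):
                    s += X[k, b] * w1[b, a]
                hid[a] = 1.0 / (1.0 + math.exp(-s))
            for c in range(2):
                s = b2[c]
                for a in range(h):
                    s += hid[a] * w2[a, c]
                out[c] = 1.0 / (1.0 + math.exp(-s))
            for c in range(2):
                dout[c] = (Y[k, c] - out[c]) * out[c] * (1.0 - out[c])
            for a in range(h):
                for c in range(2):
                    old_w2[a, c] = w2[a, c]
            for c in range(2):
                for a in range(h):
                    chg = lr * dout[c] * hid[a] + momentum * pw2[a, c]
                    w2[a, c] += chg
                    pw2[a, c] = chg
                chg = lr * dout[c] + momentum * pb2[c]
                b2[c] += chg
                pb2[c] = chg
            for a in range(h):
                s = 0.0
                for c in range(2):
                    s += dout[c] * old_w2[a, c]
                dhid[a] = s * hid[a] * (1.0 - hid[a])
            for a in range(h):
                for b in range(f):
                    chg = lr * dhid[a] * X[k, b] + momentum * pw1[b, a]
                    w1[b, a] += chg
                    pw1[b, a] = chg
                chg = lr * dhid[a] + momentum * pb1[a]
                b1[a] += chg
                pb1[a] = chg


try:  # compiled inner loop; the pure-Python loop above is the fallback
    from numba import njit

    _train_loop_fast = njit(cache=True)(_train_loop)
except ImportError:  # pragma: no cover
    _train_loop_fast = _train_loop

#: switchable for testing the fallback path
_ACTIVE_TRAIN_LOOP = [_train_loop_fast]


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of one discriminator training run."""

    feature_list: tuple[str, ...]
    n_hidden: int = 5
    learning_rate: float = 0.2
    momentum: float = 0.2
    epochs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        for f in self.feature_list:
            if f not in FEATURE_NAMES:
                raise ValueError(f"unknown feature {f!r}")


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature location/scale of the training stratum.

    sp_rank is log(1 + rank)-transformed before standardisation because its
    raw scale is heavy-tailed; constant columns keep scale 1 so they map to
    all-zeros.
    """

    feature_list: tuple[str, ...]
    loc: tuple[float, ...]
    scale: tuple[float, ...]

    def apply(self, records: Sequence[PSMRecord]) -> np.ndarray:
        raw = _raw_matrix(records, self.feature_list)
        return (raw - np.asarray(self.loc)) / np.asarray(self.scale)


def _raw_matrix(records: Sequence[PSMRecord], feature_list: Sequence[str]) -> np.ndarray:
    cols = []
    for f in feature_list:
        v = np.array([r.feature(f) for r in records], dtype=float)
        if f == "sp_rank":
            v = np.log1p(v)
        cols.append(v)
    return np.column_stack(cols)


def normalize_features(
    records: Sequence[PSMRecord], feature_list: Sequence[str]
) -> tuple[np.ndarray, NormalizationParams]:
    """Standardise each feature to zero mean / unit variance over a stratum."""
    feature_list = tuple(feature_list)
    raw = _raw_matrix(records, feature_list)
    loc = raw.mean(axis=0)
    scale = raw.std(axis=0)
    scale[scale == 0.0] = 1.0
    params = NormalizationParams(feature_list, tuple(loc), tuple(scale))
    return (raw - loc) / scale, params


class PSMNetClassifier(ClassifierMixin, BaseEstimator):
    """Two-output sigmoid MLP trained by per-example backpropagation.

    scikit-learn-style estimator over an already-normalised feature matrix;
    class 1 is the non-decoy (target) class.  ``predict_proba`` returns the
    normalised pair of output activations, so column 1 is the discriminant
    probability P of being a genuine hit.

    Parameters
    ----------
    n_hidden : int
        Nodes in the single hidden layer.
    learning_rate : float
        Step size of the per-example weight updates.
    momentum : float
        Fraction of the previous weight change added to the current one.
    epochs : int
        Full passes over the (reshuffled) training data.
    random_state : int
        Seeds weight initialisation and the per-epoch shuffles.
    """

    def __init__(
        self,
        n_hidden: int = 5,
        learning_rate: float = 0.2,
        momentum: float = 0.2,
        epochs: int = 1000,
        random_state: int = 0,
    ) -> None:
        self.n_hidden = n_hidden
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.epochs = epochs
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D feature matrix")
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            if classes.size == 1:
                raise ValueError("single-class training set")
            raise ValueError(f"labels must be binary 0/1, got classes {classes}")
        if min((y == 0).sum(), (y == 1).sum()) < 2:
            raise ValueError("need at least 2 examples of each class")

        n, f = X.shape
        rng = np.random.default_rng(self.random_state)
        w1 = rng.uniform(-0.5, 0.5, size=(f, self.n_hidden))
        b1 = rng.uniform(-0.5, 0.5, size=self.n_hidden)
        w2 = rng.uniform(-0.5, 0.5, size=(self.n_hidden, 2))
        b2 = rng.uniform(-0.5, 0.5, size=2)
        orders = np.empty((self.epochs, n), dtype=np.int64)
        for e in range(self.epochs):
            orders[e] = rng.permutation(n)

        Y = np.zeros((n, 2))
        Y[np.arange(n), y] = 1.0

        self.loss_initial_ = self._mean_loss(X, Y, w1, b1, w2, b2)
        _ACTIVE_TRAIN_LOOP[0](
            X, Y, w1, b1, w2, b2, orders, float(self.learning_rate), float(self.momentum)
        )
        self.loss_final_ = self._mean_loss(X, Y, w1, b1, w2, b2)

        self.classes_ = np.array([0, 1])
        self.n_features_in_ = f
        self.coefs_ = [w1, w2]
        self.intercepts_ = [b1, b2]
        return self

    @staticmethod
    def _mean_loss(X, Y, w1, b1, w2, b2) -> float:
        hid = 1.0 / (1.0 + np.exp(-(X @ w1 + b1)))
        out = 1.0 / (1.0 + np.exp(-(hid @ w2 + b2)))
        return float(0.5 * ((Y - out) ** 2).sum(axis=1).mean())

    def _activations(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        hid = 1.0 / (1.0 + np.exp(-(X @ self.coefs_[0] + self.intercepts_[0])))
        return 1.0 / (1.0 + np.exp(-(hid @ self.coefs_[1] + self.intercepts_[1])))

    def predict_proba(self, X) -> np.ndarray:
        out = self._activations(X)
        return out / out.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


@dataclass(frozen=True)
class NetworkModel:
    """A trained discriminator: architecture, weights and normalisation."""

    config: TrainingConfig
    w_hidden: np.ndarray  # (n_inputs, n_hidden)
    b_hidden: np.ndarray
    w_output: np.ndarray  # (n_hidden, 2)
    b_output: np.ndarray
    normalization: Optional[NormalizationParams] = None
    loss_initial: float = float("nan")
    loss_final: float = float("nan")

    @property
    def n_inputs(self) -> int:
        return self.w_hidden.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.w_hidden.shape[1]

    def activations(self, X: np.ndarray) -> np.ndarray:
        hid = 1.0 / (1.0 + np.exp(-(np.asarray(X) @ self.w_hidden + self.b_hidden)))
        return 1.0 / (1.0 + np.exp(-(hid @ self.w_output + self.b_output)))

    def probabilities(self, X: np.ndarray) -> np.ndarray:
        """Discriminant probability P(non-decoy) for normalised features."""
        out = self.activations(X)
        return out[:, 1] / out.sum(axis=1)

    def to_json(self) -> str:
        doc = {
            "architecture": {
                "n_inputs": self.n_inputs,
                "n_hidden": self.n_hidden,
                "n_outputs": 2,
            },
            "config": {
                "feature_list": list(self.config.feature_list),
                "n_hidden": self.config.n_hidden,
                "learning_rate": self.config.learning_rate,
                "momentum": self.config.momentum,
                "epochs": self.config.epochs,
                "seed": self.config.seed,
            },
            "weights": {
                "w_hidden": self.w_hidden.tolist(),
                "b_hidden": self.b_hidden.tolist(),
                "w_output": self.w_output.tolist(),
                "b_output": self.b_output.tolist(),
            },
            "normalization": None
            if self.normalization is None
            else {
                "feature_list": list(self.normalization.feature_list),
                "loc": list(self.normalization.loc),
                "scale": list(self.normalization.scale),
            },
            "loss": {"initial": self.loss_initial, "final": self.loss_final},
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NetworkModel":
        doc = json.loads(text)
        cfg = doc["config"]
        norm = doc.get("normalization")
        return cls(
            config=TrainingConfig(
                feature_list=tuple(cfg["feature_list"]),
                n_hidden=cfg["n_hidden"],
                learning_rate=cfg["learning_rate"],
                momentum=cfg["momentum"],
                epochs=cfg["epochs"],
                seed=cfg["seed"],
            ),
            w_hidden=np.array(doc["weights"]["w_hidden"]),
            b_hidden=np.array(doc["weights"]["b_hidden"]),
            w_output=np.array(doc["weights"]["w_output"]),
            b_output=np.array(doc["weights"]["b_output"]),
            normalization=None
            if norm is None
            else NormalizationParams(
                tuple(norm["feature_list"]), tuple(norm["loc"]), tuple(norm["scale"])
            ),
            loss_initial=doc["loss"]["initial"],
            loss_final=doc["loss"]["final"],
        )


@dataclass(frozen=True)
class ScoredPSM:
    """A PSM with its discriminant probability of being a genuine hit."""

    record: PSMRecord
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability must lie in [0, 1], got {self.probability}")


def train_network(
    matrix: np.ndarray,
    labels: Sequence[int],
    config: TrainingConfig,
    normalization: Optional[NormalizationParams] = None,
) -> NetworkModel:
    """Train the discriminator on a normalised feature matrix.

    Labels: 1 = target (non-decoy), 0 = decoy.  Deterministic given
    (matrix, labels, config).
    """
    clf = PSMNetClassifier(
        n_hidden=config.n_hidden,
        learning_rate=config.learning_rate,
        momentum=config.momentum,
        epochs=config.epochs,
        random_state=config.seed,
    ).fit(matrix, np.asarray(labels))
    return NetworkModel(
        config=config,
        w_hidden=clf.coefs_[0],
        b_hidden=clf.intercepts_[0],
        w_output=clf.coefs_[1],
        b_output=clf.intercepts_[1],
        normalization=normalization,
        loss_initial=clf.loss_initial_,
        loss_final=clf.loss_final_,
    )


def train_scorer(records: Sequence[PSMRecord], config: TrainingConfig) -> NetworkModel:
    """Normalise a stratum's features and train the discriminator on it."""
    matrix, params = normalize_features(records, config.feature_list)
    labels = np.array([0 if r.is_decoy else 1 for r in records])
    return train_network(matrix, labels, config, normalization=params)


def score(model: NetworkModel, records: Sequence[PSMRecord]) -> list[ScoredPSM]:
    """Score records with a trained model, preserving input order."""
    if model.normalization is None:
        raise ValueError("model carries no normalization parameters")
    X = model.normalization.apply(records)
    probs = model.probabilities(X)
    return [ScoredPSM(r, float(p)) for r, p in zip(records, probs)]


def run_protocol(
    records: Sequence[PSMRecord],
    feature_list: Sequence[str],
    base_seed: int,
) -> list[list[ScoredPSM]]:
    """Train and score the six reference runs on one stratum.

    Run *i* (1-based) uses seed ``base_seed + i`` (reduced mod 2**31).
    """
    out = []
    for i, (n_hidden, lr, epochs) in enumerate(PROTOCOL_RUNS, start=1):
        config = TrainingConfig(
            feature_list=tuple(feature_list),
            n_hidden=n_hidden,
            learning_rate=lr,
            momentum=PROTOCOL_MOMENTUM,
            epochs=epochs,
            seed=(base_seed + i) % (2**31),
        )
        model = train_scorer(records, config)
        out.append(score(model, records))
    return out
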