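"""Classifiers and wrapper feature selection.

Two classifiers discriminate normal from SCD-prone observations:

* a three-layer perceptron (input - 5 sigmoid hidden units - 1 linear
  output) trained by batch back-propagation with the classic
  variable-learning-rate schedule: the rate grows 5% after an improving
  step and shrinks to 0.7x (with weight rollback) after a step that
  worsens the MSE by more than 4%; training stops when the MSE falls
  below 0.01 or after 1000 iterations;
* a k-nearest-neighbour vote (k odd, Euclidean metric, default k = 7)
  with distance ties broken by training-row order.

Features are z-scored per training fold before either classifier sees
them; infinite-ratio sentinels are clipped to the fold maximum.  Labels
are coded 0 = normal, 1 = scd, with "scd" the positive class.

Sequential forward selection wraps a classifier: starting empty, it
greedily adds the feature whose addition maximises leave-one-out accuracy
on the training table, breaking ties toward the lower feature index, and
stops when the best candidate no longer improves the accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import FeatureTable
from .features.vector import SENTINEL

__all__ = [
    "MlpSpec",
    "KnnSpec",
    "FoldScaler",
    "MlpClassifier",
    "KnnClassifier",
    "make_classifier",
    "SelectionResult",
    "sequential_forward_selection",
    "loo_accuracy",
]


@dataclass(frozen=True)
class MlpSpec:
    n_hidden: int = 5
    max_iter: int = 1000
    target_mse: float = 0.01
    learning_rate: float = 0.1  # initial; adapted during training
    lr_up: float = 1.05
    lr_down: float = 0.7
    max_mse_increase: float = 0.04
    seed: int = 0
    zscore: bool = True

    def __post_init__(self) -> None:
        if self.n_hidden < 1 or self.max_iter < 1:
            raise ValueError("n_hidden and max_iter must be >= 1")


@dataclass(frozen=True)
class KnnSpec:
    k: int = 7
    zscore: bool = True

    def __post_init__(self) -> None:
        if self.k % 2 == 0:
            raise ValueError("k must be odd (binary ties impossible)")
        if self.k not in (1, 3, 5, 7, 9):
            raise ValueError("k must be one of 1, 3, 5, 7, 9")


class FoldScaler:
    """Per-fold z-scoring with sentinel clipping.

    Means/SDs come from the training rows only.  Values at or above the
    infinite-ratio sentinel are clipped to the largest non-sentinel
    training value of that feature before standardisation.
    """

    def fit(self, X: np.ndarray) -> "FoldScaler":
        X = np.asarray(X, dtype=float)
        self.caps_ = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            col = X[:, j]
            ok = col < SENTINEL
            self.caps_[j] = col[ok].max() if ok.any() else 0.0
        Xc = self._cap(X)
        self.mean_ = Xc.mean(axis=0)
        sd = Xc.std(axis=0, ddof=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        return self

    def _cap(self, X: np.ndarray) -> np.ndarray:
        return np.minimum(X, self.caps_)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (self._cap(X) - self.mean_) / self.sd_


class MlpClassifier:
    """13(-or-selected)-5-1 perceptron with variable-learning-rate backprop."""

    def __init__(self, spec: MlpSpec = MlpSpec()):
        self.spec = spec
        self.converged_: bool | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MlpClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1, 1)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        if self.spec.zscore:
            self.scaler_ = FoldScaler().fit(X)
            X = self.scaler_.transform(X)
        else:
            self.scaler_ = None
        n, d = X.shape
        h = self.spec.n_hidden
        rng = np.random.default_rng(self.spec.seed)
        w1 = rng.uniform(-0.5, 0.5, size=(d, h))
        b1 = rng.uniform(-0.5, 0.5, size=h)
        w2 = rng.uniform(-0.5, 0.5, size=(h, 1))
        b2 = rng.uniform(-0.5, 0.5, size=1)
        lr = self.spec.learning_rate
        mse = np.inf
        self.converged_ = False
        for _ in range(self.spec.max_iter):
            z1 = X @ w1 + b1
            a1 = 1.0 / (1.0 + np.exp(-z1))
            out = a1 @ w2 + b2  # linear output
            err = out - y
            new_mse = float(np.mean(err**2))
            if new_mse > mse * (1.0 + self.spec.max_mse_increase):
                # reject the step: roll back and shrink the rate
                w1, b1, w2, b2 = w1_prev, b1_prev, w2_prev, b2_prev
                lr *= self.spec.lr_down
                continue
            if new_mse < mse:
                lr *= self.spec.lr_up
            mse = new_mse
            if mse < self.spec.target_mse:
                self.converged_ = True
                break
            # gradients of the batch MSE
            g_out = 2.0 * err / n
            g_w2 = a1.T @ g_out
            g_b2 = g_out.sum(axis=0)
            g_a1 = g_out @ w2.T
            g_z1 = g_a1 * a1 * (1.0 - a1)
            g_w1 = X.T @ g_z1
            g_b1 = g_z1.sum(axis=0)
            w1_prev, b1_prev, w2_prev, b2_prev = w1, b1, w2, b2
            w1 = w1 - lr * g_w1
            b1 = b1 - lr * g_b1
            w2 = w2 - lr * g_w2
            b2 = b2 - lr * g_b2
        self.weights_ = (w1, b1, w2, b2)
        self.final_mse_ = mse
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.scaler_ is not None:
            X = self.scaler_.transform(X)
        w1, b1, w2, b2 = self.weights_
        a1 = 1.0 / (1.0 + np.exp(-(X @ w1 + b1)))
        return (a1 @ w2 + b2).ravel()

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) >= 0.5).astype(int)

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        """Output clipped to [0, 1]; interpretable as event probability."""
        return np.clip(self.decision_function(X), 0.0, 1.0)


class KnnClassifier:
    """Majority vote among the k nearest (Euclidean) training rows."""

    def __init__(self, spec: KnnSpec = KnnSpec()):
        self.spec = spec

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KnnClassifier":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < self.spec.k:
            raise ValueError(f"need at least k={self.spec.k} training rows")
        if self.spec.zscore:
            self.scaler_ = FoldScaler().fit(X)
            self.X_ = self.scaler_.transform(X)
        else:
            self.scaler_ = None
            self.X_ = X
        self.y_ = np.asarray(y, dtype=int)
        return self

    def _votes(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.scaler_ is not None:
            X = self.scaler_.transform(X)
        d = np.sqrt(((X[:, None, :] - self.X_[None, :, :]) ** 2).sum(axis=2))
        # stable sort: equal distances keep training-row order
        nearest = np.argsort(d, axis=1, kind="stable")[:, : self.spec.k]
        return self.y_[nearest].mean(axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self._votes(X) > 0.5).astype(int)

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        """Fraction of the k neighbours voting for the positive class."""
        return self._votes(X)


ClassifierSpec = MlpSpec | KnnSpec


def make_classifier(spec: ClassifierSpec, seed: int | None = None):
    """Instantiate a classifier from its spec; ``seed`` overrides MlpSpec.seed."""
    if isinstance(spec, MlpSpec):
        if seed is not None:
            spec = MlpSpec(**{**spec.__dict__, "seed": int(seed) % (2**31 - 1)})
        return MlpClassifier(spec)
    if isinstance(spec, KnnSpec):
        return KnnClassifier(spec)
    raise TypeError(f"unknown classifier spec {type(spec).__name__}")


def loo_accuracy(
    X: np.ndarray, y: np.ndarray, spec: ClassifierSpec, seed: int = 0
) -> float:
    """Leave-one-out accuracy of a classifier on (X, y)."""
    n = X.shape[0]
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        clf = make_classifier(spec, seed=seed)
        clf.fit(X[mask], y[mask])
        correct += int(clf.predict(X[i : i + 1])[0] == y[i])
    return correct / n


@dataclass
class SelectionResult:
    selected: list[str]
    accuracies: list[float] = field(default_factory=list)
    stopping_reason: str = ""


def sequential_forward_selection(
    table: FeatureTable, spec: ClassifierSpec, seed: int = 0
) -> SelectionResult:
    """Greedy forward wrapper selection scored by LOO accuracy.

    At each step the candidate feature with the highest LOO accuracy when
    added to the current set is selected (ties toward the lower feature
    index); the search stops when the best candidate fails to improve on
    the current accuracy.
    """
    X, y = table.to_arrays()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if X.shape[0] < 4 or X.shape[1] < 1:
        raise ValueError("need at least 4 observations and 1 feature")
    names = list(table.feature_names)
    selected_idx: list[int] = []
    accuracies: list[float] = []
    current_acc = -np.inf
    remaining = list(range(len(names)))
    while remaining:
        best_idx, best_acc = None, -np.inf
        for j in remaining:  # ascending index order -> lower-index tie-break
            acc = loo_accuracy(X[:, selected_idx + [j]], y, spec, seed=seed)
            if acc > best_acc:
                best_idx, best_acc = j, acc
        if best_acc <= current_acc:
            reason = "no candidate improved the accuracy"
            break
        selected_idx.append(best_idx)
        remaining.remove(best_idx)
        accuracies.append(best_acc)
        current_acc = best_acc
    else:
        reason = "all features selected"
    return SelectionResult(
        selected=[names[j] for j in selected_idx],
        accuracies=accuracies,
        stopping_reason=reason,
    )
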