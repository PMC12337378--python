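"""Class-weighted multiclass training and evaluation.

The primary model is a feedforward network over fixed-length sequence
embeddings: two dense hidden layers (800 and 400 units by default) with ReLU
activations and 50% inverted dropout, a softmax output over the K
environments, categorical crossentropy weighted per class, and the Adam
optimiser at learning rate 1e-4 (batch 512, 200 epochs). It is implemented
directly in NumPy and is deterministic for a fixed seed under single-threaded
execution.

Benchmarks: a multinomial logistic regression (saga solver, L2 penalty, same
class weighting) on either one-hot positional features or embeddings, and a
gap-aware per-environment profile scorer (position-specific log-frequency
scoring with Laplace pseudocounts) standing in for a profile-HMM search
benchmark.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.class_weight import compute_class_weight as _sk_class_weight

from .seqs import ALPHABET, SequenceSet

__all__ = [
    "AnnSpec",
    "EvaluationReport",
    "FeedForwardClassifier",
    "ProfileClassifier",
    "stratified_split",
    "compute_class_weights",
    "train_ann",
    "train_multinomial_lr",
    "train_profile_classifier",
    "classify_profile",
    "evaluate",
    "summarize_per_class_accuracy",
    "mcfadden_r2",
    "multinomial_loglik",
    "null_loglik",
]


# --------------------------------------------------------------------------
# splits and class weights
# --------------------------------------------------------------------------

def stratified_split(
    labels: Sequence[str],
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Single stratified train/test split; returns (train, test) index arrays.

    Per class, round(n_c * test_fraction) members go to the test side; the
    split is disjoint, exhaustive and deterministic per seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        if members.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        members = rng.permutation(members)
        k = int(round(members.size * test_fraction))
        k = min(max(k, 1), members.size - 1)  # both sides non-empty
        test_idx.append(members[:k])
        train_idx.append(members[k:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def compute_class_weights(labels: Sequence[str]) -> dict[str, float]:
    """Balanced class weights w_c = N / (K * n_c)."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    weights = _sk_class_weight("balanced", classes=classes, y=labels)
    return {str(c): float(w) for c, w in zip(classes, weights)}


# --------------------------------------------------------------------------
# evaluation report
# --------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Confusion matrix plus per-class and aggregate classification metrics."""

    classes: list[str]
    confusion: pd.DataFrame  # true x predicted counts
    per_class_accuracy: dict[str, float]  # = recall
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    overall_accuracy: float
    mean_per_class_accuracy: float
    sd_per_class_accuracy: float
    train_loss_curve: list[float] = field(default_factory=list)
    validation_loss_curve: list[float] = field(default_factory=list)

    @property
    def confusion_percent(self) -> pd.DataFrame:
        """Row-normalised confusion matrix (% of each true class)."""
        counts = self.confusion.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * counts / counts.sum(axis=1, keepdims=True)
        return pd.DataFrame(
            np.nan_to_num(pct), index=self.confusion.index, columns=self.confusion.columns
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
            }
        )


def summarize_per_class_accuracy(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample SD (ddof=1) of per-class accuracies."""
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def evaluate(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    classes: Sequence[str] | None = None,
) -> EvaluationReport:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = sorted(set(map(str, y_true)) | set(map(str, y_pred)))
    classes = [str(c) for c in classes]
    counts = _sk_confusion(y_true, y_pred, labels=classes)
    confusion = pd.DataFrame(counts, index=classes, columns=classes)
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0
    )
    per_class_acc = {c: float(r) for c, r in zip(classes, recall)}
    mean_acc, sd_acc = summarize_per_class_accuracy(list(per_class_acc.values()))
    return EvaluationReport(
        classes=classes,
        confusion=confusion,
        per_class_accuracy=per_class_acc,
        precision={c: float(p) for c, p in zip(classes, precision)},
        recall={c: float(r) for c, r in zip(classes, recall)},
        f1={c: float(v) for c, v in zip(classes, f1)},
        overall_accuracy=float((y_true == y_pred).mean()),
        mean_per_class_accuracy=mean_acc,
        sd_per_class_accuracy=sd_acc,
    )


def f1_score_from(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def mcfadden_r2(loglik_model: float, loglik_null: float) -> float:
    """McFadden's pseudo-R^2: 1 - loglik_model / loglik_null."""
    if loglik_null >= 0:
        raise ValueError("null log-likelihood must be negative")
    return 1.0 - loglik_model / loglik_null


def multinomial_loglik(proba: np.ndarray, y_index: np.ndarray) -> float:
    """Sum of log predicted probabilities of the observed classes."""
    p = np.clip(proba[np.arange(len(y_index)), y_index], 1e-300, None)
    return float(np.log(p).sum())


def null_loglik(y_index: np.ndarray) -> float:
    """Log-likelihood of the intercept-only (class-frequency) model."""
    _, counts = np.unique(y_index, return_counts=True)
    freqs = counts / counts.sum()
    return float((counts * np.log(freqs)).sum())


# --------------------------------------------------------------------------
# the feedforward network
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnSpec:
    """Hyperparameters of the feedforward network."""

    hidden_layers: tuple[int, ...] = (800, 400)
    dropout: float = 0.5
    learning_rate: float = 1e-4
    batch_size: int = 512
    epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w < 1 for w in self.hidden_layers):
            raise ValueError("hidden layer widths must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


class FeedForwardClassifier(BaseEstimator, ClassifierMixin):
    """Dense ReLU network with dropout, softmax output and Adam training.

    Parameters mirror :class:`AnnSpec`; ``class_weight`` is ``'balanced'``
    (w_c = N / (K n_c)), ``None`` (all ones) or an explicit mapping. Dropout
    is inverted (activations rescaled during training, identity at
    prediction time). Per-example losses are multiplied by the class weight
    of their label; the reported epoch loss is the mean weighted
    crossentropy over examples.

    Fitted attributes: ``classes_``, ``weights_``/``biases_``,
    ``loss_curve_`` and (when a validation set is passed to ``fit``)
    ``validation_loss_curve_``.
    """

    def __init__(
        self,
        hidden_layers: tuple[int, ...] = (800, 400),
        dropout: float = 0.5,
        learning_rate: float = 1e-4,
        batch_size: int = 512,
        epochs: int = 200,
        class_weight: str | Mapping[str, float] | None = "balanced",
        beta1: float = 0.9,
        beta2: float = 0.999,
        epsilon: float = 1e-8,
        random_state: int = 0,
    ):
        self.hidden_layers = hidden_layers
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.class_weight = class_weight
        self.beta1 = beta1
        self.beta2 = beta2
        self.epsilon = epsilon
        self.random_state = random_state

    # ---- internals ------------------------------------------------------

    def _init_params(self, d_in: int, k_out: int, rng: np.random.Generator):
        sizes = [d_in, *self.hidden_layers, k_out]
        weights, biases = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot-style uniform
            weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            biases.append(np.zeros(fan_out))
        return weights, biases

    @staticmethod
    def _softmax(z: np.ndarray) -> np.ndarray:
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def _forward_train(self, X, rng):
        """Forward pass with inverted dropout; returns activations and masks."""
        acts = [X]
        masks = []
        a = X
        keep = 1.0 - self.dropout
        for i, (W, b) in enumerate(zip(self.weights_, self.biases_)):
            z = a @ W + b
            if i < len(self.weights_) - 1:
                a = np.maximum(z, 0.0)
                if self.dropout > 0:
                    mask = (rng.random(a.shape) < keep) / keep
                    a = a * mask
                else:
                    mask = None
                masks.append(mask)
                acts.append(a)
            else:
                a = self._softmax(z)
        return acts, masks, a

    def _resolve_class_weights(self, y_index: np.ndarray, k: int) -> np.ndarray:
        if self.class_weight is None:
            return np.ones(k)
        if self.class_weight == "balanced":
            counts = np.bincount(y_index, minlength=k)
            return len(y_index) / (k * np.maximum(counts, 1))
        return np.array(
            [float(self.class_weight[str(c)]) for c in self.classes_]
        )

    def _weighted_loss(self, proba, y_index, w_class) -> float:
        p = np.clip(proba[np.arange(len(y_index)), y_index], 1e-12, None)
        return float((w_class[y_index] * -np.log(p)).mean())

    # ---- estimator API --------------------------------------------------

    def fit(self, X, y, validation_data: tuple | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per label")
        self.classes_, y_index = np.unique(y, return_inverse=True)
        k = len(self.classes_)
        if k < 2:
            raise ValueError("need at least two classes")
        rng = np.random.default_rng(self.random_state)
        self.weights_, self.biases_ = self._init_params(X.shape[1], k, rng)
        w_class = self._resolve_class_weights(y_index, k)

        # Adam state
        m_w = [np.zeros_like(w) for w in self.weights_]
        v_w = [np.zeros_like(w) for w in self.weights_]
        m_b = [np.zeros_like(b) for b in self.biases_]
        v_b = [np.zeros_like(b) for b in self.biases_]
        t = 0

        val = None
        if validation_data is not None:
            X_val = np.asarray(validation_data[0], dtype=float)
            y_val = np.asarray(validation_data[1])
            class_pos = {c: i for i, c in enumerate(self.classes_)}
            y_val_index = np.array([class_pos[c] for c in y_val])
            val = (X_val, y_val_index)

        self.loss_curve_: list[float] = []
        self.validation_loss_curve_: list[float] = []
        n = len(X)
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, self.batch_size):
                batch = order[start : start + self.batch_size]
                xb, yb = X[batch], y_index[batch]
                acts, masks, proba = self._forward_train(xb, rng)
                loss = self._weighted_loss(proba, yb, w_class)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss {loss} at epoch {epoch}, "
                        f"batch starting {start} (lr={self.learning_rate})"
                    )
                epoch_losses.append(loss)

                # backward: weighted softmax-crossentropy gradient
                grad_z = proba.copy()
                grad_z[np.arange(len(yb)), yb] -= 1.0
                grad_z *= w_class[yb][:, None] / len(yb)
                grads_w, grads_b = [], []
                for layer in range(len(self.weights_) - 1, -1, -1):
                    a_prev = acts[layer]
                    grads_w.append(a_prev.T @ grad_z)
                    grads_b.append(grad_z.sum(axis=0))
                    if layer > 0:
                        grad_a = grad_z @ self.weights_[layer].T
                        if masks[layer - 1] is not None:
                            grad_a = grad_a * masks[layer - 1]
                        grad_z = grad_a * (acts[layer] > 0)
                grads_w.reverse()
                grads_b.reverse()

                t += 1
                lr_t = self.learning_rate * (
                    np.sqrt(1 - self.beta2**t) / (1 - self.beta1**t)
                )
                for i in range(len(self.weights_)):
                    m_w[i] = self.beta1 * m_w[i] + (1 - self.beta1) * grads_w[i]
                    v_w[i] = self.beta2 * v_w[i] + (1 - self.beta2) * grads_w[i] ** 2
                    self.weights_[i] -= lr_t * m_w[i] / (np.sqrt(v_w[i]) + self.epsilon)
                    m_b[i] = self.beta1 * m_b[i] + (1 - self.beta1) * grads_b[i]
                    v_b[i] = self.beta2 * v_b[i] + (1 - self.beta2) * grads_b[i] ** 2
                    self.biases_[i] -= lr_t * m_b[i] / (np.sqrt(v_b[i]) + self.epsilon)

            self.loss_curve_.append(float(np.mean(epoch_losses)))
            if val is not None:
                proba_val = self.predict_proba(val[0])
                self.validation_loss_curve_.append(
                    self._weighted_loss(proba_val, val[1], w_class)
                )
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.weights_[0].shape[0]:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects "
                f"{self.weights_[0].shape[0]}"
            )
        a = X
        for i, (W, b) in enumerate(zip(self.weights_, self.biases_)):
            z = a @ W + b
            a = np.maximum(z, 0.0) if i < len(self.weights_) - 1 else self._softmax(z)
        return a

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def score(self, X, y) -> float:
        return float((self.predict(X) == np.asarray(y)).mean())


def train_ann(
    X: np.ndarray,
    y: Sequence[str],
    spec: AnnSpec | None = None,
    class_weight: str | Mapping[str, float] | None = "balanced",
    folds: int = 5,
) -> tuple[FeedForwardClassifier, list[EvaluationReport]]:
    """Fivefold cross-validated training, then a refit on the full data.

    Each fold trains on its training part with the fold's held-out part as
    validation, producing per-epoch training/validation loss curves plus a
    held-out evaluation report. The returned model is refit on all rows.
    """
    spec = spec or AnnSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)

    def make(seed: int) -> FeedForwardClassifier:
        return FeedForwardClassifier(
            hidden_layers=spec.hidden_layers,
            dropout=spec.dropout,
            learning_rate=spec.learning_rate,
            batch_size=spec.batch_size,
            epochs=spec.epochs,
            class_weight=class_weight,
            random_state=seed,
        )

    reports: list[EvaluationReport] = []
    if folds >= 2:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
        for i, (tr, va) in enumerate(splitter.split(X, y)):
            model = make(spec.seed + i + 1)
            model.fit(X[tr], y[tr], validation_data=(X[va], y[va]))
            report = evaluate(y[va], model.predict(X[va]), classes=model.classes_)
            report.train_loss_curve = model.loss_curve_
            report.validation_loss_curve = model.validation_loss_curve_
            reports.append(report)

    final = make(spec.seed).fit(X, y)
    return final, reports


# --------------------------------------------------------------------------
# benchmarks
# --------------------------------------------------------------------------

def train_multinomial_lr(
    X: np.ndarray,
    y: Sequence[str],
    class_weight: str | Mapping | None = "balanced",
    l2_strength: float = 1.0,
    max_iter: int = 6000,
    seed: int = 0,
) -> LogisticRegression:
    """Class-weighted multinomial logistic regression with an L2 penalty.

    Saga solver, as in the benchmark protocol; ``l2_strength`` is the ridge
    coefficient (sklearn's C = 1 / l2_strength).
    """
    if l2_strength <= 0:
        raise ValueError("l2_strength must be positive")
    model = LogisticRegression(
        solver="saga",
        C=1.0 / l2_strength,
        max_iter=max_iter,
        class_weight=class_weight if class_weight != "none" else None,
        random_state=seed,
        tol=1e-6,
    )
    model.fit(np.asarray(X, dtype=float), np.asarray(y))
    return model


class ProfileClassifier(BaseEstimator, ClassifierMixin):
    """Per-environment position-specific log-frequency scorer.

    For each environment the training alignment yields per-position residue
    frequencies over the 21-symbol dictionary (gap included) with a Laplace
    pseudocount; a query aligned sequence is assigned the environment whose
    profile maximises the summed log frequency. Ties break toward the
    earliest environment in sorted order, with a warning.
    """

    def __init__(self, pseudocount: float = 1.0):
        self.pseudocount = pseudocount

    def fit(self, X: SequenceSet | Sequence[str], y: Sequence[str] | None = None):
        if isinstance(X, SequenceSet):
            seqs, labels = X.sequences, X.environments
        else:
            seqs, labels = list(X), list(y)  # type: ignore[arg-type]
        labels = np.asarray(labels)
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("training sequences must be aligned (equal length)")
        L = lengths.pop()
        self.alignment_length_ = L
        self.classes_ = np.unique(labels)
        symbol_index = {s: i for i, s in enumerate(ALPHABET)}
        self.log_profiles_ = np.empty((len(self.classes_), L, len(ALPHABET)))
        matrix = np.array([[symbol_index[c] for c in s] for s in seqs])
        for ci, cls in enumerate(self.classes_):
            block = matrix[labels == cls]
            counts = np.stack(
                [
                    np.bincount(block[:, j], minlength=len(ALPHABET))
                    for j in range(L)
                ]
            ).astype(float)
            counts += self.pseudocount
            self.log_profiles_[ci] = np.log(counts / counts.sum(axis=1, keepdims=True))
        return self

    def decision_function(self, X: SequenceSet | Sequence[str]) -> np.ndarray:
        seqs = X.sequences if isinstance(X, SequenceSet) else list(X)
        symbol_index = {s: i for i, s in enumerate(ALPHABET)}
        scores = np.empty((len(seqs), len(self.classes_)))
        cols = np.arange(self.alignment_length_)
        for i, s in enumerate(seqs):
            if len(s) != self.alignment_length_:
                raise ValueError(
                    f"query length {len(s)} != alignment length "
                    f"{self.alignment_length_}"
                )
            idx = np.array([symbol_index[c] for c in s])
            scores[i] = self.log_profiles_[:, cols, idx].sum(axis=1)
        return scores

    def predict(self, X: SequenceSet | Sequence[str]) -> np.ndarray:
        scores = self.decision_function(X)
        best = scores.max(axis=1, keepdims=True)
        ties = (np.isclose(scores, best).sum(axis=1) > 1).sum()
        if ties:
            warnings.warn(
                f"{ties} query sequence(s) had tied profile scores; "
                "breaking ties by environment order",
                stacklevel=2,
            )
        return self.classes_[np.argmax(scores, axis=1)]


def train_profile_classifier(
    aln_train: SequenceSet, pseudocount: float = 1.0
) -> ProfileClassifier:
    return ProfileClassifier(pseudocount=pseudocount).fit(aln_train)


def classify_profile(
    model: ProfileClassifier, seqs: SequenceSet | Sequence[str]
) -> np.ndarray:
    return model.predict(seqs)
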