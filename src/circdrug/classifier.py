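"""Fully connected prediction head over pair embeddings.

A circRNA embedding and a drug embedding are concatenated (circRNA
first) into one feature row per candidate pair.  A three-hidden-layer
MLP (128/64/32 units, ReLU) with a single sigmoid output scores the
pair; training minimises binary cross-entropy with mini-batch Adam,
Glorot-uniform weights and zero biases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Adam, Tensor, glorot_uniform
from .errors import TrainingDivergedError, ValidationError
from .gate import Embedding

__all__ = [
    "ClassifierConfig",
    "PairFeatures",
    "MLPHead",
    "build_pair_features",
    "train_classifier",
    "predict_scores",
]


@dataclass(frozen=True)
class ClassifierConfig:
    hidden_dims: tuple[int, ...] = (128, 64, 32)
    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if any(d < 1 for d in self.hidden_dims):
            raise ValidationError("hidden_dims must be positive")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")


@dataclass
class PairFeatures:
    """Feature rows for (circRNA, drug) index pairs, optionally labelled."""

    pairs: list[tuple[int, int]]
    X_pair: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        if self.X_pair.shape[0] != len(self.pairs):
            raise ValidationError("X_pair row count != number of pairs")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != len(self.pairs):
                raise ValidationError("labels length != number of pairs")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValidationError("labels must be binary")


@dataclass
class MLPHead:
    """Trained parameters of the prediction network."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    input_dim: int

    def logits(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.input_dim:
            raise ValidationError(
                f"feature width {X.shape[1]} != training width {self.input_dim}"
            )
        h = np.asarray(X, dtype=np.float64)
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        return (h @ self.weights[-1] + self.biases[-1]).ravel()


def build_pair_features(
    emb_c: Embedding, emb_d: Embedding, pairs, labels=None
) -> PairFeatures:
    """Concatenate circRNA and drug embeddings per pair (circRNA first)."""
    pairs = [(int(i), int(j)) for i, j in pairs]
    n_c, n_d = emb_c.H.shape[0], emb_d.H.shape[0]
    for i, j in pairs:
        if not (0 <= i < n_c and 0 <= j < n_d):
            raise ValidationError(f"pair index ({i},{j}) out of range")
    if pairs:
        ci = np.array([p[0] for p in pairs])
        dj = np.array([p[1] for p in pairs])
        X = np.concatenate([emb_c.H[ci], emb_d.H[dj]], axis=1)
    else:
        X = np.zeros((0, emb_c.H.shape[1] + emb_d.H.shape[1]))
    return PairFeatures(pairs, X, None if labels is None else np.asarray(labels))


def train_classifier(train: PairFeatures, config: ClassifierConfig) -> MLPHead:
    """Mini-batch Adam training of the MLP head on labelled pairs."""
    if train.labels is None:
        raise ValidationError("training requires labels")
    y = np.asarray(train.labels, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValidationError("training set must contain both classes")
    X = np.asarray(train.X_pair, dtype=np.float64)
    rng = np.random.default_rng(config.seed)

    dims = (X.shape[1],) + tuple(config.hidden_dims) + (1,)
    Ws = [Tensor(glorot_uniform(rng, dims[k], dims[k + 1]))
          for k in range(len(dims) - 1)]
    bs = [Tensor(np.zeros(dims[k + 1])) for k in range(len(dims) - 1)]
    params = Ws + bs
    opt = Adam(params, lr=config.learning_rate)

    n = X.shape[0]
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], y[idx]
            h = Tensor(xb)
            for W, b in zip(Ws[:-1], bs[:-1]):
                h = (h @ W + b).relu()
            z = (h @ Ws[-1] + bs[-1]).reshape(-1)
            # BCE with logits: mean( softplus(-z) + (1-y) z )
            loss = ((-z).softplus() + z * (1.0 - yb)).mean()
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(epoch)
            opt.zero_grad()
            loss.backward()
            opt.step()
    return MLPHead([W.data.copy() for W in Ws], [b.data.copy() for b in bs],
                   input_dim=X.shape[1])


def predict_scores(head: MLPHead, features: PairFeatures) -> np.ndarray:
    """Sigmoid scores in [0, 1], one per pair; deterministic forward pass."""
    z = head.logits(features.X_pair)
    with np.errstate(over="ignore"):
        return np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)),
                        np.exp(z) / (1.0 + np.exp(z)))
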