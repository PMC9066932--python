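"""Graph attention auto-encoder (GATE) for node representation learning.

The encoder stack turns node attributes into low-dimensional embeddings
by attending over graph neighbourhoods; a mirrored decoder stack
reconstructs the attributes.  For layer ``k`` with trainable weight
``W`` and attention vectors ``v_s``, ``v_r`` shared across nodes:

    c_ij   = sigmoid(v_s' s_i + v_r' s_j),   s_j = act(W h_j)
    alpha_ij = softmax_{j in N(i)} c_ij
    h_i^(k)  = sum_{j in N(i)} alpha_ij s_j

where ``N(i)`` includes ``i`` itself (the input graph carries
self-loops).  The decoder applies the same mechanism with independent
parameters, mapping dimensions back up to the input width.  Training
minimises

    Loss = sum_i ||x_i - xhat_i||_2
           - lambda * sum_i sum_{j in N(i)} log sigmoid(h_i' h_j)

i.e. an (unsquared) Euclidean attribute-reconstruction term plus a
structure term that pushes embeddings of neighbours together.  Each
undirected edge contributes once per direction.  Optimisation is
full-batch Adam; the activation ``act`` defaults to identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Adam, Tensor, glorot_uniform
from .errors import TrainingDivergedError, ValidationError
from .similarity import BinaryGraph

__all__ = [
    "GateConfig",
    "GateModel",
    "NodeFeatures",
    "Embedding",
    "attention_weights",
    "encoder_forward",
    "decoder_forward",
    "gate_loss",
    "train_gate",
]

_ACTIVATIONS = {
    "identity": lambda t: t,
    "relu": Tensor.relu,
    "sigmoid": Tensor.sigmoid,
}


@dataclass(frozen=True)
class GateConfig:
    """Hyperparameters of the auto-encoder.

    Defaults: two encoder layers of 128 and 64 units, learning rate
    1e-3, structure-loss weight ``lam`` = 1, dropout 0, 200 epochs,
    identity activation.
    """

    layer_dims: tuple[int, ...] = (128, 64)
    learning_rate: float = 1e-3
    lam: float = 1.0
    dropout: float = 0.0
    epochs: int = 200
    activation: str = "identity"
    seed: int = 0

    def __post_init__(self):
        if len(self.layer_dims) < 1 or any(d < 1 for d in self.layer_dims):
            raise ValidationError("layer_dims must be positive")
        if self.lam < 0:
            raise ValidationError("lam must be >= 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValidationError("dropout must be in [0, 1)")
        if self.activation not in _ACTIVATIONS:
            raise ValidationError(f"unknown activation {self.activation!r}")


@dataclass
class NodeFeatures:
    ids: tuple[str, ...]
    X: np.ndarray


@dataclass
class Embedding:
    ids: tuple[str, ...]
    H: np.ndarray


@dataclass
class GateModel:
    """Per-layer parameters of encoder and decoder (no weight tying).

    Encoder layer k maps d(k-1) -> d(k): weight (d(k), d(k-1)) with
    attention vectors of length d(k).  Decoder layer k maps
    d(k) -> d(k-1): weight (d(k-1), d(k)) with attention vectors of
    length d(k-1).
    """

    input_dim: int
    layer_dims: tuple[int, ...]
    enc_W: list[Tensor] = field(default_factory=list)
    enc_vs: list[Tensor] = field(default_factory=list)
    enc_vr: list[Tensor] = field(default_factory=list)
    dec_W: list[Tensor] = field(default_factory=list)
    dec_vs: list[Tensor] = field(default_factory=list)
    dec_vr: list[Tensor] = field(default_factory=list)

    @classmethod
    def init(cls, input_dim: int, config: GateConfig) -> "GateModel":
        rng = np.random.default_rng(config.seed)
        model = cls(input_dim, tuple(config.layer_dims))
        dims = (input_dim,) + tuple(config.layer_dims)
        for k in range(1, len(dims)):
            d_in, d_out = dims[k - 1], dims[k]
            model.enc_W.append(Tensor(glorot_uniform(rng, d_in, d_out, (d_out, d_in))))
            model.enc_vs.append(Tensor(glorot_uniform(rng, d_out, 1, (d_out,))))
            model.enc_vr.append(Tensor(glorot_uniform(rng, d_out, 1, (d_out,))))
        for k in range(1, len(dims)):
            d_hi, d_lo = dims[k], dims[k - 1]
            model.dec_W.append(Tensor(glorot_uniform(rng, d_hi, d_lo, (d_lo, d_hi))))
            model.dec_vs.append(Tensor(glorot_uniform(rng, d_lo, 1, (d_lo,))))
            model.dec_vr.append(Tensor(glorot_uniform(rng, d_lo, 1, (d_lo,))))
        return model

    def parameters(self) -> list[Tensor]:
        return (
            self.enc_W + self.enc_vs + self.enc_vr
            + self.dec_W + self.dec_vs + self.dec_vr
        )


def _layer(h, W, vs, vr, src, dst, n, act):
    """One attention layer on the edge list (src aggregates over dst)."""
    s = act(h @ W.T)                      # (n, d_out) transformed features
    e_s = s @ vs                          # (n,)
    e_r = s @ vr
    c = (e_s.take_rows(src) + e_r.take_rows(dst)).sigmoid()
    ec = c.exp()
    denom = ec.segment_sum(src, n)
    alpha = ec / denom.take_rows(src)
    msg = s.take_rows(dst) * alpha.reshape(-1, 1)
    return msg.segment_sum(src, n), alpha


def _dropout(h: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    if p <= 0.0:
        return h
    mask = (rng.random(h.shape) >= p) / (1.0 - p)
    return h * mask


def _check_graph(graph: BinaryGraph, n_rows: int) -> tuple[np.ndarray, np.ndarray]:
    if len(graph.ids) != n_rows:
        raise ValidationError(
            f"feature rows ({n_rows}) do not match graph nodes ({len(graph.ids)})"
        )
    return graph.edges()


def attention_weights(
    h_prev: np.ndarray,
    graph: BinaryGraph,
    model: GateModel,
    layer: int,
    direction: str = "encode",
    activation: str = "identity",
) -> np.ndarray:
    """Dense attention matrix alpha of one layer; zeros off the graph.

    ``h_prev`` is the layer's input representation (layer ``k``'s input
    is ``h^(k-1)`` for the encoder, ``hhat^(k)`` for the decoder).  Rows
    are normalised over each node's neighbour set, so every row sums
    to 1.
    """
    if direction not in ("encode", "decode"):
        raise ValidationError(f"direction must be encode/decode, got {direction!r}")
    act = _ACTIVATIONS[activation]
    src, dst = _check_graph(graph, h_prev.shape[0])
    n = len(graph.ids)
    if direction == "encode":
        W, vs, vr = model.enc_W[layer], model.enc_vs[layer], model.enc_vr[layer]
    else:
        W, vs, vr = model.dec_W[layer], model.dec_vs[layer], model.dec_vr[layer]
    _, alpha = _layer(Tensor(h_prev), W, vs, vr, src, dst, n, act)
    dense = np.zeros((n, n))
    dense[src, dst] = alpha.data
    return dense


def _encode(X_t, src, dst, n, model, act, dropout=0.0, rng=None):
    h = X_t
    intermediates = [h]
    for k in range(len(model.layer_dims)):
        h = _dropout(h, dropout, rng) if rng is not None else h
        h, _ = _layer(h, model.enc_W[k], model.enc_vs[k], model.enc_vr[k],
                      src, dst, n, act)
        intermediates.append(h)
    return h, intermediates


def _decode(H_t, src, dst, n, model, act, dropout=0.0, rng=None):
    h = H_t
    for k in reversed(range(len(model.layer_dims))):
        h = _dropout(h, dropout, rng) if rng is not None else h
        h, _ = _layer(h, model.dec_W[k], model.dec_vs[k], model.dec_vr[k],
                      src, dst, n, act)
    return h


def encoder_forward(
    X: NodeFeatures, graph: BinaryGraph, model: GateModel, config: GateConfig
) -> tuple[Embedding, list[np.ndarray]]:
    """Run the encoder stack; returns the embedding and all h^(k)."""
    if X.X.shape[1] != model.input_dim:
        raise ValidationError(
            f"feature width {X.X.shape[1]} != model input dim {model.input_dim}"
        )
    src, dst = _check_graph(graph, X.X.shape[0])
    act = _ACTIVATIONS[config.activation]
    h, inter = _encode(Tensor(X.X), src, dst, len(graph.ids), model, act)
    return Embedding(X.ids, h.data.copy()), [t.data.copy() for t in inter]


def decoder_forward(
    H: Embedding, graph: BinaryGraph, model: GateModel, config: GateConfig
) -> np.ndarray:
    """Run the decoder stack; returns reconstructed features (width d(0))."""
    if H.H.shape[1] != model.layer_dims[-1]:
        raise ValidationError(
            f"embedding width {H.H.shape[1]} != last layer dim {model.layer_dims[-1]}"
        )
    src, dst = _check_graph(graph, H.H.shape[0])
    act = _ACTIVATIONS[config.activation]
    out = _decode(Tensor(H.H), src, dst, len(graph.ids), model, act)
    return out.data.copy()


def _loss_tensor(X_const, Xhat_t, H_t, src, dst, lam):
    diff = Tensor(X_const) - Xhat_t
    feat = diff.row_norms_sum()
    hi = H_t.take_rows(src)
    hj = H_t.take_rows(dst)
    dots = (hi * hj).sum(axis=1)
    struct = dots.logsigmoid().sum()
    return feat - lam * struct


def gate_loss(
    X: np.ndarray, Xhat: np.ndarray, H: np.ndarray, graph: BinaryGraph, lam: float
) -> float:
    """Joint attribute + structure reconstruction loss (see module docstring)."""
    src, dst = graph.edges()
    return float(
        _loss_tensor(np.asarray(X, float), Tensor(Xhat), Tensor(H), src, dst, lam).data
    )


def train_gate(
    X: NodeFeatures, graph: BinaryGraph, config: GateConfig
) -> tuple[GateModel, Embedding, list[float]]:
    """Full-batch Adam minimisation of the joint loss.

    Returns the trained model, the final-layer embedding evaluated
    without dropout, and the per-epoch loss history (entry 0 is the loss
    before the first update).  Reproducible from ``config.seed``.
    """
    src, dst = _check_graph(graph, X.X.shape[0])
    n = len(graph.ids)
    act = _ACTIVATIONS[config.activation]
    model = GateModel.init(X.X.shape[1], config)
    params = model.parameters()
    opt = Adam(params, lr=config.learning_rate)
    drop_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    X_const = np.asarray(X.X, dtype=np.float64)
    history: list[float] = []
    for epoch in range(config.epochs):
        rng = drop_rng if config.dropout > 0 else None
        H_t, _ = _encode(Tensor(X_const), src, dst, n, model, act,
                         config.dropout, rng)
        Xhat_t = _decode(H_t, src, dst, n, model, act, config.dropout, rng)
        loss = _loss_tensor(X_const, Xhat_t, H_t, src, dst, config.lam)
        if not np.isfinite(loss.data):
            raise TrainingDivergedError(epoch)
        history.append(float(loss.data))
        opt.zero_grad()
        loss.backward()
        opt.step()
    H_final, _ = _encode(Tensor(X_const), src, dst, n, model, act)
    return model, Embedding(X.ids, H_final.data.copy()), history
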