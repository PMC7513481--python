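"""Five-layer feed-forward classifier over pair feature vectors.

The predictor maps an aggregated pair vector through ReLU layers to a
two-unit softmax head; the second component s(a_ij) is the predicted
interaction probability. Training is mini-batch Adam on the two-class
cross-entropy. Because concatenation is order-sensitive, pair scores are by
default symmetrized at prediction time by averaging s over both orderings
[Z_i, Z_j] and [Z_j, Z_i].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._optim import Adam
from .encoder import EmbeddingMatrix, glorot
from .features import PairDataset, aggregate_batch, pair_feature_dim

__all__ = [
    "PredictorConfig",
    "PredictorState",
    "init_predictor",
    "predictor_forward",
    "predictor_loss",
    "train_predictor",
    "predict_pair_scores",
]

_CLIP = 1e-10


@dataclass(frozen=True)
class PredictorConfig:
    """Predictor hyperparameters.

    ``layer_sizes`` lists neuron counts per layer including input and the
    two-unit output; the default (256, 128, 64, 32, 2) matches a
    concatenation of two 128-dimensional embeddings.
    """

    learning_rate: float = 0.01
    epochs: int = 140
    batch_size: int = 50
    dropout: float = 0.001
    layer_sizes: tuple = (256, 128, 64, 32, 2)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "layer_sizes", tuple(int(s) for s in self.layer_sizes))
        if self.learning_rate <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate, epochs and batch_size must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if len(self.layer_sizes) < 2:
            raise ValueError("need at least input and output layers")
        if self.layer_sizes[-1] != 2:
            raise ValueError("output layer must have 2 units (no-interaction / interaction)")
        if any(s <= 0 for s in self.layer_sizes):
            raise ValueError("layer sizes must be positive")

    @property
    def input_dim(self) -> int:
        return self.layer_sizes[0]

    def for_input_dim(self, dim: int) -> "PredictorConfig":
        """Same hidden architecture, adapted to a new input width."""
        return replace(self, layer_sizes=(dim,) + self.layer_sizes[1:])

    def replace(self, **kw) -> "PredictorConfig":
        return replace(self, **kw)


@dataclass
class PredictorState:
    """Per-layer weights and biases of the feed-forward classifier."""

    weights: list
    biases: list
    config: PredictorConfig
    trained: bool = field(default=False)

    def __post_init__(self):
        sizes = self.config.layer_sizes
        for k, (W, b) in enumerate(zip(self.weights, self.biases)):
            if W.shape != (sizes[k], sizes[k + 1]) or b.shape != (sizes[k + 1],):
                raise ValueError(f"layer {k} shape mismatch: {W.shape} vs {sizes[k:k+2]}")
            if not (np.isfinite(W).all() and np.isfinite(b).all()):
                raise ValueError("predictor parameters must be finite")


def init_predictor(config: PredictorConfig) -> PredictorState:
    rng = np.random.default_rng(config.seed)
    sizes = config.layer_sizes
    weights = [glorot(rng, sizes[k], sizes[k + 1]) for k in range(len(sizes) - 1)]
    biases = [np.zeros(sizes[k + 1]) for k in range(len(sizes) - 1)]
    return PredictorState(weights, biases, config)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def predictor_forward(state: PredictorState, x) -> np.ndarray:
    """Forward pass; returns (P(no-interaction), P(interaction)) per record.

    Accepts a single vector or an (n, d) batch; components sum to 1.
    """
    X = np.asarray(x, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != state.config.input_dim:
        raise ValueError(
            f"input has {X.shape[1]} features, predictor expects {state.config.input_dim}"
        )
    H = X
    n_layers = len(state.weights)
    for k in range(n_layers - 1):
        H = np.maximum(H @ state.weights[k] + state.biases[k], 0.0)
    probs = _softmax(H @ state.weights[-1] + state.biases[-1])
    return probs[0] if single else probs


def predictor_loss(probs: np.ndarray, labels) -> float:
    """Mean two-class cross-entropy: -log of the probability of the true class."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    y = np.asarray(labels, dtype=int).ravel()
    if probs.shape[0] != y.size:
        raise ValueError(f"{probs.shape[0]} predictions vs {y.size} labels")
    p_true = np.clip(probs[np.arange(y.size), y], _CLIP, None)
    return float(-np.log(p_true).mean())


def train_predictor(dataset: PairDataset, config: PredictorConfig):
    """Mini-batch Adam training on the cross-entropy.

    Shuffling, initialization and dropout are all driven by ``config.seed``;
    the same seed reproduces the loss trace exactly. Returns the trained
    state and the per-epoch mean loss trace.
    """
    X, y = dataset.X, dataset.y
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(f"training set contains a single class {classes.tolist()}")
    if X.shape[1] != config.input_dim:
        config = config.for_input_dim(X.shape[1])
    state = init_predictor(config)
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31))
    opt = Adam([p for pair in zip(state.weights, state.biases) for p in pair],
               lr=config.learning_rate)
    n = X.shape[0]
    keep = 1.0 - config.dropout
    trace = np.empty(config.epochs)

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, sizes = [], []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            loss, grads = _batch_grads(state, X[idx], y[idx], rng, keep)
            opt.step(grads)
            losses.append(loss)
            sizes.append(idx.size)
        trace[epoch] = np.average(losses, weights=sizes)
        if not np.isfinite(trace[epoch]):
            raise FloatingPointError(f"predictor loss diverged at epoch {epoch}")
    state.trained = True
    return state, trace


def _batch_grads(state: PredictorState, X, y, rng, keep):
    Ws, bs = state.weights, state.biases
    n_layers = len(Ws)
    acts = [X]
    pre = []
    masks = []
    H = X
    for k in range(n_layers - 1):
        if keep < 1.0:
            mask = rng.binomial(1, keep, size=H.shape) / keep
            H = H * mask
        else:
            mask = None
        masks.append(mask)
        acts[-1] = H  # dropped input actually fed to layer k
        P = H @ Ws[k] + bs[k]
        pre.append(P)
        H = np.maximum(P, 0.0)
        acts.append(H)
    if keep < 1.0:
        mask = rng.binomial(1, keep, size=H.shape) / keep
        H = H * mask
    else:
        mask = None
    masks.append(mask)
    acts[-1] = H
    logits = H @ Ws[-1] + bs[-1]
    probs = _softmax(logits)
    nb = X.shape[0]
    loss = predictor_loss(probs, y)

    onehot = np.zeros_like(probs)
    onehot[np.arange(nb), y] = 1.0
    dlogits = (probs - onehot) / nb
    gW = [None] * n_layers
    gb = [None] * n_layers
    delta = dlogits
    for k in range(n_layers - 1, -1, -1):
        gW[k] = acts[k].T @ delta
        gb[k] = delta.sum(axis=0)
        if k > 0:
            dH = delta @ Ws[k].T
            if masks[k] is not None:
                dH = dH * masks[k]
            delta = dH * (pre[k - 1] > 0)
    grads = [g for pair in zip(gW, gb) for g in pair]
    return loss, grads


def predict_pair_scores(state: PredictorState, Z: EmbeddingMatrix, pairs,
                        op_name: str, symmetrize: bool = True) -> np.ndarray:
    """Interaction probability s(a_ij) for each pair of drug indices.

    With the order-sensitive concatenation operator the score is averaged
    over both orderings so that score(i, j) == score(j, i); symmetric
    operators are unaffected.
    """
    if not state.trained:
        raise ValueError("predictor has not been trained")
    pairs = [tuple(p) for p in pairs]
    if not pairs:
        return np.empty(0)
    m = Z.n_drugs
    for i, j in pairs:
        if not (0 <= i < m and 0 <= j < m):
            raise KeyError(f"pair ({i}, {j}) indexes outside the {m}-drug embedding")
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    X = aggregate_batch(op_name, Z.Z[ii], Z.Z[jj])
    s = predictor_forward(state, X)[:, 1]
    if symmetrize and op_name == "concatenation":
        X_rev = aggregate_batch(op_name, Z.Z[jj], Z.Z[ii])
        s = 0.5 * (s + predictor_forward(state, X_rev)[:, 1])
    return s
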