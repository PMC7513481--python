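"""Two-layer graph-convolutional autoencoder over the DDI network.

The encoder maps the normalized adjacency to per-drug embeddings

    Z = ReLU( A_hat . ReLU( A_hat . H0 . W0 ) . W1 )

with H0 the node feature matrix (the identity when drugs carry no input
features). It is trained full-batch with Adam to reconstruct the adjacency
through an inner-product decoder q(a_ij) = sigmoid(z_i . z_j), under a
positive-weighted binary cross-entropy: the positive term is weighted by
W_pos, the ratio of unlabeled to annotated pairs, which counteracts the
extreme class imbalance of sparse DDI networks.

Numerical notes: probabilities are clipped to [1e-10, 1 - 1e-10] inside the
loss (ReLU embeddings can be exactly zero, putting q exactly at 0.5, but
trained embeddings can also saturate the sigmoid); diagonal entries are
excluded from the loss because a self-interaction is undefined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from ._optim import Adam
from .network import DDINetwork, NormalizedAdjacency, count_unlabeled_pairs, normalize_adjacency

__all__ = [
    "EncoderConfig",
    "EncoderState",
    "EmbeddingMatrix",
    "init_encoder",
    "encoder_forward",
    "reconstruction_scores",
    "positive_weight",
    "extractor_loss",
    "train_encoder",
    "glorot",
]

logger = logging.getLogger(__name__)

_CLIP = 1e-10


@dataclass(frozen=True)
class EncoderConfig:
    """Feature-extractor hyperparameters.

    Defaults are the tuned dataset-scale values (full-batch training,
    learning rate 1e-3, 1400 epochs, dropout 1e-4, hidden 512, embedding
    128); synthetic-network experiments in this package use a smaller
    configuration, see the methods note.
    """

    learning_rate: float = 0.001
    epochs: int = 1400
    dropout: float = 0.0001
    hidden_dim: int = 512
    embedding_dim: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs <= 0:
            raise ValueError("epochs must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.hidden_dim <= 0 or self.embedding_dim <= 0:
            raise ValueError("layer dimensions must be positive")
        if self.embedding_dim > self.hidden_dim:
            raise ValueError(
                f"embedding_dim {self.embedding_dim} exceeds hidden_dim {self.hidden_dim}"
            )

    def replace(self, **kw) -> "EncoderConfig":
        return replace(self, **kw)


@dataclass
class EncoderState:
    """Learned GCN weights W0 (input -> hidden) and W1 (hidden -> embedding)."""

    W0: np.ndarray
    W1: np.ndarray
    config: EncoderConfig
    trained: bool = False

    def __post_init__(self):
        if self.W0.shape[1] != self.config.hidden_dim:
            raise ValueError("W0 width does not match hidden_dim")
        if self.W1.shape != (self.config.hidden_dim, self.config.embedding_dim):
            raise ValueError("W1 shape does not match config")
        if not (np.isfinite(self.W0).all() and np.isfinite(self.W1).all()):
            raise ValueError("encoder weights must be finite")


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Per-drug latent vectors; row i is the embedding of drug i.

    Entries are non-negative because the final layer is a ReLU.
    """

    Z: np.ndarray

    def __post_init__(self):
        if (np.asarray(self.Z) < 0).any():
            raise ValueError("embeddings are ReLU outputs and must be >= 0")

    @property
    def n_drugs(self) -> int:
        return self.Z.shape[0]

    @property
    def dim(self) -> int:
        return self.Z.shape[1]

    def to_frame(self, drug_ids):
        import pandas as pd

        return pd.DataFrame(self.Z, index=list(drug_ids),
                            columns=[f"z{k}" for k in range(self.dim)])


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot/Xavier uniform init: Var = 2 / (fan_in + fan_out)."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_encoder(config: EncoderConfig, m: int, n_features: int | None = None) -> EncoderState:
    """Seeded Glorot initialization; ``n_features`` defaults to m (identity
    input features)."""
    if m < 1:
        raise ValueError("need at least one drug")
    f = m if n_features is None else n_features
    rng = np.random.default_rng(config.seed)
    W0 = glorot(rng, f, config.hidden_dim)
    W1 = glorot(rng, config.hidden_dim, config.embedding_dim)
    return EncoderState(W0, W1, config)


def _resolve_h0(H0, m: int) -> np.ndarray:
    if isinstance(H0, str):
        if H0 != "identity":
            raise ValueError(f"unknown feature mode {H0!r}")
        return np.eye(m)
    H0 = np.asarray(H0, dtype=float)
    if H0.shape[0] != m:
        raise ValueError(f"feature matrix has {H0.shape[0]} rows for {m} drugs")
    return H0


def encoder_forward(state: EncoderState, A_hat: NormalizedAdjacency, H0="identity") -> EmbeddingMatrix:
    """Deterministic forward pass (no dropout): Z = ReLU(A_hat ReLU(A_hat H0 W0) W1)."""
    Ah = A_hat.matrix
    m = Ah.shape[0]
    X0 = Ah @ _resolve_h0(H0, m)
    if X0.shape[1] != state.W0.shape[0]:
        raise ValueError(
            f"feature dim {X0.shape[1]} does not match W0 input dim {state.W0.shape[0]}"
        )
    H1 = np.maximum(X0 @ state.W0, 0.0)
    Z = np.maximum(Ah @ H1 @ state.W1, 0.0)
    return EmbeddingMatrix(Z)


def reconstruction_scores(Z: EmbeddingMatrix) -> np.ndarray:
    """Inner-product decoder: q(a_ij) = sigmoid(z_i . z_j); symmetric."""
    return expit(Z.Z @ Z.Z.T)


def positive_weight(net: DDINetwork) -> float:
    """W_pos = (# unlabeled pairs) / (# annotated pairs), unordered counts."""
    if net.n_edges == 0:
        raise ValueError("positive weight undefined with zero positive pairs")
    return count_unlabeled_pairs(net) / net.n_edges


def extractor_loss(q: np.ndarray, labels: np.ndarray, w_pos: float,
                   exclude_diagonal: bool = True) -> float:
    """Positive-weighted binary cross-entropy, averaged over trained entries.

    loss = mean_ij of -[ p * W_pos * log q + (1 - p) * log(1 - q) ]
    """
    q = np.asarray(q, dtype=float)
    p = np.asarray(labels, dtype=float)
    if q.shape != p.shape:
        raise ValueError(f"shape mismatch: scores {q.shape} vs labels {p.shape}")
    if ((q <= 0) | (q >= 1)).any():
        logger.debug("clipping reconstruction probabilities at %g", _CLIP)
    q = np.clip(q, _CLIP, 1 - _CLIP)
    terms = -(p * np.log(q) * w_pos + (1 - p) * np.log1p(-q))
    if exclude_diagonal and terms.ndim == 2 and terms.shape[0] == terms.shape[1]:
        mask = ~np.eye(terms.shape[0], dtype=bool)
        return float(terms[mask].mean())
    return float(terms.mean())


def train_encoder(net: DDINetwork, config: EncoderConfig, H0="identity",
                  w_pos: float | None = None):
    """Train the autoencoder on a network's adjacency.

    Runs ``config.epochs`` full-batch Adam steps minimizing the weighted
    reconstruction cross-entropy over all off-diagonal adjacency entries.

    Returns
    -------
    (EncoderState, EmbeddingMatrix, ndarray)
        Trained state, final embeddings (computed without dropout) and the
        per-epoch loss trace.
    """
    m = net.n_drugs
    Ah = normalize_adjacency(net).matrix
    H0m = _resolve_h0(H0, m)
    if w_pos is None:
        w_pos = positive_weight(net)
    labels = net.adjacency.astype(float)
    offdiag = ~np.eye(m, dtype=bool)
    n_entries = offdiag.sum()

    state = init_encoder(config, m, n_features=H0m.shape[1])
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31))
    opt = Adam([state.W0, state.W1], lr=config.learning_rate)
    X0_clean = Ah @ H0m
    keep = 1.0 - config.dropout
    trace = np.empty(config.epochs)

    for epoch in range(config.epochs):
        if config.dropout > 0:
            X0 = X0_clean * rng.binomial(1, keep, size=X0_clean.shape) / keep
        else:
            X0 = X0_clean
        P1 = X0 @ state.W0
        H1 = np.maximum(P1, 0.0)
        if config.dropout > 0:
            mask1 = rng.binomial(1, keep, size=H1.shape) / keep
            H1d = H1 * mask1
        else:
            mask1 = None
            H1d = H1
        AH1 = Ah @ H1d
        P2 = AH1 @ state.W1
        Z = np.maximum(P2, 0.0)
        S = Z @ Z.T
        q = expit(S)

        qc = np.clip(q, _CLIP, 1 - _CLIP)
        loss_terms = -(labels * np.log(qc) * w_pos + (1 - labels) * np.log1p(-qc))
        loss = float(loss_terms[offdiag].mean())
        if not np.isfinite(loss):
            raise FloatingPointError(f"encoder loss diverged at epoch {epoch}")
        trace[epoch] = loss

        # dL/dS for the weighted BCE through the sigmoid
        G = (-w_pos * labels * (1 - q) + (1 - labels) * q) / n_entries
        G[np.diag_indices(m)] = 0.0
        dZ = (G + G.T) @ Z
        dP2 = dZ * (P2 > 0)
        dW1 = AH1.T @ dP2
        dH1d = Ah @ dP2 @ state.W1.T
        dH1 = dH1d if mask1 is None else dH1d * mask1
        dP1 = dH1 * (P1 > 0)
        dW0 = X0.T @ dP1
        opt.step([dW0, dW1])

    state.trained = True
    Z_final = encoder_forward(state, NormalizedAdjacency(Ah, net), H0m)
    return state, Z_final, trace
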