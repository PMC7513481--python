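"""Model/Results facade over the full pipeline.

``DPDDI`` bundles the three phases — graph-convolutional embedding of the
DDI network, pair-feature aggregation, and feed-forward classification —
behind a single model object whose :meth:`fit` returns a
:class:`DPDDIResults` carrying the learned embeddings, loss traces,
prediction and ranking methods, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __about__
from .encoder import (
    EncoderConfig,
    EncoderState,
    EmbeddingMatrix,
    positive_weight,
    train_encoder,
)
from .evaluation import CVReport, RankedPredictions, rank_novel_pairs, run_cross_validation
from .features import AGGREGATORS, build_pair_dataset, pair_feature_dim
from .network import DDINetwork, load_edge_list, network_sparsity, sample_negatives
from .predictor import PredictorConfig, PredictorState, predict_pair_scores, train_predictor

__all__ = ["DPDDI", "DPDDIResults"]


class DPDDI:
    """Drug-drug interaction link predictor over a DDI network.

    Parameters
    ----------
    network : DDINetwork
        The annotated interaction network (positives).
    operator : str
        Pair aggregation operator; concatenation by default.
    ratio : int or "all"
        Negatives sampled per positive for predictor training.
    encoder_config, predictor_config : optional
        Hyperparameters; defaults are the tuned dataset-scale values.
    """

    def __init__(self, network: DDINetwork, operator: str = "concatenation",
                 ratio=1, encoder_config: EncoderConfig | None = None,
                 predictor_config: PredictorConfig | None = None,
                 symmetrize: bool = True):
        if operator not in AGGREGATORS:
            raise ValueError(f"unknown operator {operator!r}; choose from {AGGREGATORS}")
        self.network = network
        self.operator = operator
        self.ratio = ratio
        self.encoder_config = encoder_config or EncoderConfig()
        self.predictor_config = predictor_config or PredictorConfig()
        self.symmetrize = symmetrize

    @classmethod
    def from_edge_list(cls, path, **kwargs) -> "DPDDI":
        return cls(load_edge_list(path), **kwargs)

    def fit(self, seed: int = 0) -> "DPDDIResults":
        """Train encoder then predictor on the full network.

        All randomness (weight init, dropout, negative sampling, batch
        shuffling) derives from ``seed``.
        """
        sub = np.random.default_rng(seed).integers(2**31, size=3)
        enc_cfg = self.encoder_config.replace(seed=int(sub[0]))
        enc_state, Z, enc_trace = train_encoder(self.network, enc_cfg)

        negatives = sample_negatives(self.network, self.ratio, int(sub[1]))
        positives = self.network.edges
        pairs = positives + negatives
        labels = [1] * len(positives) + [0] * len(negatives)
        ds = build_pair_dataset(Z.Z, pairs, labels, self.operator)
        pred_cfg = self.predictor_config.for_input_dim(
            pair_feature_dim(self.operator, Z.dim)).replace(seed=int(sub[2]))
        pred_state, pred_trace = train_predictor(ds, pred_cfg)

        return DPDDIResults(model=self, seed=seed, encoder_state=enc_state,
                            embeddings=Z, predictor_state=pred_state,
                            encoder_loss=enc_trace, predictor_loss=pred_trace,
                            n_negatives=len(negatives))

    def cross_validate(self, n_runs: int = 10, seed: int = 0,
                       leaky_encoder: bool = False) -> CVReport:
        """The repeated 5-fold cross-validation protocol on this network."""
        return run_cross_validation(self.network, self.encoder_config,
                                    self.predictor_config, ratio=self.ratio,
                                    operator=self.operator, n_runs=n_runs,
                                    seed=seed, leaky_encoder=leaky_encoder,
                                    symmetrize=self.symmetrize)


@dataclass
class DPDDIResults:
    """Fitted pipeline: embeddings, trained predictor, traces and reports."""

    model: DPDDI
    seed: int
    encoder_state: EncoderState
    embeddings: EmbeddingMatrix
    predictor_state: PredictorState
    encoder_loss: np.ndarray
    predictor_loss: np.ndarray
    n_negatives: int
    _extras: dict = field(default_factory=dict, repr=False)

    # -- prediction --------------------------------------------------------
    def predict_pairs(self, pairs) -> np.ndarray:
        """Interaction probability for index pairs (or drug-id pairs)."""
        idx_pairs = [self._as_index_pair(p) for p in pairs]
        return predict_pair_scores(self.predictor_state, self.embeddings,
                                   idx_pairs, self.model.operator,
                                   symmetrize=self.model.symmetrize)

    def rank_novel(self, top_k: int = 20) -> RankedPredictions:
        """Top-k unlabeled pairs by predicted interaction probability."""
        return rank_novel_pairs(self.predictor_state, self.embeddings,
                                self.model.network, top_k,
                                op_name=self.model.operator,
                                symmetrize=self.model.symmetrize)

    def _as_index_pair(self, p):
        i, j = p
        net = self.model.network
        if isinstance(i, str):
            i = net.index_of(i)
        if isinstance(j, str):
            j = net.index_of(j)
        return (i, j)

    # -- reporting -----------------------------------------------------------
    def embeddings_frame(self) -> pd.DataFrame:
        return self.embeddings.to_frame(self.model.network.drug_ids)

    def summary(self) -> str:
        net = self.model.network
        lines = [
            f"DPDDI results (dpddi {__about__.__version__})",
            f"  network: {net.n_drugs} drugs, {net.n_edges} interactions "
            f"(sparsity {100 * network_sparsity(net):.1f}%)",
            f"  positive weight W_pos = {positive_weight(net):.2f}",
            f"  embeddings: {self.embeddings.n_drugs} x {self.embeddings.dim}",
            f"  operator: {self.model.operator}; negatives per positive: {self.model.ratio}"
            f" ({self.n_negatives} sampled)",
            f"  encoder loss: {self.encoder_loss[0]:.4f} -> {self.encoder_loss[-1]:.4f} "
            f"over {self.encoder_loss.size} epochs",
            f"  predictor loss: {self.predictor_loss[0]:.4f} -> {self.predictor_loss[-1]:.4f} "
            f"over {self.predictor_loss.size} epochs",
            f"  seed: {self.seed}",
        ]
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        """Loss traces of both training stages (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.encoder_loss, label="encoder (reconstruction)")
        ax.plot(self.predictor_loss, label="predictor (cross-entropy)")
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax.legend()
        return ax
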