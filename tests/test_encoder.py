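"""Graph-convolutional autoencoder: initialization, forward pass,
reconstruction decoding, weighted loss, and training behaviour."""

import numpy as np
import pytest
from scipy.special import expit

from dpddi.encoder import (
    EncoderConfig,
    EncoderState,
    EmbeddingMatrix,
    encoder_forward,
    extractor_loss,
    init_encoder,
    positive_weight,
    reconstruction_scores,
    train_encoder,
)
from dpddi.network import DDINetwork, NormalizedAdjacency, normalize_adjacency

from conftest import SMOKE_ENCODER


class TestConfig:
    def test_defaults_are_tuned_values(self):
        cfg = EncoderConfig()
        assert (cfg.learning_rate, cfg.epochs, cfg.dropout) == (0.001, 1400, 0.0001)
        assert (cfg.hidden_dim, cfg.embedding_dim) == (512, 128)

    @pytest.mark.parametrize("kw", [
        {"learning_rate": 0}, {"epochs": 0}, {"dropout": 1.0},
        {"hidden_dim": -1}, {"hidden_dim": 8, "embedding_dim": 16},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            EncoderConfig(**kw)


class TestInit:
    def test_shapes(self):
        cfg = EncoderConfig(hidden_dim=4, embedding_dim=2)
        st = init_encoder(cfg, m=10)
        assert st.W0.shape == (10, 4)
        assert st.W1.shape == (4, 2)

    def test_seed_reproducibility(self):
        cfg = EncoderConfig(hidden_dim=4, embedding_dim=2, seed=11)
        a, b = init_encoder(cfg, 10), init_encoder(cfg, 10)
        np.testing.assert_array_equal(a.W0, b.W0)
        np.testing.assert_array_equal(a.W1, b.W1)

    def test_glorot_variance(self):
        cfg = EncoderConfig(hidden_dim=4, embedding_dim=2, seed=0)
        st = init_encoder(cfg, m=1000)
        target = 2.0 / (1000 + 4)
        assert abs(st.W0.var() - target) / target < 0.2


class TestForward:
    def test_single_node_identity(self):
        net = DDINetwork(("a",), np.zeros((1, 1)))
        cfg = EncoderConfig(hidden_dim=1, embedding_dim=1)
        st = EncoderState(np.array([[1.0]]), np.array([[1.0]]), cfg)
        Z = encoder_forward(st, normalize_adjacency(net))
        np.testing.assert_allclose(Z.Z, [[1.0]])

    def test_negative_final_weights_give_zero_embeddings(self, sbm30):
        cfg = EncoderConfig(hidden_dim=4, embedding_dim=3, seed=0)
        st = init_encoder(cfg, sbm30.n_drugs)
        st.W1 = -np.abs(st.W1)
        Z = encoder_forward(st, normalize_adjacency(sbm30))
        np.testing.assert_array_equal(Z.Z, 0.0)

    def test_two_node_hand_computed(self, two_node):
        cfg = EncoderConfig(hidden_dim=1, embedding_dim=1)
        st = EncoderState(np.ones((2, 1)), np.ones((1, 1)), cfg)
        Z = encoder_forward(st, normalize_adjacency(two_node))
        np.testing.assert_allclose(Z.Z, [[1.0], [1.0]])

    def test_shape_mismatch_named(self, sbm30):
        cfg = EncoderConfig(hidden_dim=4, embedding_dim=2)
        st = init_encoder(cfg, m=7)  # wrong m on purpose
        with pytest.raises(ValueError, match="30"):
            encoder_forward(st, normalize_adjacency(sbm30))

    def test_matches_dense_matrix_oracle(self, rng):
        """Forward pass equals the literal two-layer matrix formula on random
        small graphs and random weights (100 trials)."""
        for _ in range(100):
            m = int(rng.integers(2, 9))
            A = np.triu((rng.random((m, m)) < 0.5).astype(int), 1)
            net = DDINetwork(tuple(f"d{k}" for k in range(m)), A + A.T)
            h1, h2 = int(rng.integers(1, 5)), 1
            cfg = EncoderConfig(hidden_dim=h1, embedding_dim=h2)
            st = EncoderState(rng.normal(size=(m, h1)), rng.normal(size=(h1, h2)), cfg)
            Ah = normalize_adjacency(net).matrix
            expected = np.maximum(Ah @ np.maximum(Ah @ np.eye(m) @ st.W0, 0) @ st.W1, 0)
            got = encoder_forward(st, normalize_adjacency(net)).Z
            np.testing.assert_allclose(got, expected, atol=1e-9)


class TestReconstruction:
    def test_orthogonal_rows_give_half(self):
        Z = EmbeddingMatrix(np.eye(3))
        q = reconstruction_scores(Z)
        off = q[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.5)

    def test_scalar_sigmoid_value(self):
        Z = EmbeddingMatrix(np.array([[1.0, 2.0], [2.0, 1.0]]))
        assert reconstruction_scores(Z)[0, 1] == pytest.approx(expit(4.0), abs=1e-4)
        assert reconstruction_scores(Z)[0, 1] == pytest.approx(0.9820, abs=1e-4)

    def test_symmetric_and_in_unit_interval(self, rng):
        Z = EmbeddingMatrix(np.abs(rng.normal(size=(20, 5))))
        q = reconstruction_scores(Z)
        np.testing.assert_allclose(q, q.T, atol=1e-9)
        assert ((q > 0) & (q < 1)).all()


class TestPositiveWeight:
    def test_ten_positives_of_45_pairs(self, rng):
        edges = set()
        while len(edges) < 10:
            i, j = sorted(rng.choice(10, 2, replace=False))
            edges.add((int(i), int(j)))
        net = DDINetwork.from_edges([str(k) for k in range(10)], sorted(edges))
        assert positive_weight(net) == pytest.approx(3.5)

    def test_complete_graph_zero(self, k3):
        assert positive_weight(k3) == 0.0

    def test_balanced_network_one(self):
        # 3 edges among 4 drugs: C(4,2)=6 pairs, 3 pos, 3 neg
        net = DDINetwork.from_edges("abcd", [(0, 1), (1, 2), (2, 3)])
        assert positive_weight(net) == 1.0

    def test_zero_positives_errors(self):
        net = DDINetwork(("a", "b"), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            positive_weight(net)


class TestExtractorLoss:
    def test_single_positive_at_half(self):
        q = np.array([[0.5]])
        p = np.array([[1.0]])
        assert extractor_loss(q, p, w_pos=1.0, exclude_diagonal=False) == \
            pytest.approx(np.log(2), abs=1e-12)

    def test_perfect_reconstruction_near_zero(self):
        p = np.array([[0.0, 1.0], [1.0, 0.0]])
        q = np.clip(p, 1e-12, 1 - 1e-12)
        assert extractor_loss(q, p, w_pos=2.0) < 1e-8

    def test_linear_in_positive_weight(self, rng):
        q = rng.uniform(0.1, 0.9, size=(6, 6))
        q = (q + q.T) / 2
        p = (rng.random((6, 6)) < 0.3).astype(float)
        p = np.triu(p, 1) + np.triu(p, 1).T
        l1 = extractor_loss(q, p, w_pos=1.0)
        l2 = extractor_loss(q, p, w_pos=2.0)
        mask = ~np.eye(6, dtype=bool)
        pos_term = -(p * np.log(q))[mask].mean()
        assert l2 - l1 == pytest.approx(pos_term, rel=1e-9)

    def test_matches_entrywise_oracle_unweighted(self, rng):
        """With W_pos = 1 the loss equals plain binary cross-entropy computed
        entry by entry."""
        q = rng.uniform(0.05, 0.95, size=(5, 5))
        p = (rng.random((5, 5)) < 0.5).astype(float)
        oracle = []
        for i in range(5):
            for j in range(5):
                if i != j:
                    oracle.append(-(p[i, j] * np.log(q[i, j])
                                    + (1 - p[i, j]) * np.log(1 - q[i, j])))
        assert extractor_loss(q, p, w_pos=1.0) == pytest.approx(np.mean(oracle), abs=1e-9)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            extractor_loss(np.ones((2, 2)) / 2, np.zeros((3, 3)), 1.0)


class TestTraining:
    def test_loss_decreases_on_fixture(self, sbm30):
        _, _, trace = train_encoder(sbm30, SMOKE_ENCODER.replace(epochs=200, seed=0))
        assert np.isfinite(trace).all()
        assert trace[-1] < trace[0]

    def test_same_seed_identical_traces(self, sbm30):
        cfg = SMOKE_ENCODER.replace(seed=3, dropout=0.1)
        _, Z1, t1 = train_encoder(sbm30, cfg)
        _, Z2, t2 = train_encoder(sbm30, cfg)
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_array_equal(Z1.Z, Z2.Z)

    def test_early_epochs_decrease_on_seeds(self, sbm30):
        for seed in range(5):
            _, _, trace = train_encoder(sbm30, SMOKE_ENCODER.replace(epochs=10, seed=seed))
            assert trace[-1] < trace[0]

    def test_trained_flag_and_nonnegative_embeddings(self, sbm30):
        state, Z, _ = train_encoder(sbm30, SMOKE_ENCODER)
        assert state.trained
        assert (Z.Z >= 0).all()
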