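"""Synthetic DDI networks with planted community structure, plus the
deterministic fixture suite used throughout the tests.

Real DDI networks are sparse (roughly 10-35% of all drug pairs annotated)
and clustered: drugs sharing pharmacology interact with overlapping partner
sets. A stochastic block model (SBM) reproduces exactly the property link
prediction needs — within-community pairs are more likely to interact — so
an embedding-based predictor has recoverable signal. Degree heterogeneity
of curated databases is deliberately not modelled; see the methods note.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .features import PropertyFeatureTable, encode_atc_onehot
from .network import DDINetwork

__all__ = [
    "SBMSpec",
    "block_labels",
    "generate_sbm_network",
    "expected_density",
    "generate_fixture_suite",
    "BENCHMARK_SBM",
    "SMALL_SBM",
]


@dataclass(frozen=True)
class SBMSpec:
    """Planted-partition model: each unordered pair is an edge independently
    with probability p_in (same block) or p_out (different blocks)."""

    n_drugs: int
    n_blocks: int
    p_in: float
    p_out: float
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError(f"need 0 <= p_out < p_in <= 1, got {self.p_out}, {self.p_in}")
        if not 1 <= self.n_blocks <= self.n_drugs:
            raise ValueError("n_blocks must be between 1 and n_drugs")


# the benchmark regimes: a 200-drug, 4-community network whose density sits
# in the sparse range of curated DDI databases, and a 30-drug smoke fixture
BENCHMARK_SBM = SBMSpec(n_drugs=200, n_blocks=4, p_in=0.3, p_out=0.02, seed=7)
SMALL_SBM = SBMSpec(n_drugs=30, n_blocks=2, p_in=0.4, p_out=0.05, seed=7)


def block_labels(spec: SBMSpec) -> np.ndarray:
    """Deterministic contiguous block assignment (sizes differ by <= 1)."""
    return np.sort(np.arange(spec.n_drugs) % spec.n_blocks)


def generate_sbm_network(spec: SBMSpec) -> DDINetwork:
    """Sample a DDI network from the planted-partition model (seeded)."""
    n = spec.n_drugs
    labels = block_labels(spec)
    same = labels[:, None] == labels[None, :]
    probs = np.where(same, spec.p_in, spec.p_out)
    rng = np.random.default_rng(spec.seed)
    upper = np.triu(rng.random((n, n)) < probs, k=1)
    A = (upper | upper.T).astype(np.int8)
    width = len(str(n - 1))
    ids = tuple(f"D{idx:0{width}d}" for idx in range(n))
    return DDINetwork(ids, A)


def expected_density(spec: SBMSpec) -> float:
    """Closed-form expected fraction of pairs that are edges."""
    sizes = np.bincount(block_labels(spec), minlength=spec.n_blocks)
    within = float((sizes * (sizes - 1) // 2).sum())
    total = spec.n_drugs * (spec.n_drugs - 1) / 2
    return (within * spec.p_in + (total - within) * spec.p_out) / total


_TOY_ATC_CODES = [
    "A01AA01", "A02BC05", "B01AC06", "C07AB02", "C09AA05",
    "J01CA04", "L01XE07", "M01AE01", "N02BE01", "R03AC02",
]


def generate_fixture_suite(out_dir) -> list:
    """Write the canonical plain-text fixtures; byte-identical on rerun.

    Contents: K3 and 2-node/1-edge edge lists, the 30- and 200-node SBM
    benchmark networks, and a 10-drug toy feature table pair (ATC one-hot
    and synthetic fingerprint bits).
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []

    def edge_file(name, net):
        path = os.path.join(out_dir, name)
        with open(path, "w") as fh:
            fh.write("drug_id_1\tdrug_id_2\n")
            for i, j in net.edges:
                fh.write(f"{net.drug_ids[i]}\t{net.drug_ids[j]}\n")
        written.append(path)

    edge_file("k3.tsv", DDINetwork.from_edges(("a", "b", "c"),
                                              [(0, 1), (1, 2), (0, 2)]))
    edge_file("pair.tsv", DDINetwork.from_edges(("a", "b"), [(0, 1)]))
    edge_file("sbm30.tsv", generate_sbm_network(SMALL_SBM))
    edge_file("sbm200.tsv", generate_sbm_network(BENCHMARK_SBM))

    ids = tuple(f"T{k}" for k in range(10))
    atc = PropertyFeatureTable(ids, np.vstack([encode_atc_onehot(c)
                                               for c in _TOY_ATC_CODES]), "ATC")
    atc_path = os.path.join(out_dir, "toy_atc.tsv")
    atc.write_tsv(atc_path)
    written.append(atc_path)

    rng = np.random.default_rng(11)
    fp = PropertyFeatureTable(ids, rng.binomial(1, 0.1, size=(10, 881)), "CS")
    fp_path = os.path.join(out_dir, "toy_fingerprints.tsv")
    fp.write_tsv(fp_path)
    written.append(fp_path)

    return written
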