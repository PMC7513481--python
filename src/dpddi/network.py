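"""DDI network data model: adjacency construction, normalization, pair
enumeration, negative sampling and cross-validation splitting.

A drug-drug interaction (DDI) network is an undirected graph G(D, E) over m
drugs, stored as a symmetric binary adjacency matrix A with zero diagonal.
Pairs are unordered and canonicalized to (i, j) with i < j throughout; drug
indices are assigned by sorting identifiers lexicographically, so the
adjacency is deterministic regardless of input row order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DDINetwork",
    "NormalizedAdjacency",
    "SplitPlan",
    "FoldSplit",
    "load_edge_list",
    "read_adjacency",
    "write_adjacency",
    "normalize_adjacency",
    "unlabeled_pair_count",
    "pair_sparsity",
    "count_unlabeled_pairs",
    "network_sparsity",
    "enumerate_unlabeled_pairs",
    "sample_negatives",
    "make_cv_splits",
    "subnetwork_with_edges",
]


@dataclass(frozen=True)
class DDINetwork:
    """An undirected DDI network: drug identifiers plus a symmetric binary
    adjacency matrix.

    Attributes
    ----------
    drug_ids : tuple of str
        Ordered unique identifiers; row/column i of ``adjacency`` is drug
        ``drug_ids[i]``.
    adjacency : ndarray of shape (m, m)
        Symmetric 0/1 matrix with zero diagonal.
    """

    drug_ids: tuple
    adjacency: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {A.shape}")
        if len(self.drug_ids) != A.shape[0]:
            raise ValueError(
                f"{len(self.drug_ids)} drug ids but adjacency is {A.shape[0]}x{A.shape[1]}"
            )
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValueError("drug ids must be unique")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if (A != A.T).any():
            raise ValueError("adjacency must be symmetric")
        if np.diagonal(A).any():
            raise ValueError("adjacency diagonal must be zero (self-interactions undefined)")
        object.__setattr__(self, "adjacency", A.astype(np.int8))
        object.__setattr__(self, "drug_ids", tuple(self.drug_ids))

    # -- basic properties -------------------------------------------------
    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def edges(self) -> list:
        """Unordered edges as index pairs (i, j) with i < j."""
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(iu.tolist(), ju.tolist()))

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def index_of(self, drug_id: str) -> int:
        try:
            return self.drug_ids.index(drug_id)
        except ValueError:
            raise KeyError(f"unknown drug id {drug_id!r}") from None

    @classmethod
    def from_edges(cls, drug_ids, edges) -> "DDINetwork":
        """Build from index pairs; symmetrizes and ignores duplicate edges."""
        m = len(drug_ids)
        A = np.zeros((m, m), dtype=np.int8)
        for i, j in edges:
            if i == j:
                raise ValueError(f"self-pair at index {i} ({drug_ids[i]!r})")
            A[i, j] = A[j, i] = 1
        return cls(tuple(drug_ids), A)


@dataclass(frozen=True)
class NormalizedAdjacency:
    """Symmetrically normalized adjacency A_hat = D~^(-1/2) (A + I) D~^(-1/2),
    where D~ is the degree matrix of A + I. The added self-loops guarantee
    every diagonal degree is >= 1, so isolated nodes are well defined."""

    matrix: np.ndarray
    source: DDINetwork = field(repr=False, compare=False)


def normalize_adjacency(net: DDINetwork) -> NormalizedAdjacency:
    """Symmetric degree normalization with self-loops.

    For a k-regular graph every row of the result sums to exactly 1; an
    isolated node normalizes to a unit self-loop.
    """
    A_tilde = net.adjacency.astype(float) + np.eye(net.n_drugs)
    d = A_tilde.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(d)
    A_hat = A_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    return NormalizedAdjacency(A_hat, net)


# -- pair counting ---------------------------------------------------------

def unlabeled_pair_count(n_drugs: int, n_edges: int) -> int:
    """Number of unordered drug pairs with no annotated interaction:
    m(m-1)/2 - |E| (self-pairs excluded)."""
    total = n_drugs * (n_drugs - 1) // 2
    if n_edges > total:
        raise ValueError(f"{n_edges} edges exceed {total} possible pairs")
    return total - n_edges

def pair_sparsity(n_drugs: int, n_edges: int) -> float:
    """Fraction of all unordered pairs that are annotated interactions."""
    if n_drugs < 2:
        raise ValueError("sparsity undefined for fewer than 2 drugs")
    return n_edges / (n_drugs * (n_drugs - 1) / 2)

def count_unlabeled_pairs(net: DDINetwork) -> int:
    return unlabeled_pair_count(net.n_drugs, net.n_edges)

def network_sparsity(net: DDINetwork) -> float:
    return pair_sparsity(net.n_drugs, net.n_edges)


def enumerate_unlabeled_pairs(net: DDINetwork) -> list:
    """All unordered non-edge pairs (i, j), i < j, in index order."""
    iu, ju = np.triu_indices(net.n_drugs, k=1)
    mask = net.adjacency[iu, ju] == 0
    return list(zip(iu[mask].tolist(), ju[mask].tolist()))


# -- I/O --------------------------------------------------------------------

_HEADER_TOKENS = {"drug", "drug1", "drug2", "drug_id_1", "drug_id_2", "drug_a",
                  "drug_b", "id1", "id2", "source", "target", "from", "to"}


def load_edge_list(path) -> DDINetwork:
    """Read an undirected edge list from a two-column TSV/CSV file.

    Duplicate rows and reversed duplicates collapse to a single edge.
    A header row is detected by common column-name tokens. Drug identifiers
    are sorted lexicographically to fix the index order.
    """
    pairs = set()
    with open(path) as fh:
        lines = fh.read().splitlines()
    start = 0
    if lines:
        first = [t.strip().lower() for t in _split_row(lines[0])]
        if any(t in _HEADER_TOKENS for t in first):
            start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        tokens = [t.strip() for t in _split_row(line)]
        if len(tokens) < 2 or not tokens[0] or not tokens[1]:
            raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}")
        a, b = tokens[0], tokens[1]
        if a == b:
            raise ValueError(f"{path}: self-pair for drug {a!r} at line {lineno}")
        pairs.add((a, b) if a < b else (b, a))
    if not pairs:
        raise ValueError(f"{path}: no edges")
    ids = sorted({d for p in pairs for d in p})
    index = {d: i for i, d in enumerate(ids)}
    return DDINetwork.from_edges(ids, [(index[a], index[b]) for a, b in pairs])


def _split_row(line: str) -> list:
    return line.split("\t") if "\t" in line else line.split(",")


def write_adjacency(net: DDINetwork, path) -> None:
    """Dense adjacency as TSV with drug ids as header row and index column."""
    pd.DataFrame(net.adjacency, index=list(net.drug_ids),
                 columns=list(net.drug_ids)).to_csv(path, sep="\t")


def read_adjacency(path) -> DDINetwork:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: adjacency header row and index column disagree")
    return DDINetwork(tuple(str(c) for c in df.columns), df.to_numpy())


# -- negative sampling -------------------------------------------------------

def sample_negatives(net: DDINetwork, ratio, seed: int) -> list:
    """Sample unlabeled (non-interacting) unordered pairs as negatives.

    Parameters
    ----------
    ratio : int or "all"
        Negatives per positive. ``"all"`` returns every unlabeled pair in
        deterministic index order.
    seed : int
        Same seed gives the same sample.
    """
    unlabeled = enumerate_unlabeled_pairs(net)
    if ratio == "all":
        return unlabeled
    n_needed = int(ratio) * net.n_edges
    if n_needed > len(unlabeled):
        raise ValueError(
            f"requested {n_needed} negatives but only {len(unlabeled)} "
            f"unlabeled pairs exist"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(unlabeled), size=n_needed, replace=False)
    return [unlabeled[k] for k in idx]


# -- cross-validation splitting ----------------------------------------------

@dataclass(frozen=True)
class FoldSplit:
    """Pair sets for one CV iteration (all lists of (i, j) tuples)."""

    train_pos: list
    train_neg: list
    val_pos: list
    val_neg: list
    test_pos: list
    test_neg: list

    def all_sets(self):
        return (self.train_pos, self.train_neg, self.val_pos,
                self.val_neg, self.test_pos, self.test_neg)


@dataclass(frozen=True)
class SplitPlan:
    """A 5-fold CV plan over positive and sampled negative pairs.

    Positives are partitioned into 5 folds of near-equal size; negatives are
    partitioned into 5 folds from the same RNG stream. In each iteration one
    fold is the test set and the held-in pairs are split 90%/10% into
    training and validation (positives and negatives separately, so class
    ratios are preserved).
    """

    positive_folds: list
    negative_folds: list
    iterations: list
    ratio: object
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.positive_folds)

    def to_json(self, drug_ids) -> str:
        def key(p):
            return f"{drug_ids[p[0]]}|{drug_ids[p[1]]}"

        doc = {
            "ratio": self.ratio,
            "seed": self.seed,
            "positive_folds": {key(p): f for f, fold in enumerate(self.positive_folds)
                               for p in fold},
            "negative_folds": {key(p): f for f, fold in enumerate(self.negative_folds)
                               for p in fold},
        }
        return json.dumps(doc, indent=1)


def make_cv_splits(net: DDINetwork, negatives, seed: int, n_folds: int = 5,
                   val_fraction: float = 0.1) -> SplitPlan:
    """Build the 5-fold CV plan used by the evaluation protocol."""
    positives = net.edges
    if len(positives) < n_folds:
        raise ValueError(f"need at least {n_folds} positive pairs, have {len(positives)}")
    pos_set = set(positives)
    for p in negatives:
        if p in pos_set:
            raise ValueError(f"negative pair {p} is annotated as positive")

    # separate deterministic substreams: the positive-side plan depends only
    # on (net, seed), so encoder training folds are identical across
    # negative-sampling ratios and embeddings can be shared in ablations
    pos_rng = np.random.default_rng([seed, 0])
    neg_rng = np.random.default_rng([seed, 1])
    pos_folds = _partition(positives, n_folds, pos_rng)
    neg_folds = _partition(list(negatives), n_folds, neg_rng)

    iterations = []
    for t in range(n_folds):
        heldin_pos = [p for f in range(n_folds) if f != t for p in pos_folds[f]]
        heldin_neg = [p for f in range(n_folds) if f != t for p in neg_folds[f]]
        train_pos, val_pos = _train_val(heldin_pos, val_fraction, pos_rng)
        train_neg, val_neg = _train_val(heldin_neg, val_fraction, neg_rng)
        iterations.append(FoldSplit(train_pos, train_neg, val_pos, val_neg,
                                    list(pos_folds[t]), list(neg_folds[t])))
    return SplitPlan(pos_folds, neg_folds, iterations, _ratio_of(positives, negatives), seed)


def _partition(items, n_folds, rng):
    order = rng.permutation(len(items))
    return [[items[k] for k in chunk] for chunk in np.array_split(order, n_folds)]


def _train_val(items, val_fraction, rng):
    order = rng.permutation(len(items))
    n_train = int(round((1.0 - val_fraction) * len(items)))
    return [items[k] for k in order[:n_train]], [items[k] for k in order[n_train:]]


def _ratio_of(positives, negatives):
    if positives and len(negatives) % len(positives) == 0:
        return len(negatives) // len(positives)
    return len(negatives) / max(len(positives), 1)


def subnetwork_with_edges(net: DDINetwork, edges) -> DDINetwork:
    """Same drugs, adjacency containing only the given edges.

    Used to build the leak-free training adjacency for the encoder: edges of
    validation and test pairs are simply absent.
    """
    return DDINetwork.from_edges(net.drug_ids, list(edges))
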