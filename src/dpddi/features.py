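"""Pair feature aggregation and per-drug property encodings.

Two per-drug vectors Z_i, Z_j are merged into one pair feature vector
F(d_i, d_j) by one of three operators: inner product (length 1), summation
(length k) or concatenation (length 2k). Concatenation is the operator of
choice for the full pipeline; the others exist for the ablation harness.

The module also hosts the alternative per-drug property encodings used when
comparing network-derived embeddings against drug properties: 881-bit
chemical-substructure fingerprints (CS), 1121-bit drug-binding-protein
indicator vectors (DBP) and a 118-bit one-hot encoding of the 7-character
ATC classification code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AGGREGATORS",
    "PROPERTY_WIDTHS",
    "PairDataset",
    "PropertyFeatureTable",
    "aggregate",
    "aggregate_batch",
    "encode_atc_onehot",
    "encode_atc_codes",
    "build_pair_dataset",
    "read_feature_table",
]

AGGREGATORS = ("inner_product", "summation", "concatenation")

# expected column counts per property kind; NS (network structure) is the
# learned embedding and has no fixed width
PROPERTY_WIDTHS = {"CS": 881, "DBP": 1121, "ATC": 118}

# ATC code structure: letter, digit, digit, letter, letter, digit, digit
# one-hot blocks of 26+10+10+26+26+10+10 = 118 bits
_ATC_BLOCKS = ("L", "D", "D", "L", "L", "D", "D")
_BLOCK_SIZES = {"L": 26, "D": 10}
_ATC_OFFSETS = np.concatenate(([0], np.cumsum([_BLOCK_SIZES[b] for b in _ATC_BLOCKS])))
ATC_ONEHOT_BITS = int(_ATC_OFFSETS[-1])


def aggregate(op_name: str, Zi, Zj) -> np.ndarray:
    """Merge two same-length drug vectors into one pair feature vector."""
    Zi = np.asarray(Zi, dtype=float)
    Zj = np.asarray(Zj, dtype=float)
    if Zi.shape != Zj.shape:
        raise ValueError(f"vector length mismatch: {Zi.shape} vs {Zj.shape}")
    if op_name == "inner_product":
        return np.array([float(Zi @ Zj)])
    if op_name == "summation":
        return Zi + Zj
    if op_name == "concatenation":
        return np.concatenate([Zi, Zj])
    raise ValueError(f"unknown aggregation operator {op_name!r}; choose from {AGGREGATORS}")


def aggregate_batch(op_name: str, Zi: np.ndarray, Zj: np.ndarray) -> np.ndarray:
    """Vectorized :func:`aggregate` over rows of two (n, k) matrices."""
    if Zi.shape != Zj.shape:
        raise ValueError(f"matrix shape mismatch: {Zi.shape} vs {Zj.shape}")
    if op_name == "inner_product":
        return np.einsum("ij,ij->i", Zi, Zj)[:, None]
    if op_name == "summation":
        return Zi + Zj
    if op_name == "concatenation":
        return np.hstack([Zi, Zj])
    raise ValueError(f"unknown aggregation operator {op_name!r}; choose from {AGGREGATORS}")


def pair_feature_dim(op_name: str, k: int) -> int:
    return {"inner_product": 1, "summation": k, "concatenation": 2 * k}[op_name]


def encode_atc_onehot(code: str) -> np.ndarray:
    """One-hot encode a 7-character ATC code into 118 bits (exactly 7 ones).

    Each character is one-hot within its own alphabet block: position 1 an
    uppercase letter (26 bits), positions 2-3 digits (10 bits each),
    positions 4-5 letters, positions 6-7 digits.
    """
    code = str(code)
    if len(code) != 7:
        raise ValueError(f"ATC code must have 7 characters, got {code!r}")
    vec = np.zeros(ATC_ONEHOT_BITS, dtype=np.int8)
    for pos, (ch, block) in enumerate(zip(code.upper(), _ATC_BLOCKS), start=1):
        if block == "L":
            if not ch.isalpha() or not ch.isascii():
                raise ValueError(f"ATC code {code!r}: expected a letter at position {pos}")
            idx = ord(ch) - ord("A")
        else:
            if not ch.isdigit():
                raise ValueError(f"ATC code {code!r}: expected a digit at position {pos}")
            idx = ord(ch) - ord("0")
        vec[_ATC_OFFSETS[pos - 1] + idx] = 1
    return vec


def encode_atc_codes(codes, multi: str = "union") -> np.ndarray:
    """Encode one or several ATC codes for a single drug.

    Drugs frequently carry multiple ATC codes; ``multi="union"`` takes the
    bitwise OR of the individual one-hot vectors, ``multi="first"`` keeps
    only the first code.
    """
    if isinstance(codes, str):
        codes = [codes]
    if not codes:
        raise ValueError("need at least one ATC code")
    if multi == "first":
        return encode_atc_onehot(codes[0])
    if multi != "union":
        raise ValueError(f"unknown multi-code policy {multi!r}")
    out = np.zeros(ATC_ONEHOT_BITS, dtype=np.int8)
    for c in codes:
        out |= encode_atc_onehot(c)
    return out


@dataclass(frozen=True)
class PropertyFeatureTable:
    """Binary per-drug property matrix with a kind tag (CS/DBP/ATC/NS)."""

    drug_ids: tuple
    matrix: np.ndarray
    kind: str

    def __post_init__(self):
        M = np.asarray(self.matrix)
        if M.shape[0] != len(self.drug_ids):
            raise ValueError("one row per drug required")
        if self.kind in PROPERTY_WIDTHS:
            want = PROPERTY_WIDTHS[self.kind]
            if M.shape[1] != want:
                raise ValueError(f"{self.kind} features must have {want} columns, got {M.shape[1]}")
            if not np.isin(M, (0, 1)).all():
                raise ValueError(f"{self.kind} features must be binary")
        elif self.kind != "NS":
            raise ValueError(f"unknown feature kind {self.kind!r}")
        object.__setattr__(self, "drug_ids", tuple(self.drug_ids))

    def row(self, drug_id: str) -> np.ndarray:
        try:
            return self.matrix[self.drug_ids.index(drug_id)]
        except ValueError:
            raise KeyError(f"unknown drug id {drug_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        cols = [f"bit{k}" for k in range(self.matrix.shape[1])]
        return pd.DataFrame(self.matrix, index=list(self.drug_ids), columns=cols)

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "drug_id"
        df.to_csv(path, sep="\t")


def read_feature_table(path, kind: str) -> PropertyFeatureTable:
    """Read a per-drug feature TSV (first column drug_id, remaining columns bits)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PropertyFeatureTable(tuple(str(i) for i in df.index), df.to_numpy(), kind)


@dataclass(frozen=True)
class PairDataset:
    """Labeled drug pairs with aggregated feature vectors.

    ``labels`` may contain -1 for unknown (unscored) pairs.
    """

    pairs: list
    X: np.ndarray
    y: np.ndarray
    op_name: str

    def __post_init__(self):
        if len(self.pairs) != self.X.shape[0] or len(self.pairs) != len(self.y):
            raise ValueError("pairs, X and y must align")
        if not np.isfinite(self.X).all():
            raise ValueError("pair features must be finite")

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self, drug_ids) -> pd.DataFrame:
        keys = [f"{drug_ids[i]}|{drug_ids[j]}" for i, j in self.pairs]
        df = pd.DataFrame(self.X, columns=[f"f{k}" for k in range(self.X.shape[1])])
        df.insert(0, "pair", keys)
        df.insert(1, "label", self.y)
        return df


def build_pair_dataset(features: np.ndarray, pairs, labels, op_name: str) -> PairDataset:
    """Aggregate per-drug feature rows into one record per labeled pair.

    ``features`` is the (m, k) per-drug matrix (embeddings or property
    vectors); ``pairs`` are index pairs into its rows; order is preserved.
    """
    features = np.asarray(features, dtype=float)
    m = features.shape[0]
    pairs = [tuple(p) for p in pairs]
    for i, j in pairs:
        if not (0 <= i < m and 0 <= j < m):
            raise KeyError(f"pair ({i}, {j}) indexes outside the {m}-drug feature table")
    if pairs:
        ii = np.fromiter((p[0] for p in pairs), dtype=int, count=len(pairs))
        jj = np.fromiter((p[1] for p in pairs), dtype=int, count=len(pairs))
        X = aggregate_batch(op_name, features[ii], features[jj])
    else:
        X = np.empty((0, pair_feature_dim(op_name, features.shape[1])))
    y = np.asarray(list(labels), dtype=int)
    return PairDataset(pairs, X, y, op_name)
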