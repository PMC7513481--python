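"""Cross-validated evaluation of the full pipeline and case-study ranking.

The protocol: positives (and matched sampled negatives) are partitioned into
5 folds; each fold in turn is the test set, the held-in pairs are split
90/10 into training and validation, the encoder is trained on an adjacency
containing only training-fold positive edges (leak-free by default), the
predictor is trained on aggregated training pairs, and the test pairs are
scored. Ten independent repetitions of 5CV guard against split bias; the
grand mean is the unweighted mean over all fold-level values.

``cross_validate_grid`` evaluates several aggregation operators and
negative-sampling ratios in one pass, sharing the per-fold encoder (whose
training adjacency depends only on the positive folds) across cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoder import EncoderConfig, train_encoder
from .features import build_pair_dataset
from .metrics import METRIC_NAMES, classification_metrics, f1_score_from_pr, pr_auc, roc_auc
from .network import (
    DDINetwork,
    count_unlabeled_pairs,
    enumerate_unlabeled_pairs,
    make_cv_splits,
    sample_negatives,
    subnetwork_with_edges,
)
from .predictor import PredictorConfig, predict_pair_scores, train_predictor

__all__ = ["CVReport", "RankedPredictions", "run_cross_validation",
           "cross_validate_grid", "rank_novel_pairs"]

_ROW_COLUMNS = ["run", "fold", "operator", "ratio", *METRIC_NAMES,
                "tp", "tn", "fp", "fn"]


@dataclass(frozen=True)
class CVReport:
    """Per-fold metrics of repeated 5-fold cross-validation.

    ``frame`` has one row per (run, fold) with AUC, AUPR, accuracy,
    precision, recall, F1 and the confusion counts. ``grand_mean`` is the
    unweighted mean of each metric over all fold-level values.
    """

    frame: pd.DataFrame
    operator: str
    ratio: object
    seed: int
    audit: dict = field(default_factory=dict)

    def __post_init__(self):
        for _, row in self.frame.iterrows():
            expected = f1_score_from_pr(row["precision"], row["recall"])
            if abs(row["f1"] - expected) > 1e-12:
                raise ValueError("F1 is not the harmonic mean of precision and recall")

    @property
    def grand_mean(self) -> pd.Series:
        return self.frame[list(METRIC_NAMES)].mean()

    @property
    def f1_of_mean_pr(self) -> float:
        """F1 recomputed from the grand-mean precision and recall (the other
        averaging convention sometimes seen in printed tables)."""
        gm = self.grand_mean
        return f1_score_from_pr(gm["precision"], gm["recall"])

    def summary(self) -> str:
        gm = self.grand_mean
        lines = [
            "Cross-validated DDI link prediction",
            f"  operator={self.operator}  negatives:positives={self.ratio}:1  "
            f"runs={self.frame['run'].nunique()}  folds/run={self.frame['fold'].nunique()}",
            "  metric      mean     sd",
        ]
        sd = self.frame[list(METRIC_NAMES)].std(ddof=0)
        for name in METRIC_NAMES:
            lines.append(f"  {name:<10} {gm[name]:6.3f}  {sd[name]:6.3f}")
        lines.append(f"  F1 of mean P/R: {self.f1_of_mean_pr:.3f}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps({
            "operator": self.operator,
            "ratio": self.ratio,
            "seed": self.seed,
            "grand_mean": {k: float(v) for k, v in self.grand_mean.items()},
            "f1_of_mean_pr": self.f1_of_mean_pr,
            "folds": self.frame.to_dict(orient="records"),
            "audit": self.audit,
        }, indent=1)

    def to_csv(self, path) -> None:
        long = self.frame.melt(id_vars=["run", "fold", "operator", "ratio"],
                               value_vars=list(METRIC_NAMES),
                               var_name="metric", value_name="value")
        long.to_csv(path, index=False)


@dataclass(frozen=True)
class RankedPredictions:
    """Unlabeled pairs ordered by predicted interaction probability."""

    pairs: list
    scores: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("ranked scores must be non-increasing")

    def to_frame(self, drug_ids) -> pd.DataFrame:
        return pd.DataFrame({
            "drug_id_1": [drug_ids[i] for i, _ in self.pairs],
            "drug_id_2": [drug_ids[j] for _, j in self.pairs],
            "score": self.scores,
            "rank": np.arange(1, len(self.pairs) + 1),
        })


def _derive_seed(*parts) -> int:
    return int(np.random.default_rng(list(parts)).integers(2**31))


def cross_validate_grid(net: DDINetwork, encoder_config: EncoderConfig,
                        predictor_config: PredictorConfig, operators,
                        ratios, n_runs: int = 10, seed: int = 0,
                        n_folds: int = 5, leaky_encoder: bool = False,
                        symmetrize: bool = True) -> dict:
    """Run repeated 5CV for every (operator, ratio) cell.

    Ratios must be positive integers here; the per-fold encoder is trained
    once and its embeddings are reused by every cell. Returns a dict mapping
    (operator, ratio) to a :class:`CVReport`.
    """
    ratios = [int(r) for r in ratios]
    if min(ratios) < 1:
        raise ValueError("ratios must be >= 1")
    max_ratio = max(ratios)
    if max_ratio * net.n_edges > count_unlabeled_pairs(net):
        raise ValueError(
            f"ratio {max_ratio} needs {max_ratio * net.n_edges} negatives but only "
            f"{count_unlabeled_pairs(net)} unlabeled pairs exist")

    rows = {cell: [] for cell in ((op, r) for op in operators for r in ratios)}
    leak_checks = violations = 0

    for run in range(n_runs):
        run_seed = _derive_seed(seed, run)
        # one superset sample; a ratio-r cell uses the first r*P negatives,
        # which is itself a uniform sample without replacement
        negatives = sample_negatives(net, max_ratio, run_seed)
        plans = {r: make_cv_splits(net, negatives[:r * net.n_edges], run_seed,
                                   n_folds=n_folds) for r in ratios}
        ref_plan = plans[ratios[0]]
        for fold in range(n_folds):
            ref_it = ref_plan.iterations[fold]
            if leaky_encoder:
                enc_net = net
            else:
                enc_net = subnetwork_with_edges(net, ref_it.train_pos)
                for p in ref_it.test_pos + ref_it.val_pos:
                    leak_checks += 1
                    if enc_net.adjacency[p[0], p[1]]:
                        violations += 1
                if violations:
                    raise AssertionError(
                        "held-out positive edge leaked into encoder adjacency")
            enc_cfg = encoder_config.replace(seed=_derive_seed(seed, run, fold, 1))
            _, Z, _ = train_encoder(enc_net, enc_cfg)

            for op in operators:
                for r in ratios:
                    it = plans[r].iterations[fold]
                    assert it.train_pos == ref_it.train_pos  # shared-encoder premise
                    train_pairs = it.train_pos + it.train_neg
                    labels = [1] * len(it.train_pos) + [0] * len(it.train_neg)
                    ds = build_pair_dataset(Z.Z, train_pairs, labels, op)
                    pred_cfg = predictor_config.for_input_dim(ds.X.shape[1]).replace(
                        seed=_derive_seed(seed, run, fold, 2))
                    state, _ = train_predictor(ds, pred_cfg)
                    test_pairs = it.test_pos + it.test_neg
                    y_test = np.array([1] * len(it.test_pos) + [0] * len(it.test_neg))
                    s = predict_pair_scores(state, Z, test_pairs, op,
                                            symmetrize=symmetrize)
                    counts, thr = classification_metrics(s, y_test)
                    rows[(op, r)].append({
                        "run": run, "fold": fold, "operator": op, "ratio": r,
                        "auc": roc_auc(s, y_test), "aupr": pr_auc(s, y_test),
                        **thr, "tp": counts.tp, "tn": counts.tn,
                        "fp": counts.fp, "fn": counts.fn,
                    })

    audit = {"leak_checks": leak_checks, "leak_violations": violations,
             "leaky_encoder": leaky_encoder}
    return {cell: CVReport(pd.DataFrame(cell_rows, columns=_ROW_COLUMNS),
                           operator=cell[0], ratio=cell[1], seed=seed, audit=audit)
            for cell, cell_rows in rows.items()}


def run_cross_validation(net: DDINetwork, encoder_config: EncoderConfig,
                         predictor_config: PredictorConfig, ratio=1,
                         operator: str = "concatenation", n_runs: int = 10,
                         seed: int = 0, n_folds: int = 5,
                         leaky_encoder: bool = False,
                         symmetrize: bool = True) -> CVReport:
    """Repeated 5-fold cross-validation for one operator and one ratio."""
    if ratio == "all":
        return _run_cv_all_negatives(net, encoder_config, predictor_config,
                                     operator, n_runs, seed, n_folds,
                                     leaky_encoder, symmetrize)
    grid = cross_validate_grid(net, encoder_config, predictor_config,
                               [operator], [int(ratio)], n_runs=n_runs,
                               seed=seed, n_folds=n_folds,
                               leaky_encoder=leaky_encoder,
                               symmetrize=symmetrize)
    return grid[(operator, int(ratio))]


def _run_cv_all_negatives(net, encoder_config, predictor_config, operator,
                          n_runs, seed, n_folds, leaky_encoder, symmetrize):
    """CV with every unlabeled pair as a negative (no sampling)."""
    rows = []
    leak_checks = violations = 0
    negatives = enumerate_unlabeled_pairs(net)
    for run in range(n_runs):
        run_seed = _derive_seed(seed, run)
        plan = make_cv_splits(net, negatives, run_seed, n_folds=n_folds)
        for fold in range(n_folds):
            it = plan.iterations[fold]
            enc_net = net if leaky_encoder else subnetwork_with_edges(net, it.train_pos)
            if not leaky_encoder:
                for p in it.test_pos + it.val_pos:
                    leak_checks += 1
                    violations += int(enc_net.adjacency[p[0], p[1]])
                if violations:
                    raise AssertionError(
                        "held-out positive edge leaked into encoder adjacency")
            enc_cfg = encoder_config.replace(seed=_derive_seed(seed, run, fold, 1))
            _, Z, _ = train_encoder(enc_net, enc_cfg)
            train_pairs = it.train_pos + it.train_neg
            labels = [1] * len(it.train_pos) + [0] * len(it.train_neg)
            ds = build_pair_dataset(Z.Z, train_pairs, labels, operator)
            pred_cfg = predictor_config.for_input_dim(ds.X.shape[1]).replace(
                seed=_derive_seed(seed, run, fold, 2))
            state, _ = train_predictor(ds, pred_cfg)
            test_pairs = it.test_pos + it.test_neg
            y_test = np.array([1] * len(it.test_pos) + [0] * len(it.test_neg))
            s = predict_pair_scores(state, Z, test_pairs, operator, symmetrize=symmetrize)
            counts, thr = classification_metrics(s, y_test)
            rows.append({"run": run, "fold": fold, "operator": operator,
                         "ratio": "all", "auc": roc_auc(s, y_test),
                         "aupr": pr_auc(s, y_test), **thr,
                         "tp": counts.tp, "tn": counts.tn,
                         "fp": counts.fp, "fn": counts.fn})
    audit = {"leak_checks": leak_checks, "leak_violations": violations,
             "leaky_encoder": leaky_encoder}
    return CVReport(pd.DataFrame(rows, columns=_ROW_COLUMNS), operator=operator,
                    ratio="all", seed=seed, audit=audit)


def rank_novel_pairs(state, Z, net: DDINetwork, top_k: int,
                     op_name: str = "concatenation",
                     symmetrize: bool = True) -> RankedPredictions:
    """Score every unlabeled pair and return the top_k, highest first.

    Annotated pairs are excluded by construction; ties break on pair index
    order for determinism.
    """
    unlabeled = enumerate_unlabeled_pairs(net)
    if top_k > len(unlabeled):
        raise ValueError(f"top_k={top_k} exceeds {len(unlabeled)} unlabeled pairs")
    scores = predict_pair_scores(state, Z, unlabeled, op_name, symmetrize=symmetrize)
    order = np.argsort(-scores, kind="stable")[:top_k]
    return RankedPredictions([unlabeled[k] for k in order], scores[order])
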