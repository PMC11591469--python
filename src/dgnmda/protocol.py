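"""Sampling, splitting and evaluation protocol.

Known associations are the positives; an equal number of unobserved
pairs is drawn uniformly without replacement as negatives (balanced
undersampling).  The balanced pair list is split 8:2 into training and
test material, stratified by label, and the training portion is
partitioned into 5 stratified cross-validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_recall_curve,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.metrics import auc as _auc

from .data import AssociationMatrix

__all__ = [
    "FoldSplit",
    "negative_undersample",
    "split_and_folds",
    "bce_loss",
    "pair_embedding",
    "evaluate",
    "make_score_table",
]

Pair = tuple[int, int, int]  # (miRNA index, disease index, label)


@dataclass
class FoldSplit:
    """Disjoint, label-balanced train/validation/test pair sets for one fold."""

    train_pairs: list[Pair]
    val_pairs: list[Pair]
    test_pairs: list[Pair]
    fold_id: int
    seed: int

    def __post_init__(self):
        sets = [set((i, j) for i, j, _ in s) for s in (self.train_pairs, self.val_pairs, self.test_pairs)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("fold pair sets must be disjoint")


def negative_undersample(assoc: AssociationMatrix, seed: int) -> list[Pair]:
    """All positive pairs plus an equal-size uniform sample of zero cells."""
    pos = [(int(i), int(j), 1) for i, j in np.argwhere(assoc.values == 1)]
    zeros = np.argwhere(assoc.values == 0)
    if len(zeros) < len(pos):
        raise ValueError("not enough unobserved pairs to balance the positives")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(zeros), size=len(pos), replace=False)
    neg = [(int(zeros[k, 0]), int(zeros[k, 1]), 0) for k in sorted(pick)]
    return pos + neg


def split_and_folds(
    pairs: list[Pair], test_fraction: float = 0.2, folds: int = 5, seed: int = 0
) -> list[FoldSplit]:
    """Stratified 8:2 train/test split, then stratified k folds on the 80%.

    Per-fold class balance holds within +-1 item: each class is dealt
    round-robin across folds with a cursor that carries over between
    classes.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    by_label: dict[int, list[Pair]] = {0: [], 1: []}
    for p in pairs:
        by_label[p[2]].append(p)
    test: list[Pair] = []
    fold_bins: list[list[Pair]] = [[] for _ in range(folds)]
    cursor = 0
    for label in (1, 0):
        group = by_label[label]
        if len(group) < folds:
            raise ValueError(f"class {label} has fewer pairs than folds")
        order = rng.permutation(len(group))
        n_test = int(round(test_fraction * len(group)))
        test.extend(group[k] for k in order[:n_test])
        for k in order[n_test:]:
            fold_bins[cursor % folds].append(group[k])
            cursor += 1
    out = []
    for f in range(folds):
        train = [p for g, b in enumerate(fold_bins) if g != f for p in b]
        out.append(FoldSplit(train, list(fold_bins[f]), list(test), fold_id=f, seed=seed))
    return out


def bce_loss(scores: np.ndarray, labels: np.ndarray, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy with probabilities clamped to [eps, 1-eps]."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if scores.size == 0 or scores.shape != labels.shape:
        raise ValueError("scores and labels must be nonempty and congruent")
    p = np.clip(scores, eps, 1 - eps)
    return float(-np.mean(labels * np.log(p) + (1 - labels) * np.log(1 - p)))


def pair_embedding(h: np.ndarray, i: int, j: int, n_mirna: int) -> np.ndarray:
    """Concatenate the miRNA-i and disease-j rows of the node embedding."""
    n = h.shape[0]
    if not (0 <= i < n_mirna) or not (0 <= n_mirna + j < n):
        raise IndexError("pair indices out of range")
    return np.concatenate([h[i], h[n_mirna + j]])


def evaluate(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> dict[str, float]:
    """AUC, AUPRC and thresholded accuracy/F1/recall/precision."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.intp)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    pred = (scores >= threshold).astype(int)
    prec, rec, _ = precision_recall_curve(labels, scores)
    return {
        "ACC": float(accuracy_score(labels, pred)),
        "F1": float(f1_score(labels, pred, zero_division=0)),
        "Recall": float(recall_score(labels, pred, zero_division=0)),
        "Precision": float(precision_score(labels, pred, zero_division=0)),
        "AUC": float(roc_auc_score(labels, scores)),
        "AUPRC": float(_auc(rec, prec)),
    }


def make_score_table(
    rows: list[tuple[str, str, int, float, int, str]],
) -> pd.DataFrame:
    """Assemble a score table (one row per scored pair) with within-group ranks."""
    df = pd.DataFrame(rows, columns=["mirna_id", "disease_id", "label", "score", "fold", "split"])
    df["rank"] = (
        df.groupby(["fold", "split"])["score"].rank(ascending=False, method="first").astype(int)
    )
    return df
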