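"""M component: cumulative top-k models and the performance table.

The k-th cumulative model uses the union of the gene sets of the k
best-scoring groups as features, is fitted fresh on the training samples,
and is evaluated on the held-out test samples with accuracy, sensitivity,
specificity and AUC.  One row per k forms the split's performance table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_config import LabelTable, OmicsMatrix, RunConfig, TrimintError, derive_seed
from .scoring import ClassifierSpec, ScoredGroup, make_classifier


@dataclass
class PerformanceRow:
    """Held-out metrics of the cumulative model at one k."""

    cumulative_rank: int
    unique_gene_count: int
    accuracy: float
    specificity: float
    sensitivity: float
    auc: float  # NaN when the test truth is single-class

    def __post_init__(self) -> None:
        for m in (self.accuracy, self.specificity, self.sensitivity):
            assert np.isnan(m) or 0.0 <= m <= 1.0
        assert np.isnan(self.auc) or 0.0 <= self.auc <= 1.0


def cumulative_union(scored: list[ScoredGroup], k: int) -> list[str]:
    """Union of gene IDs of groups ranked 1..k, first-appearance order."""
    if not (1 <= k <= len(scored)):
        raise TrimintError(f"k={k} out of range 1..{len(scored)}")
    ordered = sorted(scored, key=lambda s: s.rank)
    seen: dict[str, None] = {}
    for sg in ordered[:k]:
        for g in sg.group.gene_ids:
            seen.setdefault(g, None)
    return list(seen)


def rank_auc(y_true: np.ndarray, positive_scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic; ties count 1/2.

    Returns NaN when only one class is present in ``y_true``.
    """
    y_true = np.asarray(y_true)
    positive_scores = np.asarray(positive_scores, dtype=float)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(positive_scores)
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_metrics(
    true_labels: np.ndarray,
    predicted_labels: np.ndarray,
    positive_scores: np.ndarray,
    positive_label=1,
) -> tuple[float, float, float, float]:
    """Accuracy, sensitivity, specificity and AUC for a two-class prediction.

    Sensitivity is the true-positive rate with respect to ``positive_label``;
    specificity the true-negative rate.  AUC is the Mann-Whitney statistic on
    ``positive_scores`` (NaN for single-class truth; sensitivity/specificity
    are NaN when their denominator class is absent).
    """
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape or true_labels.size == 0:
        raise TrimintError("label vectors must be equal-length and non-empty")
    is_pos = true_labels == positive_label
    pred_pos = predicted_labels == positive_label
    tp = int(np.sum(is_pos & pred_pos))
    tn = int(np.sum(~is_pos & ~pred_pos))
    fp = int(np.sum(~is_pos & pred_pos))
    fn = int(np.sum(is_pos & ~pred_pos))
    n = tp + tn + fp + fn
    accuracy = (tp + tn) / n
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    auc = rank_auc(is_pos.astype(int), positive_scores)
    return accuracy, sensitivity, specificity, auc


def evaluate_cumulative(
    scored: list[ScoredGroup],
    C_train: OmicsMatrix,
    C_test: OmicsMatrix,
    labels: LabelTable,
    cfg: RunConfig,
    seed: int,
) -> list[PerformanceRow]:
    """Fit and evaluate cumulative models for k = 1..min(top_k, #groups).

    A fresh, seeded random forest is trained per k (no warm start).  The
    positive-class score used for the AUC is the forest's predicted
    probability (fraction of trees voting positive).
    """
    if not scored:
        raise TrimintError("evaluate_cumulative needs at least one scored group")
    if set(C_train.sample_ids) & set(C_test.sample_ids):
        raise TrimintError("train and test sample sets must be disjoint")
    y_train = labels.vector(C_train.sample_ids)
    y_test = labels.vector(C_test.sample_ids)
    rows: list[PerformanceRow] = []
    for k in range(1, min(cfg.top_k_groups, len(scored)) + 1):
        genes = cumulative_union(scored, k)
        X_train = C_train.data.loc[genes].to_numpy(dtype=float).T
        X_test = C_test.data.loc[genes].to_numpy(dtype=float).T
        clf = make_classifier(ClassifierSpec("random_forest", cfg.rf_trees, derive_seed(seed, k)))
        clf.fit(X_train, y_train)
        pred = clf.predict(X_test)
        pos_col = list(clf.classes_).index(1) if 1 in clf.classes_ else None
        scores = (
            clf.predict_proba(X_test)[:, pos_col]
            if pos_col is not None
            else np.zeros(len(y_test))
        )
        acc, sens, spec, auc = compute_metrics(y_test, pred, scores, positive_label=1)
        rows.append(PerformanceRow(k, len(genes), acc, spec, sens, auc))
    return rows
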