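"""Binary-classification metrics and cross-species transfer evaluation.

Threshold metrics (sensitivity, specificity, accuracy, Matthews correlation)
derive from confusion counts at a configurable decision threshold (default
0.5, tie rule: score >= threshold predicts positive). AUC uses the rank-based
Mann-Whitney formulation (ties count 1/2), which equals the trapezoidal area
under the ROC curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import Dataset

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics",
    "roc_auc",
    "cross_species_evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """Sn, Sp, Acc in [0,1]; MCC in [-1,1]; NaN marks an undefined ratio."""

    Sn: float
    Sp: float
    Acc: float
    MCC: float
    threshold: float = 0.5


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with prediction = (score >= threshold)."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError(
            f"labels and scores differ in length: {labels.shape} vs {scores.shape}"
        )
    if labels.size == 0:
        raise ValueError("confusion requires at least one record")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        TN=int(np.sum(~pred & ~pos)),
        FP=int(np.sum(pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def metrics(counts: ConfusionCounts, threshold: float = 0.5) -> MetricsReport:
    """Sensitivity, specificity, accuracy and Matthews correlation.

    Sn or Sp with an empty class is reported as NaN (never silently 0); a zero
    factor in the MCC denominator yields MCC = 0 by convention.
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    if counts.total == 0:
        raise ValueError("metrics require at least one evaluated record")
    sn = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    sp = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    acc = (tp + tn) / counts.total
    denom = (tp + fp) * (tn + fn) * (tp + fn) * (tn + fp)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsReport(Sn=sn, Sp=sp, Acc=acc, MCC=mcc, threshold=threshold)


def roc_auc(labels, scores) -> float:
    """Area under the ROC curve (Mann-Whitney: P(pos > neg), ties = 1/2)."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    rank_sum_pos = float(ranks[labels == 1].sum())
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def _holdout_split(dataset: Dataset, test_fraction: float, seed: int):
    from sklearn.model_selection import train_test_split

    idx = np.arange(len(dataset))
    y = dataset.labels()
    tr, te = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=seed
    )
    recs = dataset.records
    return (
        Dataset([recs[i] for i in sorted(tr)], name=dataset.name),
        Dataset([recs[i] for i in sorted(te)], name=dataset.name),
    )


def cross_species_evaluate(
    train_sets: list[Dataset],
    test_sets: list[Dataset],
    make_classifier=None,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Train-on-one, test-on-another AUC matrix.

    One model is fit per training dataset; every test dataset is scored with
    each model. When a test set shares its name with the training set, the
    evaluation uses that dataset's held-out split (never training records).
    Cells whose test split contains a single class are NaN, not 0. The
    returned DataFrame has training datasets as columns (x-axis) and testing
    datasets as rows (y-axis), ready for heatmap rendering.
    """
    if not train_sets or not test_sets:
        raise ValueError("need at least one training and one testing dataset")
    if make_classifier is None:
        from .estimator import KmerTransformerClassifier

        def make_classifier():
            return KmerTransformerClassifier(random_state=seed)

    matrix = pd.DataFrame(
        index=[d.name for d in test_sets],
        columns=[d.name for d in train_sets],
        dtype=float,
    )
    for train_ds in train_sets:
        fit_part, holdout = _holdout_split(train_ds, test_fraction, seed)
        clf = make_classifier()
        clf.fit(fit_part.sequences(), fit_part.labels())
        for test_ds in test_sets:
            eval_ds = holdout if test_ds.name == train_ds.name else test_ds
            y = eval_ds.labels()
            if len(np.unique(y)) < 2:
                matrix.loc[test_ds.name, train_ds.name] = float("nan")
                continue
            scores = clf.predict_proba(eval_ds.sequences())[:, 1]
            matrix.loc[test_ds.name, train_ds.name] = roc_auc(y, scores)
    return matrix
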