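"""Evaluation: confusion metrics, ROC/AUC, LOOCV, independent test.

Scalar metrics follow the usual confusion-table definitions::

    SEN = TP/(TP+FN)            SPE = TN/(TN+FP)
    ACC = (TP+TN)/total         PRE = TP/(TP+FP)
    MCC = (TP*TN - FP*FN)/sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP))
    F1  = 2*PRE*SEN/(PRE+SEN)

A metric whose denominator is zero is reported as 0 with a warning.  ROC
traces TPR against FPR over all decision thresholds; the trapezoidal AUC
equals the Mann-Whitney statistic (ties counted 1/2).

Leave-one-out cross-validation holds out each labeled pair in turn.  To
prevent the held-out association from leaking into its own features, its
lncRNA-protein edge is removed from the network before that pair's
features are computed; the classifier is retrained on the remaining
pairs each round.  The independent test fits once on training pairs and
scores a disjoint test set whose positive edges are likewise removed
from the feature network first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import sqrt
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .exceptions import EvaluationError, ProtocolError
from .metapath import MetaPath
from .model import (
    ClassifierConfig,
    LabeledPairSet,
    build_feature_table,
    train_classifier,
)
from .netio import HeteroNetwork

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "metrics_from_counts",
    "roc_auc",
    "evaluate_scores",
    "loocv",
    "independent_test",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise EvaluationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    """Scalar metrics plus (optionally) the ROC curve and its AUC."""

    SEN: float
    SPE: float
    ACC: float
    PRE: float
    MCC: float
    F1: float
    counts: ConfusionCounts | None = None
    roc: list[tuple[float, float]] = field(default_factory=list)
    auc: float | None = None

    def as_dict(self) -> dict:
        out = {
            "SEN": self.SEN,
            "SPE": self.SPE,
            "ACC": self.ACC,
            "PRE": self.PRE,
            "MCC": self.MCC,
            "F1": self.F1,
        }
        if self.auc is not None:
            out["AUC"] = self.auc
        if self.counts is not None:
            out.update(
                TP=self.counts.TP, FP=self.counts.FP, TN=self.counts.TN, FN=self.counts.FN
            )
        return out


def confusion_counts(
    labels: Sequence[int], predictions: Sequence[int]
) -> ConfusionCounts:
    """Tally TP/FP/TN/FN from binary labels and binary predictions."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape or labels.ndim != 1:
        raise EvaluationError("labels and predictions must be 1-D and equal length")
    for arr, name in ((labels, "labels"), (predictions, "predictions")):
        if not np.isin(arr, (0, 1)).all():
            raise EvaluationError(f"{name} must be binary (0/1)")
    return ConfusionCounts(
        TP=int(np.sum((labels == 1) & (predictions == 1))),
        FP=int(np.sum((labels == 0) & (predictions == 1))),
        TN=int(np.sum((labels == 0) & (predictions == 0))),
        FN=int(np.sum((labels == 1) & (predictions == 0))),
    )


def _safe_ratio(num: float, denom: float, name: str) -> float:
    if denom == 0:
        warnings.warn(f"{name} has a zero denominator; reporting 0", stacklevel=3)
        return 0.0
    return num / denom


def metrics_from_counts(c: ConfusionCounts) -> MetricsReport:
    """All six scalar metrics from a confusion table (zero denominators -> 0)."""
    if c.total == 0:
        raise EvaluationError("cannot compute metrics from an empty confusion table")
    sen = _safe_ratio(c.TP, c.TP + c.FN, "SEN")
    spe = _safe_ratio(c.TN, c.TN + c.FP, "SPE")
    acc = (c.TP + c.TN) / c.total
    pre = _safe_ratio(c.TP, c.TP + c.FP, "PRE")
    mcc_denom = sqrt(
        float(c.TP + c.FN) * (c.TP + c.FP) * (c.TN + c.FN) * (c.TN + c.FP)
    )
    mcc = _safe_ratio(c.TP * c.TN - c.FP * c.FN, mcc_denom, "MCC")
    f1 = _safe_ratio(2 * pre * sen, pre + sen, "F1")
    return MetricsReport(SEN=sen, SPE=spe, ACC=acc, PRE=pre, MCC=mcc, F1=f1, counts=c)


def roc_auc(
    labels: Sequence[int], scores: Sequence[float]
) -> tuple[list[tuple[float, float]], float]:
    """ROC points over all thresholds and the area under the curve.

    The curve runs from (0, 0) to (1, 1); the AUC equals the probability
    that a random positive outscores a random negative, ties counted 1/2.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        raise EvaluationError("ROC needs both label classes present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist())), float(roc_auc_score(labels, scores))


def evaluate_scores(
    labels: Sequence[int], scores: Sequence[float], threshold: float = 0.0
) -> MetricsReport:
    """Full report from continuous scores: confusion at ``threshold`` + ROC/AUC."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    predictions = (scores >= threshold).astype(int)
    report = metrics_from_counts(confusion_counts(labels, predictions))
    report.roc, report.auc = roc_auc(labels, scores)
    return report


def _without_pairs(
    network: HeteroNetwork,
    pairs: Sequence[tuple[str, str]],
    lnc_type: str,
    prot_type: str,
    strict: bool = False,
) -> HeteroNetwork:
    """Copy of the network with the given L-P edges removed.

    ``strict`` additionally zeroes every L-P edge incident to either
    endpoint of each pair (a harsher leakage control).
    """
    adj = network.relation(lnc_type, prot_type).copy()
    for l, p in pairs:
        i = network.position(lnc_type, l)
        j = network.position(prot_type, p)
        if strict:
            adj[i, :] = 0.0
            adj[:, j] = 0.0
        else:
            adj[i, j] = 0.0
    return network.replace_relation(lnc_type, prot_type, adj)


def loocv(
    network: HeteroNetwork,
    labeled: LabeledPairSet,
    paths: Sequence[MetaPath],
    config: ClassifierConfig | None = None,
    threshold: float = 0.0,
    strict: bool = False,
) -> tuple[np.ndarray, MetricsReport]:
    """Leave-one-out cross-validation over a labeled pair set.

    Each pair is held out in turn: its L-P edge is removed from the
    network, its features recomputed on the edited network, the classifier
    retrained on all remaining pairs (whose features come from the full
    network, computed once), and its decision score recorded.  Returns the
    held-out scores in input order and the metrics over them.
    """
    config = config or ClassifierConfig()
    if len(labeled) == 0:
        raise EvaluationError("LOOCV needs a nonempty labeled set")
    if np.unique(labeled.labels).size < 2:
        raise EvaluationError("LOOCV needs both label classes present")
    lnc_type, prot_type = paths[0].types[0], paths[0].types[-1]
    base = build_feature_table(network, labeled.ids, paths, config.beta)
    scores = np.empty(len(labeled))
    for i, (l, p) in enumerate(labeled.ids):
        edited = _without_pairs(network, [(l, p)], lnc_type, prot_type, strict=strict)
        held_out = build_feature_table(edited, [(l, p)], paths, config.beta)
        remaining = labeled.drop(i)
        if np.unique(remaining.labels).size < 2:
            # degenerate round (e.g. a 2-pair set): with one training class
            # the only defensible prediction is that class, at unit margin
            scores[i] = 1.0 if remaining.labels[0] == 1 else -1.0
            continue
        clf = train_classifier(base.drop_row(i), remaining, config)
        scores[i] = clf.decision_function(held_out)[0]
    report = evaluate_scores(labeled.labels, scores, threshold=threshold)
    return scores, report


def independent_test(
    train_set: LabeledPairSet,
    test_set: LabeledPairSet,
    network: HeteroNetwork,
    paths: Sequence[MetaPath],
    config: ClassifierConfig | None = None,
    threshold: float = 0.0,
) -> MetricsReport:
    """Fit once on training pairs, evaluate on a disjoint test set.

    The test pairs' positive edges are removed from the feature network
    before test features are computed, so the classifier never sees the
    associations it is asked to recover.
    """
    config = config or ClassifierConfig()
    overlap = set(train_set.ids) & set(test_set.ids)
    if overlap:
        raise ProtocolError(
            f"train and test pair sets overlap on {len(overlap)} pairs, "
            f"e.g. {sorted(overlap)[0]}"
        )
    lnc_type, prot_type = paths[0].types[0], paths[0].types[-1]
    train_features = build_feature_table(network, train_set.ids, paths, config.beta)
    clf = train_classifier(train_features, train_set, config)
    test_positives = [(l, p) for l, p, y in test_set.pairs if y == 1]
    edited = _without_pairs(network, test_positives, lnc_type, prot_type)
    test_features = build_feature_table(edited, test_set.ids, paths, config.beta)
    scores = clf.decision_function(test_features)
    return evaluate_scores(test_set.labels, scores, threshold=threshold)
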