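"""Scoring predicted subtypes against known classes.

Unsupervised cluster ids carry no class meaning, so evaluation first finds
the cluster -> class mapping that maximizes agreement (optimal assignment
over the contingency table), then reports sensitivity, specificity,
positive/negative predictive value, accuracy, a confusion matrix, and
ROC/AUC.  For clustering output the ROC score can be either the hard label
(two-point ROC, AUC = (Sn + Sp) / 2) or a continuous per-sample consensus
membership strength.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score

from .consensus import ClusterAssignment, ConsensusMatrix

log = logging.getLogger("wmrca")


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class ClassificationMetrics:
    sn: float
    sp: float
    ppv: float
    npv: float
    acc: float

    def as_dict(self) -> dict[str, float]:
        return {"Sn": self.sn, "Sp": self.sp, "PPV": self.ppv, "NPV": self.npv, "ACC": self.acc}


def match_labels(
    pred: ClusterAssignment,
    truth: dict[str, str],
) -> tuple[dict[int, str], dict[str, str]]:
    """Optimal cluster -> class mapping and the relabeled prediction.

    Maximizes total agreement over the cluster × class contingency table
    (Hungarian assignment).  When there are more clusters than classes the
    surplus clusters map to their modal class.  Ties are resolved
    deterministically (classes considered in sorted order).
    """
    common = [s for s in pred.labels if s in truth]
    if not common:
        raise ValueError("prediction and truth share no samples")
    classes = sorted(set(truth[s] for s in common))
    clusters = list(range(1, pred.K + 1))
    cont = np.zeros((len(clusters), len(classes)), dtype=int)
    for s in common:
        cont[pred.labels[s] - 1, classes.index(truth[s])] += 1
    size = max(len(clusters), len(classes))
    padded = np.zeros((size, size), dtype=int)
    padded[: len(clusters), : len(classes)] = cont
    rows, cols = linear_sum_assignment(-padded)
    mapping: dict[int, str] = {}
    for r, c in zip(rows, cols):
        if r < len(clusters):
            if c < len(classes):
                mapping[clusters[r]] = classes[c]
            else:  # surplus cluster: fall back to its modal class
                mapping[clusters[r]] = classes[int(np.argmax(cont[r]))]
    relabeled = {s: mapping[pred.labels[s]] for s in common}
    return mapping, relabeled


def confusion_counts(
    pred_classes: dict[str, str],
    truth: dict[str, str],
    positive_class: str,
) -> ConfusionCounts:
    """Binary confusion counts for one class treated as positive."""
    common = [s for s in pred_classes if s in truth]
    if not common:
        raise ValueError("no overlapping samples")
    tp = fp = tn = fn = 0
    for s in common:
        p = pred_classes[s] == positive_class
        t = truth[s] == positive_class
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def _safe_ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        log.warning("%s undefined (zero denominator); returning NaN", name)
        return float("nan")
    return num / den


def classification_metrics(c: ConfusionCounts) -> ClassificationMetrics:
    """Sn, Sp, PPV, NPV and ACC from confusion counts (NaN when undefined)."""
    return ClassificationMetrics(
        sn=_safe_ratio(c.TP, c.TP + c.FN, "Sn"),
        sp=_safe_ratio(c.TN, c.TN + c.FP, "Sp"),
        ppv=_safe_ratio(c.TP, c.TP + c.FP, "PPV"),
        npv=_safe_ratio(c.TN, c.TN + c.FN, "NPV"),
        acc=_safe_ratio(c.TP + c.TN, c.total, "ACC"),
    )


def roc_auc_from_scores(
    scores: np.ndarray,
    truth_positive: np.ndarray,
) -> tuple[float, pd.DataFrame]:
    """AUC by the rank (Mann–Whitney) formulation with tie correction.

    ``truth_positive`` is a boolean array; higher scores should indicate
    the positive class.  Also returns the ROC points (FPR, TPR) swept over
    all score thresholds.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(truth_positive, dtype=bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present in the truth")
    ranks = rankdata(scores, method="average")
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    thresholds = np.unique(scores)[::-1]
    points = [(0.0, 0.0)]
    for th in thresholds:
        called = scores >= th
        points.append(((called & ~pos).sum() / n_neg, (called & pos).sum() / n_pos))
    roc = pd.DataFrame(points, columns=["fpr", "tpr"])
    return float(auc), roc


def roc_auc_from_labels(
    pred_classes: dict[str, str],
    truth: dict[str, str],
    positive_class: str,
) -> tuple[float, pd.DataFrame]:
    """Two-point ROC from hard class labels: AUC = (Sn + Sp) / 2."""
    m = classification_metrics(confusion_counts(pred_classes, truth, positive_class))
    if np.isnan(m.sn) or np.isnan(m.sp):
        raise ValueError("Sn or Sp undefined; cannot build a ROC from these labels")
    roc = pd.DataFrame(
        [(0.0, 0.0), (1.0 - m.sp, m.sn), (1.0, 1.0)], columns=["fpr", "tpr"])
    return float((m.sn + m.sp) / 2.0), roc


def membership_strength(cm: ConsensusMatrix, assignment: ClusterAssignment) -> dict[str, float]:
    """Per-sample mean consensus with the other members of its cluster.

    A continuous confidence score for ROC curves on clustering output:
    samples firmly inside a consensus block score near 1.
    """
    labels = assignment.to_array(cm.sample_ids)
    out: dict[str, float] = {}
    for i, s in enumerate(cm.sample_ids):
        mates = np.flatnonzero(labels == labels[i])
        mates = mates[mates != i]
        out[s] = float(cm.M[i, mates].mean()) if mates.size else 1.0
    return out


def cluster_affinity_scores(
    cm: ConsensusMatrix,
    assignment: ClusterAssignment,
    clusters: list[int],
) -> dict[str, float]:
    """Mean consensus of every sample with the members of given clusters.

    Used as the continuous ROC score for a class: samples that co-cluster
    reliably with the class's consensus block score near 1 whether or not
    they were assigned to it.
    """
    labels = assignment.to_array(cm.sample_ids)
    members = np.flatnonzero(np.isin(labels, clusters))
    if members.size == 0:
        raise ValueError(f"clusters {clusters} are empty")
    out: dict[str, float] = {}
    for i, s in enumerate(cm.sample_ids):
        others = members[members != i]
        out[s] = float(cm.M[i, others].mean()) if others.size else 1.0
    return out


def ari(pred: ClusterAssignment | dict[str, int], truth: dict[str, int | str]) -> float:
    """Adjusted Rand index between a prediction and true classes."""
    labels = pred.labels if isinstance(pred, ClusterAssignment) else pred
    common = [s for s in labels if s in truth]
    if not common:
        raise ValueError("no overlapping samples")
    return float(adjusted_rand_score(
        [str(truth[s]) for s in common], [labels[s] for s in common]))
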