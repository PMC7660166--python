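"""Classifier evaluation: ROC/AUC, Youden cutoff, confusion metrics,
cutoff-anchored score normalization, and mean-performance summaries.

A trained target model emits a raw probability x_u in [0, 1].  The
operating cutoff c is the Youden-optimal threshold (maximizing
J = SE + SP - 1) on the held-out test ROC curve.  For display, raw
probabilities are normalized so that the cutoff maps to 0.5:

    x_n = x_u ** (-log_c 2)

which fixes 0 -> 0, c -> 0.5, 1 -> 1 and is strictly increasing, so a
normalized score of 0.5 always means "exactly at the operating point"
regardless of which cutoff a given target model learned.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "RocCurve",
    "ConfusionCounts",
    "MetricSet",
    "UndefinedAUCError",
    "compute_roc_auc",
    "youden_threshold",
    "confusion_counts",
    "compute_metrics",
    "normalize_score",
    "display_round",
    "summarize_means",
    "load_reference_performance",
]

METRIC_NAMES = ("auc", "se", "sp", "acc", "bac", "mcc")


class UndefinedAUCError(ValueError):
    """ROC/AUC requested on data with a single class."""


@dataclass
class RocCurve:
    """ROC evaluated at every distinct score threshold.

    ``thresholds`` are the distinct observed scores in ascending order;
    a compound is called active when its score >= threshold, so SE is
    non-increasing and SP non-decreasing along the array.
    """

    thresholds: np.ndarray
    se: np.ndarray
    sp: np.ndarray

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.sp

    @property
    def tpr(self) -> np.ndarray:
        return self.se


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if not np.all(np.isin(classes, (0, 1))):
        raise ValueError("labels must be binary 0/1")
    if classes.size < 2:
        raise UndefinedAUCError("both classes required to evaluate a ROC curve")
    return labels


def compute_roc_auc(scores, labels) -> tuple[RocCurve, float]:
    """ROC curve over all distinct score thresholds, and its AUC.

    AUC is the probability that a random active outscores a random
    inactive, with ties counting one half (rank/Mann-Whitney form).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    thresholds = np.unique(scores)  # ascending
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    # active call: score >= t;  TP = #pos >= t, via searchsorted on sorted arrays
    tp = pos.size - np.searchsorted(pos, thresholds, side="left")
    fp = neg.size - np.searchsorted(neg, thresholds, side="left")
    se = tp / pos.size
    sp = (neg.size - fp) / neg.size
    auc = float(roc_auc_score(labels, scores))
    return RocCurve(thresholds=thresholds, se=se, sp=sp), auc


def youden_threshold(curve: RocCurve) -> float:
    """Cutoff maximizing the Youden index J = SE + SP - 1.

    Ties are broken toward the smallest cutoff.  When every score is
    identical the ROC is a single chance point (J = 0); that score is
    returned and the degeneracy is reported as a warning.
    """
    j = curve.se + curve.sp - 1.0
    best = int(np.argmax(j))  # argmax takes the first (= smallest threshold) tie
    if curve.thresholds.size == 1:
        warnings.warn("all scores identical; Youden cutoff is degenerate", stacklevel=2)
    return float(curve.thresholds[best])


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.tp + self.tn + self.fp + self.fn < 1:
            raise ValueError("confusion counts must total at least 1")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(labels, calls) -> ConfusionCounts:
    """Tally a confusion matrix from true labels and binary calls."""
    labels = np.asarray(labels, dtype=int)
    calls = np.asarray(calls, dtype=int)
    return ConfusionCounts(
        tp=int(np.sum((labels == 1) & (calls == 1))),
        tn=int(np.sum((labels == 0) & (calls == 0))),
        fp=int(np.sum((labels == 0) & (calls == 1))),
        fn=int(np.sum((labels == 1) & (calls == 0))),
    )


@dataclass
class MetricSet:
    """The six performance metrics; undefined entries are NaN and listed
    in ``undefined`` (e.g. SE with no positives in the test set)."""

    se: float = math.nan
    sp: float = math.nan
    acc: float = math.nan
    bac: float = math.nan
    mcc: float = math.nan
    auc: float = math.nan
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def compute_metrics(cc: ConfusionCounts) -> MetricSet:
    """SE, SP, ACC, BAC and MCC from confusion counts (AUC left NaN).

    SE = TP/(TP+FN); SP = TN/(TN+FP); ACC = (TP+TN)/total;
    BAC = (SE+SP)/2; MCC = (TP*TN - FP*FN) / sqrt of the product of the
    four marginals.  A zero denominator flags that metric undefined
    while the others are still returned.
    """
    out = MetricSet()
    tp, tn, fp, fn = cc.tp, cc.tn, cc.fp, cc.fn
    if tp + fn > 0:
        out.se = tp / (tp + fn)
    else:
        out.undefined.append("se")
    if tn + fp > 0:
        out.sp = tn / (tn + fp)
    else:
        out.undefined.append("sp")
    out.acc = (tp + tn) / cc.total
    if math.isnan(out.se) or math.isnan(out.sp):
        out.undefined.append("bac")
    else:
        out.bac = (out.se + out.sp) / 2.0
    denom = (
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if denom > 0:
        out.mcc = (float(tp) * tn - float(fp) * fn) / math.sqrt(denom)
    else:
        out.undefined.append("mcc")
    return out


def normalize_score(x_u, c: float):
    """Map a raw probability to the cutoff-anchored display scale.

    x_n = x_u ** (-log_c 2), so 0 -> 0, the cutoff c -> 0.5, 1 -> 1.
    Accepts scalars or arrays; requires 0 < c < 1.
    """
    if not 0.0 < c < 1.0:
        raise ValueError(f"cutoff must lie strictly inside (0, 1), got {c}")
    x = np.asarray(x_u, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("raw scores must lie in [0, 1]")
    exponent = -math.log(2.0) / math.log(c)
    out = np.power(x, exponent)
    return float(out) if np.isscalar(x_u) else out


def display_round(x: float, ndigits: int = 3) -> float:
    """Half-up rounding for report display (0.8275 -> 0.828)."""
    if isinstance(x, float) and math.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def summarize_means(per_target: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample standard deviation per metric across targets.

    ``per_target`` holds one row per target with metric columns;
    undefined (NaN) entries are skipped per column.  Requires at least
    two targets.
    """
    cols = [c for c in per_target.columns if c in METRIC_NAMES]
    if len(per_target) < 2:
        raise ValueError("need at least two targets to summarize")
    data = per_target[cols].astype(float)
    return pd.DataFrame(
        {
            "mean": data.mean(axis=0, skipna=True),
            "sd": data.std(axis=0, ddof=1, skipna=True),
            "n": data.notna().sum(axis=0),
        }
    )


def load_reference_performance(path: str | Path | None = None) -> pd.DataFrame:
    """Reference per-target test-set benchmark metrics (packaged CSV).

    Long format: one row per target x criterion with columns aid,
    abbreviation, criterion, auc, se, sp, acc, bac, mcc.  The single
    target x criterion with an all-inactive test split has NaN metrics.
    """
    if path is None:
        source = resources.files("mietox.data").joinpath("benchmark_metrics.csv")
        with resources.as_file(source) as p:
            return pd.read_csv(p)
    return pd.read_csv(path)
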