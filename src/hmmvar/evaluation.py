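"""Classifier evaluation: class-balanced metrics, ROC, threshold calibration.

Benchmark datasets of disease versus neutral substitutions are rarely
balanced, so headline metrics here are computed from *normalized* confusion
counts: each class is rescaled to unit mass (tp' = tp/(tp+fn),
tn' = tn/(tn+fp)) before the six standard measures — accuracy, precision,
specificity, sensitivity, negative predictive value and the Matthews
correlation coefficient — are derived.  Normalized accuracy is then exactly
the balanced accuracy (sensitivity + specificity) / 2.

Disease is the positive class throughout.  Scores are oriented so that more
negative means more disease-like; ROC and calibration take an orientation
flag for scorers with the opposite convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import SingleClassError, UndefinedMetricError, ValidationError
from .scoring import Call, Prediction
from .weights import DISEASE, LABELS, NEUTRAL


@dataclass(frozen=True)
class ConfusionCounts:
    """tp/fp/tn/fn; integers for raw counts, reals after normalization."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    specificity: float
    sensitivity: float
    npv: float
    mcc: float
    normalized: bool

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "npv": self.npv,
            "mcc": self.mcc,
        }


@dataclass(frozen=True)
class ConfusionResult:
    """Confusion counts plus how many records received no prediction."""

    counts: ConfusionCounts
    n_no_prediction: int
    n_total: int

    @property
    def coverage(self) -> float:
        """Fraction of labelled records that received a prediction."""
        if self.n_total == 0:
            return 0.0
        return 1.0 - self.n_no_prediction / self.n_total


def _sub_key(p: Prediction) -> tuple:
    s = p.substitution
    return (s.protein_id, s.position, s.wild_type, s.mutant)


def confusion(
    predictions: Sequence[Prediction],
    labels: Mapping[tuple, str] | Sequence[str],
) -> ConfusionResult:
    """Cross-tabulate predictions against disease/neutral labels.

    ``labels`` is either a sequence aligned with ``predictions`` or a
    mapping from (protein_id, position, wild_type, mutant) keys.  Records
    with no prediction are excluded from the counts and reported via
    ``n_no_prediction`` (the complement of analysis coverage).
    """
    if isinstance(labels, Mapping):
        resolved = []
        for p in predictions:
            key = _sub_key(p)
            if key not in labels:
                raise ValidationError(f"no label for prediction {p.substitution}")
            resolved.append(labels[key])
    else:
        if len(labels) != len(predictions):
            raise ValidationError(
                f"{len(predictions)} predictions but {len(labels)} labels"
            )
        resolved = list(labels)
    tp = fp = tn = fn = 0
    skipped = 0
    for p, label in zip(predictions, resolved):
        if label not in LABELS:
            raise ValidationError(f"label must be one of {LABELS}, got {label!r}")
        if p.call is Call.NO_PREDICTION:
            skipped += 1
            continue
        damaging = p.call is Call.DAMAGING
        if label == DISEASE:
            tp, fn = (tp + 1, fn) if damaging else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if damaging else (fp, tn + 1)
    return ConfusionResult(
        ConfusionCounts(tp, fp, tn, fn), skipped, len(predictions)
    )


def normalize(c: ConfusionCounts) -> ConfusionCounts:
    """Rescale each class to unit mass: tp' = tp/(tp+fn), tn' = tn/(tn+fp)."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("normalization", "no positive-class records (tp+fn=0)")
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("normalization", "no negative-class records (tn+fp=0)")
    tp = c.tp / (c.tp + c.fn)
    tn = c.tn / (c.tn + c.fp)
    return ConfusionCounts(tp=tp, fp=1.0 - tn, tn=tn, fn=1.0 - tp)


def metrics(c: ConfusionCounts, normalized: bool = True) -> MetricSet:
    """The six standard performance measures, optionally on normalized counts."""
    if normalized:
        c = normalize(c)
    denominators = {
        "accuracy": c.total,
        "precision": c.tp + c.fp,
        "specificity": c.tn + c.fp,
        "sensitivity": c.tp + c.fn,
        "npv": c.tn + c.fn,
    }
    for name, d in denominators.items():
        if d == 0:
            raise UndefinedMetricError(name)
    mcc_den = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if mcc_den == 0:
        raise UndefinedMetricError("mcc")
    return MetricSet(
        accuracy=(c.tp + c.tn) / c.total,
        precision=c.tp / (c.tp + c.fp),
        specificity=c.tn / (c.tn + c.fp),
        sensitivity=c.tp / (c.tp + c.fn),
        npv=c.tn / (c.tn + c.fn),
        mcc=(c.tp * c.tn - c.fp * c.fn) / math.sqrt(mcc_den),
        normalized=normalized,
    )


# ---------------------------------------------------------------------------
# ROC and threshold calibration


def _check_two_classes(labels: Sequence[str]) -> tuple[int, int]:
    n_pos = sum(1 for x in labels if x == DISEASE)
    n_neg = sum(1 for x in labels if x == NEUTRAL)
    bad = [x for x in labels if x not in LABELS]
    if bad:
        raise ValidationError(f"labels must be in {LABELS}; found {bad[0]!r}")
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError(
            f"need both classes, got {n_pos} disease / {n_neg} neutral"
        )
    return n_pos, n_neg


@dataclass(frozen=True)
class RocCurve:
    """ROC sweep over all distinct score thresholds; area by the trapezoid rule."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def truncated(self, max_fpr: float) -> "RocCurve":
        """The curve restricted to fpr <= max_fpr (e.g. a 10% false-positive
        view), with the partial area under the restricted segment."""
        if not 0 < max_fpr <= 1:
            raise ValidationError(f"max_fpr must be in (0, 1], got {max_fpr}")
        fpr, tpr = self.fpr, self.tpr
        keep = fpr <= max_fpr
        fx, ty = fpr[keep], tpr[keep]
        if fx[-1] < max_fpr:  # interpolate the boundary point
            j = int(np.searchsorted(fpr, max_fpr))
            t = (max_fpr - fpr[j - 1]) / (fpr[j] - fpr[j - 1])
            fx = np.append(fx, max_fpr)
            ty = np.append(ty, tpr[j - 1] + t * (tpr[j] - tpr[j - 1]))
        return RocCurve(fx, ty, float(np.trapezoid(ty, fx)))


def roc(
    scores: Sequence[float],
    labels: Sequence[str],
    lower_is_positive: bool = True,
) -> RocCurve:
    """ROC curve and AUC for continuous scores against disease/neutral labels.

    With the native orientation (``lower_is_positive``) a more negative score
    ranks as more disease-like.
    """
    if len(scores) != len(labels):
        raise ValidationError(f"{len(scores)} scores but {len(labels)} labels")
    _check_two_classes(labels)
    y = np.array([1 if x == DISEASE else 0 for x in labels])
    s = np.asarray(scores, dtype=float)
    if lower_is_positive:
        s = -s
    fpr, tpr, _ = _sk_roc_curve(y, s)
    return RocCurve(fpr, tpr, float(_sk_auc(fpr, tpr)))


@dataclass(frozen=True)
class CalibrationResult:
    threshold: float
    sensitivity: float
    specificity: float


def calibrate_threshold(
    scores: Sequence[float],
    labels: Sequence[str],
    lower_is_positive: bool = True,
) -> CalibrationResult:
    """The threshold at which sensitivity and specificity are jointly maximised.

    Candidate thresholds are the midpoints between adjacent distinct scores
    plus sentinels beyond either extreme; a record is called positive when
    its score falls strictly below the threshold (native orientation).  The
    candidate maximising min(sensitivity, specificity) wins; ties break
    toward larger sensitivity + specificity, then the larger threshold.
    """
    if len(scores) != len(labels):
        raise ValidationError(f"{len(scores)} scores but {len(labels)} labels")
    n_pos, n_neg = _check_two_classes(labels)
    s = np.asarray(scores, dtype=float)
    if not lower_is_positive:
        s = -s
    y = np.array([1 if x == DISEASE else 0 for x in labels])

    order = np.argsort(s, kind="stable")
    s_sorted = s[order]
    pos_below = np.cumsum(y[order])  # positives with score <= s_sorted[i]
    distinct = np.unique(s_sorted)
    span = max(distinct[-1] - distinct[0], 1.0)
    candidates = np.concatenate(
        [
            [distinct[0] - span],
            (distinct[:-1] + distinct[1:]) / 2.0,
            [distinct[-1] + span],
        ]
    )

    best: tuple[float, float, float] | None = None
    best_result: CalibrationResult | None = None
    for t in candidates:
        k = int(np.searchsorted(s_sorted, t, side="left"))  # records with score < t
        tp = int(pos_below[k - 1]) if k > 0 else 0
        fp = k - tp
        sens = tp / n_pos
        spec = (n_neg - fp) / n_neg
        key = (min(sens, spec), sens + spec, t)
        if best is None or key > best:
            best = key
            best_result = CalibrationResult(float(t), sens, spec)
    assert best_result is not None
    if not lower_is_positive:
        best_result = CalibrationResult(
            -best_result.threshold, best_result.sensitivity, best_result.specificity
        )
    return best_result


# ---------------------------------------------------------------------------
# Method overlap (Venn regions of correctly identified positives)


def method_overlap(tp_sets: Mapping[str, Iterable]) -> dict[frozenset[str], int]:
    """Venn-region counts for 2-3 named sets of correctly identified positives.

    Returns exclusive region counts keyed by the subset of method names an
    element belongs to; the regions partition the union.
    """
    names = list(tp_sets)
    if not 2 <= len(names) <= 3:
        raise ValidationError(
            f"method_overlap supports 2 or 3 sets, got {len(names)}"
        )
    sets = {name: set(v) for name, v in tp_sets.items()}
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            regions[frozenset(combo)] = len(inside - outside)
    return regions
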