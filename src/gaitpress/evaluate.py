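"""Biometric and classification metrics.

Open-set convention: a decision is *positive* when the query is accepted
as an authorized (enrolled) individual.  For authorized queries an
acceptance is a true positive and a rejection a false negative; for
unauthorized queries an acceptance is a false acceptance (FP) and a
rejection a true negative.  Whether an accepted authorized query also
names the right identity is reported separately (``tp_correct_id``).

FRR = FN / (FN + TP), FAR = FP / (FP + TN),
accuracy = (TP + TN) / total, precision = TP / (TP + FP),
recall (TPR) = TP / (TP + FN),
F1 = 2 * precision * recall / (precision + recall).

Undefined ratios (zero denominators) are returned as NaN, never as a
silent 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

from .openset import UNKNOWN

__all__ = [
    "ConfusionCounts",
    "ThresholdSweepResult",
    "MisclassRecord",
    "confusion",
    "frr",
    "far",
    "classification_metrics",
    "multiclass_metrics",
    "f1_from_precision_recall",
    "sweep_thresholds",
    "roc_auc",
    "misclassification_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    tp_correct_id: int = 0  # accepted authorized queries with correct identity

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(
    decisions: Sequence[tuple[Hashable, Hashable]],
    known: set | None = None,
) -> ConfusionCounts:
    """Tally open-set decisions ``(true_label, predicted_label_or_unknown)``.

    ``known`` is the enrolled-identity set; when omitted it is taken as
    every true label that is not ``UNKNOWN``.
    """
    if known is None:
        known = {t for t, _ in decisions if t != UNKNOWN}
    tp = fp = fn = tn = tp_id = 0
    for true, pred in decisions:
        authorized = true in known
        accepted = pred != UNKNOWN
        if authorized and accepted:
            tp += 1
            if pred == true:
                tp_id += 1
        elif authorized:
            fn += 1
        elif accepted:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, tp_correct_id=tp_id)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def frr(c: ConfusionCounts) -> float:
    """False rejection rate FN / (FN + TP); NaN when no authorized events."""
    return _ratio(c.fn, c.fn + c.tp)


def far(c: ConfusionCounts) -> float:
    """False acceptance rate FP / (FP + TN); NaN when no impostor events."""
    return _ratio(c.fp, c.fp + c.tn)


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (same units as the inputs)."""
    if precision + recall == 0:
        return float("nan")
    return 2.0 * recall * precision / (recall + precision)


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from binary confusion counts."""
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    return {
        "accuracy": _ratio(c.tp + c.tn, c.total),
        "precision": precision,
        "recall": recall,
        "f1": f1_from_precision_recall(precision, recall),
    }


def multiclass_metrics(y_true: Sequence, y_pred: Sequence) -> dict[str, float]:
    """Closed-set metrics: overall accuracy + macro-averaged P/R/F1.

    Per-class one-vs-rest counts are macro-averaged; classes never
    predicted contribute NaN-free zeros to precision only when they have
    no predictions at all (scikit-learn's zero_division=0 convention is
    *not* used: empty denominators are skipped from the macro mean).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    classes = np.unique(y_true)
    precisions, recalls, f1s = [], [], []
    for cls in classes:
        tp = int(((y_true == cls) & (y_pred == cls)).sum())
        fp = int(((y_true != cls) & (y_pred == cls)).sum())
        fn = int(((y_true == cls) & (y_pred != cls)).sum())
        p = _ratio(tp, tp + fp)
        r = _ratio(tp, tp + fn)
        if not np.isnan(p):
            precisions.append(p)
        if not np.isnan(r):
            recalls.append(r)
        if not (np.isnan(p) or np.isnan(r) or p + r == 0):
            f1s.append(f1_from_precision_recall(p, r))
        elif not (np.isnan(p) or np.isnan(r)):
            f1s.append(0.0)
    return {
        "accuracy": float((y_true == y_pred).mean()),
        "precision": float(np.mean(precisions)) if precisions else float("nan"),
        "recall": float(np.mean(recalls)) if recalls else float("nan"),
        "f1": float(np.mean(f1s)) if f1s else float("nan"),
    }


# ---------------------------------------------------------------------------
# threshold sweeps, EER, ROC


@dataclass
class ThresholdSweepResult:
    thresholds: np.ndarray
    far_curve: np.ndarray
    frr_curve: np.ndarray
    acc_known: np.ndarray
    acc_unknown: np.ndarray
    acc_overall: np.ndarray
    eer: float
    eer_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "far": self.far_curve,
            "frr": self.frr_curve,
            "acc_known": self.acc_known,
            "acc_unknown": self.acc_unknown,
            "acc_overall": self.acc_overall,
        })


def _rates_at(thresholds: np.ndarray, genuine: np.ndarray,
              impostor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """FAR(t) and FRR(t) for the accept-if-score>=t rule (vectorised)."""
    gs = np.sort(genuine)
    is_ = np.sort(impostor)
    # FRR(t) = fraction of genuine scores < t ; FAR(t) = fraction >= t
    frr_curve = np.searchsorted(gs, thresholds, side="left") / len(gs)
    far_curve = 1.0 - np.searchsorted(is_, thresholds, side="left") / len(is_)
    return far_curve, frr_curve


def compute_eer(genuine: np.ndarray, impostor: np.ndarray,
                thresholds: np.ndarray) -> tuple[float, float]:
    """EER and its threshold by linear interpolation of the crossing.

    FAR - FRR is non-increasing in the threshold; the EER is read off at
    the first sign change by linearly interpolating both step curves
    between the adjacent grid points.
    """
    far_c, frr_c = _rates_at(thresholds, genuine, impostor)
    diff = far_c - frr_c
    idx = np.nonzero(diff <= 0)[0]
    if len(idx) == 0:  # curves never cross inside the grid
        return float((far_c[-1] + frr_c[-1]) / 2), float(thresholds[-1])
    j = idx[0]
    if j == 0 or diff[j] == 0:
        return float((far_c[j] + frr_c[j]) / 2), float(thresholds[j])
    t0, t1 = thresholds[j - 1], thresholds[j]
    d0, d1 = diff[j - 1], diff[j]
    alpha = d0 / (d0 - d1)
    t_star = t0 + alpha * (t1 - t0)
    far_star = far_c[j - 1] + alpha * (far_c[j] - far_c[j - 1])
    frr_star = frr_c[j - 1] + alpha * (frr_c[j] - frr_c[j - 1])
    return float((far_star + frr_star) / 2), float(t_star)


def sweep_thresholds(
    genuine_scores: np.ndarray,
    impostor_scores: np.ndarray,
    grid: np.ndarray | None = None,
) -> ThresholdSweepResult:
    """FAR/FRR/accuracy curves over a threshold grid, with the EER.

    ``grid`` defaults to the sorted unique scores (plus end caps), the
    finest grid on which the empirical step curves change value.
    """
    genuine = np.asarray(genuine_scores, dtype=np.float64)
    impostor = np.asarray(impostor_scores, dtype=np.float64)
    if genuine.size == 0 or impostor.size == 0:
        raise ValueError("both score sets must be non-empty")
    if grid is None:
        scores = np.unique(np.concatenate([genuine, impostor]))
        pad = max(1e-6, 1e-6 * np.abs(scores).max())
        grid = np.concatenate([[scores[0] - pad], scores, [scores[-1] + pad]])
    grid = np.asarray(grid, dtype=np.float64)
    far_c, frr_c = _rates_at(grid, genuine, impostor)
    acc_known = 1.0 - frr_c
    acc_unknown = 1.0 - far_c
    n_g, n_i = len(genuine), len(impostor)
    acc_overall = (acc_known * n_g + acc_unknown * n_i) / (n_g + n_i)
    eer, eer_t = compute_eer(genuine, impostor, grid)
    return ThresholdSweepResult(
        thresholds=grid,
        far_curve=far_c,
        frr_curve=frr_c,
        acc_known=acc_known,
        acc_unknown=acc_unknown,
        acc_overall=acc_overall,
        eer=eer,
        eer_threshold=eer_t,
    )


def roc_auc(genuine_scores: np.ndarray, impostor_scores: np.ndarray) -> float:
    """AUC as P(genuine > impostor) with ties counted half (Mann-Whitney)."""
    g = np.asarray(genuine_scores, dtype=np.float64)
    i = np.asarray(impostor_scores, dtype=np.float64)
    if g.size == 0 or i.size == 0:
        raise ValueError("both score sets must be non-empty")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([g, i]))
    u = ranks[: len(g)].sum() - len(g) * (len(g) + 1) / 2
    return float(u / (len(g) * len(i)))


# ---------------------------------------------------------------------------
# misclassification attribution


@dataclass(frozen=True)
class MisclassRecord:
    count: int
    actual_id: int
    predicted_id: int
    actual_weight: float
    predicted_weight: float
    actual_shoe_size: int
    predicted_shoe_size: int
    common_points: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")


def misclassification_report(
    decisions: Sequence[tuple[int, int]],
    subject_meta: dict[int, dict],
    weight_tolerance_kg: float = 5.0,
) -> list[MisclassRecord]:
    """Aggregate closed-set confusions and attribute shared traits.

    ``subject_meta`` maps subject id -> {"weight_kg", "shoe_size_us"}.
    "Shoe Size" is marked common when the sizes are equal; "Weight" when
    the weights differ by at most ``weight_tolerance_kg``.  Records are
    sorted by descending count, then by actual id.
    """
    pairs: dict[tuple[int, int], int] = {}
    for true, pred in decisions:
        if true != pred:
            pairs[(true, pred)] = pairs.get((true, pred), 0) + 1
    records = []
    for (true, pred), count in pairs.items():
        ma, mp = subject_meta[true], subject_meta[pred]
        common = []
        if ma["shoe_size_us"] == mp["shoe_size_us"]:
            common.append("Shoe Size")
        if abs(ma["weight_kg"] - mp["weight_kg"]) <= weight_tolerance_kg:
            common.append("Weight")
        records.append(
            MisclassRecord(
                count=count,
                actual_id=true,
                predicted_id=pred,
                actual_weight=ma["weight_kg"],
                predicted_weight=mp["weight_kg"],
                actual_shoe_size=ma["shoe_size_us"],
                predicted_shoe_size=mp["shoe_size_us"],
                common_points=tuple(common),
            )
        )
    records.sort(key=lambda r: (-r.count, r.actual_id, r.predicted_id))
    return records
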