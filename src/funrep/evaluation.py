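"""Performance evaluation against a reference annotation.

The reference annotation fixes, for the evaluated organism, the set of
function ids known to be present (positives P) inside the universe of all
function ids in the database; everything else is a negative (N).  A
prediction is scored by set algebra: predicted and annotated functions
are true positives, predicted but unannotated ones false positives.

Rates follow the usual definitions and are reported in percent:
sensitivity TPR = TP/P, false-positive rate FPR = FP/N, specificity
1 - FPR, precision PPV = TP/(TP+FP), and the F1 score, the harmonic mean
of precision and sensitivity, as the single post-filtering quality index.

Ranking-based evaluation treats each evidence measure as a ranking of the
whole universe: the ROC curve and its area (AUC, the probability that a
random positive outranks a random negative, ties counted half) measure a
measure's discriminative power before any threshold is applied, and the
maximum achievable F1 over all thresholds bounds what any calibration
could reach on that ranking.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .assignments_io import HitTable
from .prediction import PredictionSet

__all__ = [
    "AnnotationReference",
    "ConfusionMetrics",
    "RocCurve",
    "confusion",
    "f1_from_rates",
    "roc_auc",
    "max_f1",
    "evalue_cutoff_sweep",
    "mean_auc",
]


@dataclass(frozen=True)
class AnnotationReference:
    """Annotated positives and the function universe of the database."""

    positives: frozenset[str]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("reference universe is empty")
        stray = self.positives - self.universe
        if stray:
            raise ValueError(
                f"positives outside the universe: {sorted(stray)[:5]}"
            )

    @property
    def negatives(self) -> frozenset[str]:
        return self.universe - self.positives

    @classmethod
    def from_files(
        cls, positives_path: str | os.PathLike, universe_path: str | os.PathLike
    ) -> "AnnotationReference":
        """Read one-function-id-per-line files (``#`` lines ignored)."""

        def read_ids(path):
            with open(path, "rt", encoding="utf-8") as fh:
                return frozenset(
                    line.strip()
                    for line in fh
                    if line.strip() and not line.startswith("#")
                )

        return cls(positives=read_ids(positives_path), universe=read_ids(universe_path))


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts with derived rates, rates in percent.

    An empty prediction has undefined precision; PPV and F1 are reported
    as 0 by convention and flagged via ``ppv_defined``.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n_positives(self) -> int:
        return self.tp + self.fn

    @property
    def n_negatives(self) -> int:
        return self.fp + self.tn

    @property
    def tpr(self) -> float:
        """Sensitivity, percent."""
        return 100.0 * self.tp / self.n_positives if self.n_positives else 0.0

    @property
    def fpr(self) -> float:
        """False-positive rate, percent."""
        return 100.0 * self.fp / self.n_negatives if self.n_negatives else 0.0

    @property
    def specificity(self) -> float:
        return 100.0 - self.fpr

    @property
    def ppv_defined(self) -> bool:
        return (self.tp + self.fp) > 0

    @property
    def ppv(self) -> float:
        """Precision, percent (0 for an empty prediction)."""
        return 100.0 * self.tp / (self.tp + self.fp) if self.ppv_defined else 0.0

    @property
    def f1(self) -> float:
        """Harmonic mean of precision and sensitivity, percent."""
        return f1_from_rates(self.tpr, self.ppv)

    def as_dict(self) -> dict[str, float]:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "TN": self.tn,
            "TPR": self.tpr,
            "FPR": self.fpr,
            "specificity": self.specificity,
            "PPV": self.ppv,
            "F1": self.f1,
        }


@dataclass(frozen=True)
class RocCurve:
    """ROC points (FPR, TPR) as fractions, plus the area under the curve."""

    points: tuple[tuple[float, float], ...]
    auc: float


def confusion(
    prediction: PredictionSet | Iterable[str], reference: AnnotationReference
) -> ConfusionMetrics:
    """Confusion counts of a prediction against the reference annotation.

    Predicted ids outside the universe are an error (they would silently
    distort the negative count otherwise).
    """
    predicted = (
        prediction.functions
        if isinstance(prediction, PredictionSet)
        else frozenset(prediction)
    )
    stray = predicted - reference.universe
    if stray:
        raise ValueError(
            f"predicted functions outside the universe: {sorted(stray)[:5]}"
        )
    tp = len(predicted & reference.positives)
    fp = len(predicted) - tp
    fn = len(reference.positives) - tp
    tn = len(reference.negatives) - fp
    return ConfusionMetrics(tp=tp, fp=fp, fn=fn, tn=tn)


def f1_from_rates(tpr_percent: float, ppv_percent: float) -> float:
    """F1 (percent) from sensitivity and precision given in percent.

    ``2 * TPR * PPV / (TPR + PPV)``; 0 by convention when both rates are 0.
    """
    if not (0.0 <= tpr_percent <= 100.0 and 0.0 <= ppv_percent <= 100.0):
        raise ValueError("rates must be in [0, 100]")
    if tpr_percent == 0.0 and ppv_percent == 0.0:
        return 0.0
    return 2.0 * tpr_percent * ppv_percent / (tpr_percent + ppv_percent)


def _universe_scores(
    scores: Mapping[str, float], reference: AnnotationReference
) -> tuple[np.ndarray, np.ndarray]:
    """Aligned (values, is_positive) arrays over the whole universe.

    Functions without an evidence entry gathered no hits at all; they are
    ranked strictly below every observed value (evidence minus infinity).
    """
    stray = set(scores) - set(reference.universe)
    if stray:
        raise ValueError(f"scored functions outside the universe: {sorted(stray)[:5]}")
    ids = sorted(reference.universe)
    values = np.array([scores.get(f, -np.inf) for f in ids], dtype=float)
    labels = np.array([f in reference.positives for f in ids], dtype=bool)
    if not labels.any() or labels.all():
        raise ValueError("AUC undefined: need at least one positive and one negative")
    return values, labels


def roc_auc(
    scores: Mapping[str, float],
    reference: AnnotationReference,
    absent_value_policy: str = "minus_infinity",
) -> RocCurve:
    """ROC curve and AUC of ranking the universe by descending evidence.

    The AUC uses the rank-statistic (Mann-Whitney) formulation with
    midranks for ties: it equals the probability that a random positive
    outranks a random negative, plus half the probability of a tie.
    """
    if absent_value_policy != "minus_infinity":
        raise ValueError(f"unknown absent_value_policy {absent_value_policy!r}")
    values, labels = _universe_scores(scores, reference)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos

    ranks = rankdata(values)  # midranks for ties; -inf ranks lowest
    auc = (float(ranks[labels].sum()) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-values, kind="mergesort")
    sorted_values = values[order]
    sorted_labels = labels[order]
    cum_tp = np.cumsum(sorted_labels)
    cum_fp = np.cumsum(~sorted_labels)
    # one ROC point per distinct threshold value (the end of each tie
    # block; != comparison rather than diff so that -inf ties compare equal)
    change = sorted_values[:-1] != sorted_values[1:]
    block_ends = np.append(np.nonzero(change)[0], sorted_values.size - 1)
    points = [(0.0, 0.0)] + [
        (cum_fp[i] / n_neg, cum_tp[i] / n_pos) for i in block_ends
    ]
    return RocCurve(points=tuple(points), auc=float(auc))


def max_f1(scores: Mapping[str, float], reference: AnnotationReference) -> float:
    """Best achievable F1 (percent) over all evidence thresholds.

    Scans every distinct score as a candidate threshold under the strict
    ``value > t`` prediction rule; this is the best possible separation of
    genuine from spurious functions on the given ranking, so it bounds the
    F1 of any calibrated threshold on the same scores.
    """
    values, labels = _universe_scores(scores, reference)
    n_pos = int(labels.sum())
    order = np.argsort(-values, kind="mergesort")
    sorted_values = values[order]
    sorted_labels = labels[order]
    cum_tp = np.cumsum(sorted_labels)
    # candidate prediction sizes: number of items strictly above each
    # distinct value, i.e. the start index of every tie block (incl. 0 =
    # empty prediction at a threshold above the maximum)
    change = sorted_values[1:] != sorted_values[:-1]
    block_starts = np.concatenate([[0], np.nonzero(change)[0] + 1])
    best = 0.0
    for k in block_starts:
        tp = int(cum_tp[k - 1]) if k > 0 else 0
        f1 = 200.0 * tp / (k + n_pos) if (k + n_pos) else 0.0
        best = max(best, f1)
    return best


def evalue_cutoff_sweep(
    hits: HitTable,
    reference: AnnotationReference,
    cutoffs: Sequence[float],
) -> list[tuple[float, ConfusionMetrics]]:
    """Naive E-value-based prediction at each cutoff, for comparison.

    At cutoff E the prediction is every function with at least one hit of
    E-value <= E; no evidence model is involved.  Tightening the cutoff
    can only remove hits, so TP and FP are non-increasing along a
    descending cutoff sequence.
    """
    frame = hits.frame
    if frame["e_value"].isna().any():
        raise ValueError("E-value sweep requires an E-value on every hit")
    results = []
    for cutoff in cutoffs:
        predicted = frozenset(frame.loc[frame["e_value"] <= cutoff, "function_id"])
        results.append((float(cutoff), confusion(predicted, reference)))
    return results


def mean_auc(curves: Iterable[RocCurve]) -> float:
    """Mean of per-sample AUCs (no curve averaging is attempted)."""
    aucs = [curve.auc for curve in curves]
    if not aucs:
        raise ValueError("no curves given")
    return float(np.mean(aucs))


def metrics_table(
    rows: Mapping[str, ConfusionMetrics]
) -> pd.DataFrame:
    """Tabulate metrics, one row per labelled prediction set or cutoff."""
    frame = pd.DataFrame(
        [{"label": label, **m.as_dict()} for label, m in rows.items()]
    )
    return frame


def write_metrics_json(
    rows: Mapping[str, ConfusionMetrics], path: str | os.PathLike, **extra
) -> None:
    payload = {label: m.as_dict() for label, m in rows.items()}
    payload.update(extra)
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
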