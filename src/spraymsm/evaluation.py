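"""Confusion-matrix bookkeeping and accuracy reporting.

The binary convention throughout is spray = positive class.  Accuracy is
the plain fraction of correct decisions,

    accuracy = 100 * (TP + TN) / (TP + FP + FN + TN)   [percent],

reported at full precision internally and rounded half-up to one decimal
for display.  Location summaries report both the unweighted mean of
per-location accuracies (the convention of the bundled field-study
reference counts) and the pooled accuracy over the summed counts, labeled
distinctly — the two generally differ when locations have unequal totals.

A small fixture of reference confusion counts from a published UAV
spray-area field study (cropland and orchard classifiers at three
locations, L1-L3) ships with the package for regression-testing the
accuracy arithmetic; see :func:`load_field_confusion_counts`.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

from .exceptions import InvalidInputError, UndefinedMetricError


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with spray as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise InvalidInputError(f"{name} must be a nonnegative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
            tn=self.tn + other.tn,
        )


@dataclass(frozen=True)
class AccuracyReport:
    """Per-location accuracies (percent) with their unweighted mean and pooled value."""

    per_location: dict[str, float]
    mean_accuracy_percent: float
    pooled_accuracy_percent: float


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up, the display convention for reported accuracies."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def confusion_from_results(
    pairs: Sequence[tuple[str, str]], positive_label: str
) -> ConfusionMatrix:
    """Tally (true_label, predicted_label) pairs into a 2x2 confusion matrix.

    Exactly two distinct labels may occur; everything that is not the
    positive label is the negative class.
    """
    if not pairs:
        raise InvalidInputError("no classification results to tally")
    labels = {lab for pair in pairs for lab in pair}
    if len(labels - {positive_label}) > 1:
        raise InvalidInputError(
            f"expected binary labels with positive {positive_label!r}, got {sorted(labels)}"
        )
    tp = fp = fn = tn = 0
    for true, pred in pairs:
        if pred == positive_label:
            if true == positive_label:
                tp += 1
            else:
                fp += 1
        else:
            if true == positive_label:
                fn += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def accuracy(cm: ConfusionMatrix) -> float:
    """Percent of correct decisions, 100 * (TP + TN) / total, full precision."""
    if cm.total < 1:
        raise UndefinedMetricError("accuracy is undefined on an empty confusion matrix")
    return 100.0 * (cm.tp + cm.tn) / cm.total


def summarize_locations(matrices: Mapping[str, ConfusionMatrix]) -> AccuracyReport:
    """Per-location accuracies plus their unweighted mean and the pooled accuracy.

    All percentages are rounded half-up to one decimal for reporting; the
    mean is taken over the *unrounded* per-location values before rounding.
    """
    if not matrices:
        raise InvalidInputError("no confusion matrices to summarize")
    exact = {loc: accuracy(cm) for loc, cm in matrices.items()}
    pooled = sum(matrices.values(), ConfusionMatrix(0, 0, 0, 0))
    return AccuracyReport(
        per_location={loc: round_half_up(a) for loc, a in exact.items()},
        mean_accuracy_percent=round_half_up(sum(exact.values()) / len(exact)),
        pooled_accuracy_percent=round_half_up(accuracy(pooled)),
    )


def report_to_frame(matrices: Mapping[str, ConfusionMatrix]) -> pd.DataFrame:
    """Tabular CSV-ready report: location, counts and accuracy per row."""
    rows = [
        {
            "location": loc,
            "tp": cm.tp,
            "fp": cm.fp,
            "fn": cm.fn,
            "tn": cm.tn,
            "accuracy_percent": round_half_up(accuracy(cm)),
        }
        for loc, cm in matrices.items()
    ]
    return pd.DataFrame(rows)


def load_field_confusion_counts() -> dict[str, dict[str, ConfusionMatrix]]:
    """Reference confusion counts from a UAV spray-area field study.

    Returns {"cropland": {"L1": cm, ...}, "orchard": {...}} for the three
    field locations; used to regression-test the accuracy arithmetic.
    """
    with resources.files("spraymsm.data").joinpath("field_confusion_counts.csv").open() as fh:
        df = pd.read_csv(fh)
    out: dict[str, dict[str, ConfusionMatrix]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.land, {})[row.location] = ConfusionMatrix(
            tp=row.tp, fp=row.fp, fn=row.fn, tn=row.tn
        )
    return out
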