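"""Confusion-matrix evaluation for the rare-class egg-fertility setting.

The positive class is the *non-fertile* egg: the minority (~1:13) class that a
hatchery-line rejector must catch.  All rates are percentages:

    TPR = TP / (TP + FN) * 100        (non-fertile recall)
    TNR = TN / (TN + FP) * 100        (fertile recall)
    FPR = FP / (FP + TN) * 100
    FNR = FN / (FN + TP) * 100
    OVA = (TP + TN) / n * 100         (overall accuracy)
    ERR = 100 - OVA

A rate whose denominator is zero is *undefined* (``None``), never silently 0:
single-class folds would otherwise corrupt monotonicity checks downstream.
Rates are kept at full precision; rounding (half-up, 2 decimals) happens only
at presentation time.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np

FERTILE = "fertile"
NONFERTILE = "non-fertile"
LABELS = frozenset({FERTILE, NONFERTILE})

#: numeric coding used when PLS regresses on the class: fertile eggs sit at
#: 1.0, non-fertile at 0.0 — the only coding under which a threshold grid of
#: 0.50–0.85 with the rule "score < TR => non-fertile" behaves sensibly.
CLASS_CODING = {FERTILE: 1.0, NONFERTILE: 0.0}


class EmptyInputError(ValueError):
    """All four confusion counts are zero."""


class LabelError(ValueError):
    """A label outside {fertile, non-fertile} was encountered."""


def round2(x: float) -> float:
    """Round half-up to 2 decimals (presentation only)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _fmt(rate: Optional[float]) -> str:
    return "undef" if rate is None else f"{round2(rate):.2f}"


@dataclass(frozen=True)
class ConfusionSummary:
    """Counts plus the five rates and the error rate.

    Undefined rates (zero denominator) are ``None``.  ``tpr``..``err`` are
    full-precision percentages in [0, 100].
    """

    tp: int
    fp: int
    tn: int
    fn: int
    tpr: Optional[float]
    tnr: Optional[float]
    fpr: Optional[float]
    fnr: Optional[float]
    ova: float
    err: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self, rounded: bool = True) -> dict:
        d = {"TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn}
        for key, val in (("TPR", self.tpr), ("TNR", self.tnr), ("FPR", self.fpr),
                         ("FNR", self.fnr), ("OVA", self.ova), ("ERR", self.err)):
            if val is None:
                d[key] = None
            else:
                d[key] = round2(val) if rounded else val
        return d

    def render(self) -> str:
        """Text rendering in the percent-with-fraction layout of the reports."""
        p = self.tp + self.fn
        f = self.tn + self.fp
        lines = [
            "                 Predicted        Predicted",
            "True class       non-fertile      fertile",
            f"non-fertile      {_fmt(self.tpr)} ({self.tp}/{p})"
            f"      {_fmt(self.fnr)} ({self.fn}/{p})",
            f"fertile          {_fmt(self.fpr)} ({self.fp}/{f})"
            f"      {_fmt(self.tnr)} ({self.tn}/{f})",
            f"OVA = {_fmt(self.ova)}%   ERR = {_fmt(self.err)}%",
        ]
        return "\n".join(lines)


def _check_labels(labels: Sequence[str], what: str) -> np.ndarray:
    arr = np.asarray(labels, dtype=object)
    bad = [str(v) for v in arr if v not in LABELS]
    if bad:
        raise LabelError(f"unknown {what} label(s): {sorted(set(bad))!r}; "
                         f"expected one of {sorted(LABELS)}")
    return arr


def confusion_counts(truth: Sequence[str], predicted: Sequence[str],
                     positive: str = NONFERTILE) -> tuple[int, int, int, int]:
    """Count (TP, FP, TN, FN) with the given positive class.

    Counts partition the sample: TP + FP + TN + FN == len(truth).
    """
    t = _check_labels(truth, "truth")
    p = _check_labels(predicted, "predicted")
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} truth vs {len(p)} predicted")
    if positive not in LABELS:
        raise LabelError(f"positive class {positive!r} not in {sorted(LABELS)}")
    tpos = t == positive
    ppos = p == positive
    tp = int(np.sum(tpos & ppos))
    fp = int(np.sum(~tpos & ppos))
    tn = int(np.sum(~tpos & ~ppos))
    fn = int(np.sum(tpos & ~ppos))
    return tp, fp, tn, fn


def rates(counts: tuple[int, int, int, int]) -> ConfusionSummary:
    """Compute the five rates plus ERR from (TP, FP, TN, FN)."""
    tp, fp, tn, fn = (int(c) for c in counts)
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    n = tp + fp + tn + fn
    if n == 0:
        raise EmptyInputError("all confusion counts are zero")

    def pct(num: int, den: int) -> Optional[float]:
        return None if den == 0 else 100.0 * num / den

    ova = 100.0 * (tp + tn) / n
    return ConfusionSummary(
        tp=tp, fp=fp, tn=tn, fn=fn,
        tpr=pct(tp, tp + fn),
        tnr=pct(tn, tn + fp),
        fpr=pct(fp, fp + tn),
        fnr=pct(fn, fn + tp),
        ova=ova,
        err=100.0 - ova,
    )


def evaluate(truth: Sequence[str], predicted: Sequence[str],
             positive: str = NONFERTILE) -> ConfusionSummary:
    """confusion_counts + rates in one call."""
    return rates(confusion_counts(truth, predicted, positive=positive))


def summaries_to_frame(rows: Iterable[dict]):
    """Flatten dicts of metadata + ConfusionSummary into a DataFrame."""
    import pandas as pd

    records = []
    for row in rows:
        rec = {k: v for k, v in row.items() if not isinstance(v, ConfusionSummary)}
        for v in row.values():
            if isinstance(v, ConfusionSummary):
                rec.update(v.as_dict())
        records.append(rec)
    return pd.DataFrame.from_records(records)
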