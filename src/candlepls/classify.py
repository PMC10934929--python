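"""Moving-threshold discrimination of continuous PLS outputs.

With fertile coded 1.0 and non-fertile 0.0, a score below the threshold TR is
called non-fertile; a score at or above TR (ties included) is called fertile.
TR therefore acts as a strict lower bound for the fertile call.  Raising TR
can only move calls from fertile to non-fertile, so TPR (non-fertile recall)
is non-decreasing and TNR non-increasing in TR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics
from .metrics import FERTILE, NONFERTILE, ConfusionSummary

#: the report grid: 0.50–0.85 in steps of 0.05, plus the distinguished 0.81
#: operating point
DEFAULT_TR_GRID = (0.50, 0.55, 0.60, 0.65, 0.70, 0.75, 0.80, 0.81, 0.85)


def classify_threshold(scores: Sequence[float], tr: float) -> np.ndarray:
    """Label each score: non-fertile if score < TR, else fertile."""
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(tr):
        raise ValueError(f"threshold must be finite, got {tr!r}")
    bad = np.flatnonzero(~np.isfinite(scores))
    if bad.size:
        raise ValueError(f"non-finite score(s) at sample index {bad.tolist()}")
    return np.where(scores < tr, NONFERTILE, FERTILE).astype(object)


@dataclass
class ThresholdSweepResult:
    """Per-threshold confusion summaries for one (day, A) model."""

    thresholds: tuple
    labels: list          # per-TR predicted label arrays
    summaries: list       # per-TR ConfusionSummary
    day: Optional[int] = None
    n_components: Optional[int] = None
    dataset_id: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def summary_at(self, tr: float) -> ConfusionSummary:
        for t, s in zip(self.thresholds, self.summaries):
            if t == tr:
                return s
        raise KeyError(f"threshold {tr} not in sweep grid {self.thresholds}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tr, s in zip(self.thresholds, self.summaries):
            row = {"day": self.day, "A": self.n_components, "TR": tr}
            row.update(s.as_dict())
            rows.append(row)
        return pd.DataFrame(rows)


def threshold_sweep(scores: Sequence[float], truth: Sequence[str],
                    thresholds: Sequence[float] = DEFAULT_TR_GRID,
                    *, positive: str = NONFERTILE,
                    day: Optional[int] = None,
                    n_components: Optional[int] = None,
                    dataset_id: Optional[str] = None) -> ThresholdSweepResult:
    """Classify at every TR in the grid and summarise each confusion matrix."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=object)
    if scores.shape[0] != truth.shape[0]:
        raise ValueError(f"{scores.shape[0]} scores vs {truth.shape[0]} truth labels")
    thresholds = tuple(float(t) for t in thresholds)
    if not thresholds:
        raise ValueError("threshold grid is empty")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError(f"thresholds must be strictly increasing, got {thresholds}")

    labels, summaries = [], []
    for tr in thresholds:
        pred = classify_threshold(scores, tr)
        labels.append(pred)
        summaries.append(metrics.evaluate(truth, pred, positive=positive))
    return ThresholdSweepResult(thresholds=thresholds, labels=labels,
                                summaries=summaries, day=day,
                                n_components=n_components, dataset_id=dataset_id)
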