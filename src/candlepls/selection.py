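"""Latent-component selection by full leave-one-out cross-validation.

Each candidate component count A on a grid (default 5, 10, ..., 50) is scored
by classifying the pooled out-of-fold LOO predictions at a fixed selection
threshold (default TR = 0.80) and reading off one confusion-matrix rate
(TPR, TNR or OVA).  The chosen A is the smallest grid member whose criterion
value reaches the grid maximum (within a tie tolerance) — a first-plateau
rule: adding components beyond the plateau buys nothing.

NIPALS components are nested, so each LOO fold is fitted once at the largest
grid value and every smaller candidate is read from the same fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics
from .classify import classify_threshold
from .metrics import ConfusionSummary
from .pls import DegenerateResponseError, encode_labels, fit_pls1, predict

DEFAULT_COMPONENT_GRID = tuple(range(5, 51, 5))
DEFAULT_SELECTION_TR = 0.80
CRITERIA = ("tpr", "tnr", "ova")


def _loo_multi(X: np.ndarray, y: np.ndarray, a_list: Sequence[int]) -> dict[int, np.ndarray]:
    """Out-of-fold LOO predictions for every component count in ``a_list``.

    One NIPALS fit per fold at max(a_list); nested coefficients give the rest.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    a_max = max(a_list)
    out = {a: np.empty(n) for a in a_list}
    for i in range(n):
        keep = np.arange(n) != i
        try:
            model = fit_pls1(X[keep], y[keep], a_max)
        except DegenerateResponseError as exc:
            raise DegenerateResponseError(f"LOO fold {i}: {exc}") from exc
        for a in a_list:
            # residual covariance can exhaust before a components; the
            # effective model is then the deepest available prefix
            out[a][i] = predict(model, X[i], a=min(a, model.A))[0]
    return out


def loo_cv_predictions(X: np.ndarray, y: Sequence, A: int) -> np.ndarray:
    """Length-n out-of-fold predictions: entry i comes from a model fitted
    without row i.  Deterministic; ``y`` may be labels or numeric."""
    y = np.asarray(y)
    y_num = encode_labels(y) if y.dtype.kind in "OUS" else y.astype(float)
    n, p = np.asarray(X).shape
    if n < 3:
        raise ValueError(f"LOO needs at least 3 samples, got {n}")
    if not 1 <= A <= min(n - 2, p):
        raise ValueError(f"A={A} outside 1..{min(n - 2, p)} for LOO with n={n}, p={p}")
    return _loo_multi(np.asarray(X, dtype=float), y_num, [A])[A]


@dataclass
class ComponentSweepResult:
    """LOO scores for each candidate component count, and the chosen one."""

    grid: tuple
    predictions: dict               # A -> out-of-fold score vector
    summaries: dict                 # A -> ConfusionSummary at selection TR
    chosen_A: int
    criterion: str
    selection_tr: float
    day: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def criterion_value(self, a: int) -> Optional[float]:
        return getattr(self.summaries[a], self.criterion)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.grid:
            row = {"A": a}
            row.update(self.summaries[a].as_dict())
            row["chosen"] = a == self.chosen_A
            rows.append(row)
        return pd.DataFrame(rows)


def sweep_components(spectra, grid: Sequence[int] = DEFAULT_COMPONENT_GRID,
                     tr: float = DEFAULT_SELECTION_TR, criterion: str = "tpr",
                     *, tie_tolerance: float = 0.0) -> ComponentSweepResult:
    """Score every component count on ``grid`` by LOO at threshold ``tr``.

    Parameters
    ----------
    spectra : SpectrumSet (or any object with ``X`` and ``y`` attributes).
    criterion : "tpr", "tnr" or "ova" — the rate that ranks candidates.
    tie_tolerance : a candidate within this many percentage points of the
        grid maximum counts as attaining it; chosen_A is the smallest such.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"criterion {criterion!r} not in {CRITERIA}")
    grid = tuple(int(a) for a in grid)
    if not grid:
        raise ValueError("component grid is empty")
    X = np.asarray(spectra.X, dtype=float)
    truth = np.asarray(spectra.y, dtype=object)
    n, p = X.shape
    a_bound = min(n - 2, p)
    bad = [a for a in grid if not 1 <= a <= a_bound]
    if bad:
        raise ValueError(f"component count(s) {bad} outside 1..{a_bound} for n={n}, p={p}")
    if len(set(truth)) < 2:
        raise ValueError("component selection needs both classes present")

    y_num = encode_labels(truth)
    preds = _loo_multi(X, y_num, sorted(set(grid)))
    summaries: dict[int, ConfusionSummary] = {}
    for a in grid:
        pred_labels = classify_threshold(preds[a], tr)
        summaries[a] = metrics.evaluate(truth, pred_labels)

    values = {a: summaries[a] for a in grid}
    crit = {a: getattr(values[a], criterion) for a in grid}
    defined = {a: v for a, v in crit.items() if v is not None}
    if not defined:
        raise ValueError(f"criterion {criterion!r} undefined for every grid member")
    best = max(defined.values())
    chosen = min(a for a, v in defined.items() if v >= best - tie_tolerance)

    day = getattr(spectra, "day", None)
    return ComponentSweepResult(grid=grid, predictions={a: preds[a] for a in grid},
                                summaries=summaries, chosen_A=chosen,
                                criterion=criterion, selection_tr=tr, day=day)
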