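"""End-to-end orchestration: spectra -> component selection -> threshold sweep.

Days are modelled independently (one PLS model per day); nothing is pooled
across incubation days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .classify import DEFAULT_TR_GRID, ThresholdSweepResult, threshold_sweep
from .hypercube import SpectrumSet
from .selection import (DEFAULT_COMPONENT_GRID, DEFAULT_SELECTION_TR,
                        ComponentSweepResult, sweep_components)

log = logging.getLogger(__name__)


@dataclass
class DayResult:
    """Component sweep plus threshold sweep at the chosen component count."""

    spectra: SpectrumSet
    components: ComponentSweepResult
    thresholds: ThresholdSweepResult

    @property
    def chosen_A(self) -> int:
        return self.components.chosen_A


def run_day(spectra: SpectrumSet,
            component_grid: Sequence[int] = DEFAULT_COMPONENT_GRID,
            selection_tr: float = DEFAULT_SELECTION_TR,
            tr_grid: Sequence[float] = DEFAULT_TR_GRID,
            criterion: str = "tpr",
            positive: str = "non-fertile") -> DayResult:
    """Select the component count by LOO CV, then sweep the decision threshold.

    The threshold sweep reuses the chosen model's out-of-fold LOO predictions,
    so every reported rate is cross-validated.
    """
    comp = sweep_components(spectra, grid=component_grid, tr=selection_tr,
                            criterion=criterion)
    scores = comp.predictions[comp.chosen_A]
    sweep = threshold_sweep(scores, spectra.y, thresholds=tr_grid,
                            positive=positive, day=spectra.day,
                            n_components=comp.chosen_A)
    for tr, s in zip(sweep.thresholds, sweep.summaries):
        log.info("day=%s A=%d TR=%.2f TP=%d FP=%d TN=%d FN=%d",
                 spectra.day, comp.chosen_A, tr, s.tp, s.fp, s.tn, s.fn)
    return DayResult(spectra=spectra, components=comp, thresholds=sweep)
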