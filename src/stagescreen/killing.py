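"""NK-cytotoxicity coculture quantification and cross-plate normalization.

Senescent target cells are seeded, a time-0 plate is counted, NK effector
cells are added at a chosen effector-to-target (E:T) ratio, and after the
coculture period (typically 48 h; 24 h for OVCAR4) nuclei are counted
again.  Killing is quantified as the percentage change in target-cell
counts over the coculture; NPA against each plate's own non-targeting
(negative) and killing-enhancer (positive) control wells makes the readout
comparable across plates, batches and replicates.  Because the positive
control loses more cells than the negative control, the plain NPA formula
already maps stronger killing to larger scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalization import ControlSummary, NPAScorer, npa

__all__ = [
    "CocultureResult",
    "percent_change",
    "effectors_needed",
    "nk_specific_effect",
    "normalize_killing",
]


@dataclass
class CocultureResult:
    """Target-cell counts for one coculture well."""

    condition_id: str
    count_t0: float
    count_end: float
    effector_ratio: float  # E:T; 0 = no-NK control arm

    def __post_init__(self) -> None:
        if self.count_t0 < 0 or self.count_end < 0 or self.effector_ratio < 0:
            raise ValueError("counts and E:T ratio must be non-negative")

    @property
    def percent_change(self) -> float:
        return percent_change(self.count_t0, self.count_end)


def percent_change(count_t0: float, count_end: float) -> float:
    """Percent change in target-cell counts over the coculture period.

    100 x (end - t0) / t0, against the separately fixed time-0 plate count;
    -100 means complete loss, positive values mean net growth.
    """
    if count_t0 <= 0:
        raise ValueError("time-0 count must be positive")
    if count_end < 0:
        raise ValueError("end-point count must be non-negative")
    return 100.0 * (count_end - count_t0) / count_t0


def effectors_needed(count_t0: float, et_ratio: float) -> float:
    """Effector cells to seed for a target count at a given E:T ratio."""
    if count_t0 <= 0 or et_ratio <= 0:
        raise ValueError("time-0 count and E:T ratio must be positive")
    return et_ratio * count_t0


def nk_specific_effect(change_with_nk: float, change_without_nk: float) -> float:
    """Difference of percent changes with vs without effectors.

    Negative values indicate NK-specific target-cell loss, separating
    killing from any cell-intrinsic (senolytic) effect of a perturbation.
    """
    if not (np.isfinite(change_with_nk) and np.isfinite(change_without_nk)):
        raise ValueError("percent changes must be finite")
    return change_with_nk - change_without_nk


def normalize_killing(
    percent_changes: pd.DataFrame, controls: ControlSummary | None = None
) -> pd.DataFrame:
    """NPA-normalize per-well killing percent changes against plate controls.

    ``percent_changes`` is a tidy well table (channel ``KILLING``, ``value``
    = percent change) whose plates each carry their own negative
    (non-targeting siRNA + NK) and positive (designated enhancer + NK)
    control wells; each plate/replicate is anchored on its own controls.
    Passing an explicit :class:`ControlSummary` instead applies it to every
    well (single-plate convenience).  Returns the table with an ``npa``
    column; larger NPA = stronger killing.
    """
    if controls is not None:
        out = percent_changes.copy()
        out["npa"] = [npa(v, controls) for v in out["value"]]
        return out
    scorer = NPAScorer(per_plate=True, clip=False)
    return scorer.fit(percent_changes).transform(percent_changes)
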