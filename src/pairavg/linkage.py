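"""Linking unit-level to pattern-level averaging.

Units are classified by their within-unit pair-vs-sum regression slope as
*near* perfect averaging (slope in the closed interval [0.45, 0.55]) or
*far* from it; the pattern-averaging statistics are then computed within
each group.  A population in which most units are near averaging should show
pattern-level averaging, while a population with the same mean slope but a
wide slope distribution need not — the dissociation this analysis exposes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ResponseDataset
from .design import ConditionTable
from .patterns import PatternMode, PatternResult, noiseless_pattern_averaging, split_half_pattern_ratio

logger = logging.getLogger(__name__)

NEAR, FAR, UNDEFINED = "near", "far", "undefined"

#: Fewer units than this in a group leaves its pattern statistic undefined.
MIN_GROUP_UNITS = 3


@dataclass(frozen=True)
class SlopeClassification:
    labels: np.ndarray  # "near" / "far" / "undefined" per unit
    proportion_near: float  # over units with a defined slope
    lo: float
    hi: float

    @property
    def n_near(self) -> int:
        return int((self.labels == NEAR).sum())

    @property
    def n_far(self) -> int:
        return int((self.labels == FAR).sum())

    @property
    def n_defined(self) -> int:
        return self.n_near + self.n_far

    def to_frame(self, unit_ids: np.ndarray, slopes: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame({"unit": unit_ids, "slope": slopes, "label": self.labels})


@dataclass(frozen=True)
class SlopeGroupResult:
    classification: SlopeClassification
    pattern_near: PatternResult | None
    pattern_far: PatternResult | None
    pattern_all: PatternResult


def classify_units(
    slopes: np.ndarray, lo: float = 0.45, hi: float = 0.55
) -> SlopeClassification:
    """Label each unit near/far by its per-unit slope.

    ``near`` is the closed interval [lo, hi] (the far group is defined
    strictly: slope < lo or slope > hi); NaN slopes are ``undefined`` and
    excluded from the proportion.
    """
    if not lo < hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    slopes = np.asarray(slopes, dtype=float)
    labels = np.full(slopes.shape, UNDEFINED, dtype=object)
    defined = ~np.isnan(slopes)
    near = defined & (slopes >= lo) & (slopes <= hi)
    far = defined & ~near
    labels[near] = NEAR
    labels[far] = FAR
    n_defined = int(defined.sum())
    prop = float(near.sum() / n_defined) if n_defined else float("nan")
    return SlopeClassification(labels=labels.astype(str), proportion_near=prop, lo=lo, hi=hi)


def pooled_proportion_near(classifications: list[SlopeClassification]) -> float:
    """Proportion of near units pooled over subjects (unit-weighted)."""
    n_near = sum(c.n_near for c in classifications)
    n_defined = sum(c.n_defined for c in classifications)
    return float(n_near / n_defined) if n_defined else float("nan")


def groupwise_pattern_averaging(
    data,
    table: ConditionTable | None = None,
    classification: SlopeClassification | None = None,
    mode: PatternMode = "split_half",
    *,
    weights=(0.5, 0.5),
    unit_mask: np.ndarray | None = None,
    **kwargs,
) -> SlopeGroupResult:
    """Pattern-averaging statistics within the near and far slope groups.

    ``data`` is a ResponseDataset (split-half mode) or a unit x condition
    mean matrix with ``table`` (noiseless mode).  Group restriction composes
    with an optional ``unit_mask`` (e.g. the responsiveness mask).  Groups
    with fewer than three units are reported as undefined.
    """
    if classification is None:
        raise ValueError("a SlopeClassification is required")
    if isinstance(data, ResponseDataset):
        n_units = data.n_units
        table = data.table
    else:
        if table is None:
            raise ValueError("noiseless mode requires a condition table")
        n_units = np.asarray(data).shape[0]
    if classification.labels.shape[0] != n_units:
        raise ValueError("classification length must match the unit axis")
    base = np.ones(n_units, dtype=bool) if unit_mask is None else np.asarray(unit_mask, bool)

    def run(mask: np.ndarray) -> PatternResult | None:
        if mask.sum() < MIN_GROUP_UNITS:
            logger.warning("pattern statistic undefined for a group of %d unit(s)",
                           int(mask.sum()))
            return None
        if mode == "split_half":
            return split_half_pattern_ratio(data, weights, unit_mask=mask, **kwargs)
        return noiseless_pattern_averaging(data, table, weights, unit_mask=mask)

    near_mask = base & (classification.labels == NEAR)
    far_mask = base & (classification.labels == FAR)
    pattern_all = run(base)
    if pattern_all is None:
        raise ValueError("too few units for the all-units pattern statistic")
    return SlopeGroupResult(
        classification=classification,
        pattern_near=run(near_mask),
        pattern_far=run(far_mask),
        pattern_all=pattern_all,
    )
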