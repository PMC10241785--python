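"""Unit-level averaging analysis.

The core statistic is the slope of the ordinary-least-squares line relating a
unit's response to an object pair to its *summed* response to the two
constituent objects shown alone.  A slope of 0.5 is perfect averaging; 1.0 is
summation; 0.55 is the reference value reported for single neurons in
macaque inferotemporal cortex.

Two granularities are provided:

* ``population_slope`` — one point per unit (pair response and summed-single
  response each averaged over all pairs first), one regression across units;
  this is the subject-level statistic.
* ``per_unit_slopes`` — one regression per unit across its pair conditions;
  feeds the near/far linkage analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ResponseDataset
from .design import BOTTOM, TOP, ConditionTable, constituent_indices, singles_by_location

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SlopeResult:
    population_slope: float
    population_intercept: float
    per_unit_slope: np.ndarray  # NaN where undefined / excluded
    n_units_used: int
    summed_single_mean: np.ndarray  # per unit, NaN where excluded
    pair_mean: np.ndarray  # per unit, NaN where excluded

    def scatter_frame(self, unit_ids: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit": unit_ids,
                "summed_single_mean": self.summed_single_mean,
                "pair_mean": self.pair_mean,
                "per_unit_slope": self.per_unit_slope,
            }
        )


def condition_means(dataset: ResponseDataset) -> np.ndarray:
    """Per-unit, per-condition mean response (mean over runs; identity for
    run-free activation matrices)."""
    if dataset.has_runs:
        return dataset.values.mean(axis=2)
    return dataset.values


def responsive_unit_mask(means: np.ndarray, table: ConditionTable) -> np.ndarray:
    """True for units responsive to objects at both locations.

    A unit qualifies iff its responses vary (non-zero variance) across the
    single-object conditions at the top location *and* across those at the
    bottom location.  Dead or location-silent units carry no pair-combination
    information and are excluded from the slope analyses.
    """
    by_loc = singles_by_location(table)
    if TOP not in by_loc or BOTTOM not in by_loc:
        raise ValueError("responsiveness mask requires a two-location design")
    var_top = means[:, by_loc[TOP]].var(axis=1)
    var_bottom = means[:, by_loc[BOTTOM]].var(axis=1)
    return (var_top > 0) & (var_bottom > 0)


def _pair_points(means: np.ndarray, table: ConditionTable) -> tuple[np.ndarray, np.ndarray]:
    """Per (unit, pair): summed constituent response and pair response."""
    pair_idx, top_idx, bottom_idx = constituent_indices(table)
    if pair_idx.size == 0:
        raise ValueError("the design has no pair conditions")
    summed = means[:, top_idx] + means[:, bottom_idx]
    paired = means[:, pair_idx]
    return summed, paired


def population_slope(
    means: np.ndarray,
    table: ConditionTable,
    unit_mask: np.ndarray | None = None,
) -> SlopeResult:
    """Across-unit regression of mean pair response on mean summed response.

    Each included unit contributes one point: its pair response and its
    summed constituent response, both averaged over all pair conditions.  An
    affine OLS line is fitted across units; the intercept is reported rather
    than forced to zero.
    """
    summed, paired = _pair_points(means, table)
    x = summed.mean(axis=1)
    y = paired.mean(axis=1)
    if unit_mask is None:
        unit_mask = np.ones(means.shape[0], dtype=bool)
    unit_mask = np.asarray(unit_mask, dtype=bool)
    xs, ys = x[unit_mask], y[unit_mask]
    if xs.size < 2 or np.ptp(xs) == 0:
        raise ValueError(
            f"population slope needs >= 2 included units with distinct summed responses "
            f"(got {xs.size} units, abscissa range {np.ptp(xs) if xs.size else 0:g})"
        )
    fit = stats.linregress(xs, ys)

    slopes = per_unit_slopes(means, table, unit_mask)
    x_out = np.where(unit_mask, x, np.nan)
    y_out = np.where(unit_mask, y, np.nan)
    return SlopeResult(
        population_slope=float(fit.slope),
        population_intercept=float(fit.intercept),
        per_unit_slope=slopes,
        n_units_used=int(unit_mask.sum()),
        summed_single_mean=x_out,
        pair_mean=y_out,
    )


def per_unit_slopes(
    means: np.ndarray,
    table: ConditionTable,
    unit_mask: np.ndarray | None = None,
) -> np.ndarray:
    """OLS slope across pair conditions, computed within each unit.

    For each unit the abscissae are the pair-wise summed constituent
    responses and the ordinates the pair responses.  Units with a degenerate
    abscissa (all pairs summing to the same value) or outside ``unit_mask``
    get NaN.
    """
    summed, paired = _pair_points(means, table)
    if unit_mask is None:
        unit_mask = np.ones(means.shape[0], dtype=bool)
    unit_mask = np.asarray(unit_mask, dtype=bool)

    xc = summed - summed.mean(axis=1, keepdims=True)
    yc = paired - paired.mean(axis=1, keepdims=True)
    sxx = (xc**2).sum(axis=1)
    sxy = (xc * yc).sum(axis=1)
    ok = unit_mask & (sxx > 0)
    slopes = np.full(means.shape[0], np.nan)
    slopes[ok] = sxy[ok] / sxx[ok]
    n_degenerate = int((unit_mask & ~ok).sum())
    if n_degenerate:
        logger.warning("per-unit slope undefined for %d unit(s) with degenerate abscissae",
                       n_degenerate)
    return slopes
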