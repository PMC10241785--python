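"""Split-half reliability and reliability-based unit selection.

A unit's reliability is the Pearson correlation, across conditions, between
its condition-mean profile in the odd runs (1, 3, 5, ... in 1-based
numbering) and in the even runs.  Selecting a fixed number of the most
reliable units equates unit counts across subjects; the downstream analyses
run unchanged on the full or selected dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ResponseDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReliabilityResult:
    per_unit_r: np.ndarray  # NaN where undefined
    selected_units: np.ndarray  # unit ids, in original dataset order
    n_requested: int

    def to_frame(self, unit_ids: np.ndarray) -> pd.DataFrame:
        selected = np.isin(unit_ids, self.selected_units)
        return pd.DataFrame({"unit": unit_ids, "r": self.per_unit_r, "selected": selected})


def split_half_means(dataset: ResponseDataset) -> tuple[np.ndarray, np.ndarray]:
    """Condition-mean matrices for the odd and even halves of the runs.

    Runs are numbered 1-based: the odd half holds runs 1, 3, 5, ... (array
    indices 0, 2, 4, ...) and the even half runs 2, 4, 6, ....
    """
    if not dataset.has_runs or dataset.n_runs < 2:
        raise ValueError("split-half requires a run axis with at least 2 runs")
    odd = dataset.values[:, :, 0::2].mean(axis=2)
    even = dataset.values[:, :, 1::2].mean(axis=2)
    return odd, even


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between matching rows of two matrices; NaN where a row is
    constant in either input."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((a**2).sum(axis=1))
    sb = np.sqrt((b**2).sum(axis=1))
    ok = (sa > 0) & (sb > 0)
    r = np.full(a.shape[0], np.nan)
    r[ok] = (a[ok] * b[ok]).sum(axis=1) / (sa[ok] * sb[ok])
    return r


def unit_reliability(dataset: ResponseDataset) -> np.ndarray:
    """Per-unit split-half reliability across all conditions.

    Returns NaN for units whose profile is constant in either half (no
    condition information); such units are excluded from selection.
    """
    if len(dataset.table) < 3:
        raise ValueError("reliability needs at least 3 conditions")
    odd, even = split_half_means(dataset)
    r = _rowwise_pearson(odd, even)
    n_bad = int(np.isnan(r).sum())
    if n_bad:
        logger.warning("reliability undefined for %d unit(s) with a constant half-profile", n_bad)
    return r


def select_top_units(
    dataset: ResponseDataset, n: int, return_result: bool = False
):
    """Retain the ``n`` units with the highest split-half reliability.

    Ties are broken by original unit order (stable sort); units with
    undefined reliability are never selected.  If fewer than ``n`` units have
    a defined reliability, all of those are retained.  The retained units
    keep their original relative order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    r = unit_reliability(dataset)
    defined = np.flatnonzero(~np.isnan(r))
    # stable sort on negated r keeps original order within ties
    order = defined[np.argsort(-r[defined], kind="stable")]
    keep = np.sort(order[: min(n, order.size)])
    subset = dataset.subset_units(keep)
    if not return_result:
        return subset
    result = ReliabilityResult(
        per_unit_r=r, selected_units=dataset.unit_ids[keep], n_requested=n
    )
    return subset, result
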