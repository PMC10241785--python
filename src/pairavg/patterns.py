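"""Population-pattern averaging statistics.

For measured (noisy, run-resolved) data the analysis is split-half and
noise-normalized: z-score each condition's pattern within each run, average
the odd and the even runs separately, then per pair compute

* actual pair correlation   — the pair pattern correlated with itself across
  the two halves (the attainable ceiling given measurement noise), and
* averaged pair correlation — the pair pattern in one half correlated with
  the weighted average of its constituents' single-object patterns in the
  other half (both cross directions, averaged).

Their ratio is the noise-normalized correlation: 1 means the pair pattern is
predicted by averaging the single-object patterns as well as by itself.

For noiseless activation matrices there is no run axis and no ceiling; the
pair pattern is simply correlated with the weighted average of the
constituent patterns.

A weighted-average sweep evaluates either statistic on a grid of top-object
weights from 0 to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

from .dataset import ResponseDataset
from .design import ConditionTable, constituent_indices
from .reliability import split_half_means

logger = logging.getLogger(__name__)

PatternMode = Literal["split_half", "noiseless"]

#: Pairs whose actual (ceiling) correlation falls at or below this value have
#: a meaningless ratio and are excluded from the subject mean.
DEFAULT_ACTUAL_R_THRESHOLD = 0.05


@dataclass(frozen=True)
class PatternResult:
    pair_ids: tuple[str, ...]
    averaged_r: np.ndarray
    weights: tuple[float, float]
    mode: PatternMode
    actual_r: np.ndarray | None = None  # split_half only
    ratio: np.ndarray | None = None  # split_half only; NaN where invalid
    mean_ratio: float | None = None  # mean of per-pair ratios over valid pairs
    ratio_of_means: float | None = None  # mean averaged_r / mean actual_r

    @property
    def mean_averaged_r(self) -> float:
        return float(np.nanmean(self.averaged_r))

    @property
    def score(self) -> float:
        """Headline statistic: mean ratio (split-half) or mean correlation
        (noiseless)."""
        if self.mode == "split_half":
            assert self.mean_ratio is not None
            return self.mean_ratio
        return self.mean_averaged_r

    def to_frame(self) -> pd.DataFrame:
        data = {"pair": list(self.pair_ids), "averaged_r": self.averaged_r}
        if self.actual_r is not None:
            data["actual_r"] = self.actual_r
        if self.ratio is not None:
            data["ratio"] = self.ratio
        return pd.DataFrame(data)


@dataclass(frozen=True)
class WeightSweepResult:
    weights: np.ndarray  # top-object weight grid
    scores: np.ndarray
    argmax_weight: float
    mode: PatternMode

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"weight_top": self.weights, "score": self.scores})


def znormalize(dataset: ResponseDataset, ddof: int = 1) -> ResponseDataset:
    """Z-score each condition's (and run's) pattern across units.

    Every (condition, run) slice — or (condition,) slice for run-free data —
    is shifted to mean 0 and scaled to SD 1 across units, removing amplitude
    differences between conditions and runs.  Sample SD (ddof=1) by default.
    """
    if dataset.n_units < 2:
        raise ValueError("z-normalization needs at least 2 units")
    v = dataset.values
    mean = v.mean(axis=0, keepdims=True)
    sd = v.std(axis=0, ddof=ddof, keepdims=True)
    bad = np.nonzero(~(sd > 0))
    if bad[0].size:
        cond_i = int(bad[1][0])
        where = f"condition {dataset.table.ids[cond_i]!r}"
        if v.ndim == 3:
            where += f", run {int(bad[2][0]) + 1}"
        raise ValueError(f"cannot z-normalize a constant pattern ({where})")
    return replace(dataset, values=(v - mean) / sd)


def pattern_correlation(p: np.ndarray, q: np.ndarray) -> float:
    """Pearson correlation between two response patterns over units."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("patterns must be 1-D vectors of equal length")
    if p.size < 3:
        raise ValueError("pattern correlation needs at least 3 units")
    pc = p - p.mean()
    qc = q - q.mean()
    sp = np.sqrt((pc**2).sum())
    sq = np.sqrt((qc**2).sum())
    if sp == 0 or sq == 0:
        raise ValueError("pattern correlation is undefined for a constant pattern")
    return float((pc * qc).sum() / (sp * sq))


def _as_weights(weights) -> tuple[float, float]:
    if np.isscalar(weights):
        w_top = float(weights)
        weights = (w_top, 1.0 - w_top)
    w_top, w_bottom = (float(w) for w in weights)
    if not (0.0 <= w_top <= 1.0 and 0.0 <= w_bottom <= 1.0):
        raise ValueError("weights must lie in [0, 1]")
    if abs(w_top + w_bottom - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    return w_top, w_bottom


def _mask_rows(mat: np.ndarray, unit_mask: np.ndarray | None) -> np.ndarray:
    if unit_mask is None:
        return mat
    unit_mask = np.asarray(unit_mask, dtype=bool)
    return mat[unit_mask]


def split_half_pattern_ratio(
    dataset: ResponseDataset,
    weights=(0.5, 0.5),
    *,
    normalize: bool = True,
    actual_r_threshold: float = DEFAULT_ACTUAL_R_THRESHOLD,
    fisher_z: bool = False,
    unit_mask: np.ndarray | None = None,
) -> PatternResult:
    """Noise-normalized pattern-averaging statistic for run-resolved data.

    Z-normalization is applied first (disable only for data normalized
    upstream), then runs are split into odd and even halves and averaged
    within each half.  The averaged-pair correlation uses both cross
    directions (pair-odd vs singles-even and pair-even vs singles-odd) and
    averages the two r values — arithmetically by default, via Fisher z with
    ``fisher_z=True``.

    Pairs whose actual correlation is at or below ``actual_r_threshold`` get
    a NaN ratio and are excluded from ``mean_ratio``.
    """
    w_top, w_bottom = _as_weights(weights)
    if normalize:
        dataset = znormalize(dataset)
    odd, even = split_half_means(dataset)
    odd = _mask_rows(odd, unit_mask)
    even = _mask_rows(even, unit_mask)

    table = dataset.table
    pair_idx, top_idx, bottom_idx = constituent_indices(table)
    pair_ids = tuple(c.id for c in table.pairs)

    n_pairs = pair_idx.size
    actual = np.empty(n_pairs)
    averaged = np.empty(n_pairs)
    for k in range(n_pairs):
        p_o, p_e = odd[:, pair_idx[k]], even[:, pair_idx[k]]
        avg_o = w_top * odd[:, top_idx[k]] + w_bottom * odd[:, bottom_idx[k]]
        avg_e = w_top * even[:, top_idx[k]] + w_bottom * even[:, bottom_idx[k]]
        actual[k] = pattern_correlation(p_o, p_e)
        r1 = pattern_correlation(p_o, avg_e)
        r2 = pattern_correlation(p_e, avg_o)
        if fisher_z:
            averaged[k] = float(np.tanh(0.5 * (np.arctanh(r1) + np.arctanh(r2))))
        else:
            averaged[k] = 0.5 * (r1 + r2)

    valid = actual > actual_r_threshold
    if not valid.all():
        logger.warning(
            "excluding %d pair(s) with actual r <= %.3g from the noise-normalized mean",
            int((~valid).sum()), actual_r_threshold,
        )
    ratio = np.where(valid, averaged / np.where(valid, actual, 1.0), np.nan)
    mean_ratio = float(np.nanmean(ratio)) if valid.any() else float("nan")
    ratio_of_means = (
        float(averaged[valid].mean() / actual[valid].mean()) if valid.any() else float("nan")
    )
    return PatternResult(
        pair_ids=pair_ids,
        averaged_r=averaged,
        actual_r=actual,
        ratio=ratio,
        mean_ratio=mean_ratio,
        ratio_of_means=ratio_of_means,
        weights=(w_top, w_bottom),
        mode="split_half",
    )


def noiseless_pattern_averaging(
    means: np.ndarray,
    table: ConditionTable,
    weights=(0.5, 0.5),
    unit_mask: np.ndarray | None = None,
) -> PatternResult:
    """Pattern-averaging correlation for noiseless activation matrices.

    Per pair: Pearson correlation between the pair's pattern and the weighted
    average of its constituents' patterns.  No noise ceiling exists, so no
    ratio is formed.
    """
    w_top, w_bottom = _as_weights(weights)
    means = _mask_rows(np.asarray(means, dtype=float), unit_mask)
    pair_idx, top_idx, bottom_idx = constituent_indices(table)
    pair_ids = tuple(c.id for c in table.pairs)
    averaged = np.empty(pair_idx.size)
    for k in range(pair_idx.size):
        pred = w_top * means[:, top_idx[k]] + w_bottom * means[:, bottom_idx[k]]
        averaged[k] = pattern_correlation(means[:, pair_idx[k]], pred)
    return PatternResult(
        pair_ids=pair_ids, averaged_r=averaged, weights=(w_top, w_bottom), mode="noiseless"
    )


def weight_sweep(
    data,
    table: ConditionTable | None = None,
    mode: PatternMode = "split_half",
    *,
    step: float = 0.1,
    score: Literal["ratio", "averaged_r"] = "ratio",
    unit_mask: np.ndarray | None = None,
    **kwargs,
) -> WeightSweepResult:
    """Evaluate the pattern statistic on a grid of top-object weights.

    ``data`` is a ResponseDataset in split-half mode or a unit x condition
    mean matrix (with ``table``) in noiseless mode.  The grid runs from 0 to
    1 in steps of ``step`` (default 0.1, i.e. 11 points).  Ties at the
    maximum resolve to the weight closest to 0.5, then to the smaller weight.
    In split-half mode the score is the noise-normalized mean ratio by
    default; ``score="averaged_r"`` uses the raw averaged-pair correlation.
    """
    n_steps = round(1.0 / step)
    if not np.isclose(n_steps * step, 1.0) or n_steps < 1:
        raise ValueError("step must evenly divide the [0, 1] weight range")
    grid = np.linspace(0.0, 1.0, n_steps + 1)

    scores = np.empty(grid.size)
    for i, w in enumerate(grid):
        if mode == "split_half":
            if not isinstance(data, ResponseDataset):
                raise TypeError("split_half mode requires a ResponseDataset")
            res = split_half_pattern_ratio(data, w, unit_mask=unit_mask, **kwargs)
            scores[i] = res.mean_ratio if score == "ratio" else res.mean_averaged_r
        elif mode == "noiseless":
            if table is None:
                raise ValueError("noiseless mode requires a condition table")
            res = noiseless_pattern_averaging(data, table, w, unit_mask=unit_mask)
            scores[i] = res.mean_averaged_r
        else:
            raise ValueError(f"unknown mode {mode!r}")

    best = np.flatnonzero(np.isclose(scores, np.nanmax(scores), rtol=0, atol=1e-12))
    # ties: closest to 0.5, then the smaller weight
    best = sorted(best, key=lambda i: (abs(grid[i] - 0.5), grid[i]))
    return WeightSweepResult(
        weights=grid, scores=scores, argmax_weight=float(grid[best[0]]), mode=mode
    )
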