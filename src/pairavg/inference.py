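"""Group-level statistics: t-tests, BH correction, effect sizes, CIs.

All subject-level statistics are compared at the group level with one-sample
or paired t-tests (one-tailed where only one direction is meaningful),
corrected within explicit comparison families by the Benjamini-Hochberg
step-up procedure, and reported with Cohen's d (mean difference over the SD
of the tested values) and the between-subject 95% confidence interval of
the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import stats

Tail = Literal["two", "greater", "less"]

_SCIPY_ALT = {"two": "two-sided", "greater": "greater", "less": "less"}


@dataclass(frozen=True)
class StatTest:
    name: str
    t: float
    df: int
    p_raw: float
    tail: Tail
    d: float
    ci95: tuple[float, float]
    family_id: str = ""
    p_adjusted: float | None = None

    def to_record(self) -> dict:
        return {
            "analysis": self.name,
            "family": self.family_id,
            "t": self.t,
            "df": self.df,
            "p_raw": self.p_raw,
            "p_adj": self.p_adjusted,
            "tail": self.tail,
            "d": self.d,
            "ci_lo": self.ci95[0],
            "ci_hi": self.ci95[1],
        }


def between_subject_ci(values: np.ndarray, confidence: float = 0.95) -> tuple[float, float]:
    """Between-subject confidence interval of the mean: mean +/- t * SEM."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("confidence interval needs n >= 2")
    if np.ptp(values) == 0:  # exactly constant: zero-width interval
        return (float(values[0]), float(values[0]))
    m = values.mean()
    sem = values.std(ddof=1) / np.sqrt(n)
    half = stats.t.ppf(0.5 + confidence / 2, n - 1) * sem
    return (float(m - half), float(m + half))


def one_sample_t(
    values: np.ndarray,
    mu: float = 0.0,
    tail: Tail = "two",
    name: str = "",
    family_id: str = "",
) -> StatTest:
    """One-sample t-test of ``values`` against ``mu``.

    ``tail="greater"`` tests mean > mu, ``"less"`` tests mean < mu.  Cohen's
    d is (mean - mu) / sd.  The CI is always the two-sided 95% interval of
    the mean, independent of the test tail.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("t-test needs n >= 2")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("t-test is degenerate for a zero-variance sample")
    res = stats.ttest_1samp(values, mu, alternative=_SCIPY_ALT[tail])
    d = float((values.mean() - mu) / sd)
    return StatTest(
        name=name,
        t=float(res.statistic),
        df=int(values.size - 1),
        p_raw=float(res.pvalue),
        tail=tail,
        d=d,
        ci95=between_subject_ci(values),
        family_id=family_id,
    )


def paired_t(
    a: np.ndarray,
    b: np.ndarray,
    tail: Tail = "two",
    name: str = "",
    family_id: str = "",
) -> StatTest:
    """Paired t-test: one-sample test of the differences against 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(a - b, 0.0, tail, name=name, family_id=family_id)


def bh_adjust(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` is the size of the comparison family, which may exceed the number
    of p-values supplied (the remaining family members are tested
    elsewhere); it defaults to ``len(p)``.  Adjusted values are
    ``p * m / rank`` with monotonicity enforced from the largest p downward,
    capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if m is None:
        m = n
    if m < n:
        raise ValueError(f"family size m={m} cannot be smaller than the {n} supplied p-values")
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def adjust_families(tests: list[StatTest], family_sizes: dict[str, int] | None = None) -> list[StatTest]:
    """Apply BH correction within each test family.

    ``family_sizes`` may declare a family size larger than the number of
    tests carried here (when part of the family lives in another analysis).
    Tests with an empty family id are adjusted alone (m = 1 each).
    """
    family_sizes = family_sizes or {}
    by_family: dict[str, list[int]] = {}
    for i, t in enumerate(tests):
        by_family.setdefault(t.family_id, []).append(i)
    out = list(tests)
    for fam, idx in by_family.items():
        if fam == "":
            for i in idx:
                out[i] = replace(out[i], p_adjusted=float(out[i].p_raw))
            continue
        p = np.array([tests[i].p_raw for i in idx])
        adj = bh_adjust(p, m=family_sizes.get(fam))
        for i, a in zip(idx, adj):
            out[i] = replace(out[i], p_adjusted=float(a))
    return out
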