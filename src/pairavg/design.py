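"""Stimulus-condition space for single-object and object-pair designs.

The experimental design places one object category at each of up to two
vertical locations (top / bottom of fixation).  Single-object conditions show
one category at one location; pair conditions show two *distinct* categories,
one at each location.  With ``k`` categories and two locations this yields
``2k`` single conditions and ``k(k-1)`` ordered pair conditions (the same two
categories in swapped locations are distinct conditions), e.g. 8 singles and
12 pairs for the canonical four-category design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

TOP = "top"
BOTTOM = "bottom"

#: Category labels of the canonical four-category design; designs with more
#: categories fall back to generated ``cat<i>`` labels.
DEFAULT_CATEGORIES: tuple[str, ...] = ("bicycle", "couch", "guitar", "shoe")

Kind = Literal["single", "pair"]


class UnsupportedDesignError(ValueError):
    """Raised for condition-space parameters outside the supported design."""


@dataclass(frozen=True)
class Condition:
    """One stimulus condition: a category at each occupied location."""

    id: str
    kind: Kind
    top_category: str = ""
    bottom_category: str = ""

    def __post_init__(self) -> None:
        n_filled = int(bool(self.top_category)) + int(bool(self.bottom_category))
        if self.kind == "single" and n_filled != 1:
            raise ValueError(f"single condition {self.id!r} must occupy exactly one location")
        if self.kind == "pair":
            if n_filled != 2:
                raise ValueError(f"pair condition {self.id!r} must occupy both locations")
            if self.top_category == self.bottom_category:
                raise ValueError(f"pair condition {self.id!r} must use two distinct categories")


@dataclass(frozen=True)
class ConditionTable:
    """Ordered condition list plus fast id/index lookup.

    Singles come first, each block lexicographically ordered by id, so the
    column order of any response matrix built against the table is
    reproducible across files and sessions.
    """

    conditions: tuple[Condition, ...]
    n_categories: int
    n_locations: int
    _index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.conditions]
        if len(set(ids)) != len(ids):
            raise ValueError("condition ids must be unique")
        object.__setattr__(self, "_index", {cid: i for i, cid in enumerate(ids)})

    def __len__(self) -> int:
        return len(self.conditions)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.conditions]

    @property
    def singles(self) -> list[Condition]:
        return [c for c in self.conditions if c.kind == "single"]

    @property
    def pairs(self) -> list[Condition]:
        return [c for c in self.conditions if c.kind == "pair"]

    def index(self, condition_id: str) -> int:
        try:
            return self._index[condition_id]
        except KeyError:
            raise KeyError(f"unknown condition id {condition_id!r}") from None

    def __contains__(self, condition_id: str) -> bool:
        return condition_id in self._index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [c.id for c in self.conditions],
                "kind": [c.kind for c in self.conditions],
                "top_category": [c.top_category for c in self.conditions],
                "bottom_category": [c.bottom_category for c in self.conditions],
            }
        )


def _single_id(category: str, location: str) -> str:
    return f"single_{category}_{location}"


def _pair_id(top_category: str, bottom_category: str) -> str:
    return f"pair_{top_category}_{bottom_category}"


def default_categories(n_categories: int) -> tuple[str, ...]:
    if n_categories <= len(DEFAULT_CATEGORIES):
        return DEFAULT_CATEGORIES[:n_categories]
    return tuple(f"cat{i + 1}" for i in range(n_categories))


def enumerate_conditions(
    n_categories: int,
    n_locations: int = 2,
    categories: Sequence[str] | None = None,
) -> ConditionTable:
    """Enumerate all single and pair conditions of a k-category design.

    Parameters
    ----------
    n_categories
        Number of object categories (k >= 1).
    n_locations
        1 or 2.  Pair conditions exist only for two locations; a design with
        more than two simultaneous locations is not supported.
    categories
        Optional explicit category labels (length ``n_categories``).

    Returns
    -------
    ConditionTable
        ``k * n_locations`` singles followed by ``k * (k - 1)`` pairs (two
        locations only), each block ordered lexicographically by id.
    """
    if n_categories < 1:
        raise ValueError(f"n_categories must be >= 1, got {n_categories}")
    if n_locations < 1:
        raise ValueError(f"n_locations must be >= 1, got {n_locations}")
    if n_locations > 2:
        raise UnsupportedDesignError(
            f"designs with {n_locations} simultaneous locations are not supported (max 2)"
        )
    if categories is None:
        categories = default_categories(n_categories)
    categories = tuple(categories)
    if len(categories) != n_categories:
        raise ValueError(f"expected {n_categories} category labels, got {len(categories)}")
    if len(set(categories)) != n_categories:
        raise ValueError("category labels must be unique")

    locations = (TOP,) if n_locations == 1 else (TOP, BOTTOM)
    singles = []
    for cat in categories:
        for loc in locations:
            singles.append(
                Condition(
                    id=_single_id(cat, loc),
                    kind="single",
                    top_category=cat if loc == TOP else "",
                    bottom_category=cat if loc == BOTTOM else "",
                )
            )
    singles.sort(key=lambda c: c.id)

    pairs = []
    if n_locations == 2:
        for cat_top in categories:
            for cat_bottom in categories:
                if cat_top == cat_bottom:
                    continue
                pairs.append(
                    Condition(
                        id=_pair_id(cat_top, cat_bottom),
                        kind="pair",
                        top_category=cat_top,
                        bottom_category=cat_bottom,
                    )
                )
        pairs.sort(key=lambda c: c.id)

    return ConditionTable(
        conditions=tuple(singles + pairs),
        n_categories=n_categories,
        n_locations=n_locations,
    )


def pair_constituents(pair_id: str, table: ConditionTable) -> tuple[str, str]:
    """Map a pair condition to its two single-object constituents.

    Returns the id of the single condition showing the pair's top category at
    the top location, then the single showing the bottom category at the
    bottom location (top constituent first, always).
    """
    idx = table.index(pair_id)
    cond = table.conditions[idx]
    if cond.kind != "pair":
        raise KeyError(f"condition {pair_id!r} is not a pair condition")
    top_id = _single_id(cond.top_category, TOP)
    bottom_id = _single_id(cond.bottom_category, BOTTOM)
    # Both must exist by construction of any valid table.
    table.index(top_id)
    table.index(bottom_id)
    return top_id, bottom_id


def constituent_indices(table: ConditionTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column indices of (pair, top constituent, bottom constituent) triples.

    Convenience for vectorised analyses: three equal-length integer arrays
    indexing the condition axis, one entry per pair condition in table order.
    """
    pair_idx, top_idx, bottom_idx = [], [], []
    for cond in table.pairs:
        top_id, bottom_id = pair_constituents(cond.id, table)
        pair_idx.append(table.index(cond.id))
        top_idx.append(table.index(top_id))
        bottom_idx.append(table.index(bottom_id))
    return (
        np.asarray(pair_idx, dtype=np.intp),
        np.asarray(top_idx, dtype=np.intp),
        np.asarray(bottom_idx, dtype=np.intp),
    )


def singles_by_location(table: ConditionTable) -> dict[str, np.ndarray]:
    """Column indices of single conditions grouped by occupied location."""
    out: dict[str, list[int]] = {TOP: [], BOTTOM: []}
    for cond in table.singles:
        loc = TOP if cond.top_category else BOTTOM
        out[loc].append(table.index(cond.id))
    return {loc: np.asarray(idx, dtype=np.intp) for loc, idx in out.items() if idx}
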