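"""In-memory container for unit x condition (x run) response data."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .design import ConditionTable


@dataclass
class ResponseDataset:
    """Responses of one subject (or one network layer).

    ``values`` is ``(n_units, n_conditions)`` for run-free activation
    matrices, or ``(n_units, n_conditions, n_runs)`` for per-run beta
    estimates.  The condition axis follows ``table`` order.
    """

    values: np.ndarray
    table: ConditionTable
    unit_ids: np.ndarray | None = None
    subject_id: str = "s0"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise ValueError(f"values must be 2-D or 3-D, got ndim={self.values.ndim}")
        if self.values.shape[1] != len(self.table):
            raise ValueError(
                f"condition axis has length {self.values.shape[1]}, "
                f"but the condition table has {len(self.table)} conditions"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("response values must be finite")
        if self.unit_ids is None:
            self.unit_ids = np.array([f"u{i:04d}" for i in range(self.values.shape[0])])
        else:
            self.unit_ids = np.asarray(self.unit_ids)
            if self.unit_ids.shape[0] != self.values.shape[0]:
                raise ValueError("unit_ids length must match the unit axis")

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def has_runs(self) -> bool:
        return self.values.ndim == 3

    @property
    def n_runs(self) -> int:
        return self.values.shape[2] if self.has_runs else 0

    def subset_units(self, which: Sequence[int] | np.ndarray) -> "ResponseDataset":
        """New dataset restricted to the given unit indices or boolean mask."""
        which = np.asarray(which)
        if which.dtype == bool:
            if which.shape[0] != self.n_units:
                raise ValueError("boolean mask length must match the unit axis")
            idx = np.flatnonzero(which)
        else:
            idx = which.astype(np.intp)
        return replace(self, values=self.values[idx], unit_ids=self.unit_ids[idx])
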