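"""Tidy-CSV interchange for response data and condition tables.

The on-disk contract is a long-format CSV with columns
``subject, unit, condition, run, value`` (``run`` optional: omit it for
noiseless activation matrices).  Every unit must carry every condition;
within a subject all (unit, condition) cells must share one run set.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ResponseDataset
from .design import BOTTOM, TOP, Condition, ConditionTable, enumerate_conditions

logger = logging.getLogger(__name__)

_REQUIRED = ["subject", "unit", "condition", "value"]


class DatasetFormatError(ValueError):
    """Raised for malformed tidy response CSVs."""


def write_condition_table(table: ConditionTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_condition_table(path) -> ConditionTable:
    df = pd.read_csv(path, keep_default_na=False)
    conditions = tuple(
        Condition(
            id=row.id,
            kind=row.kind,
            top_category=row.top_category,
            bottom_category=row.bottom_category,
        )
        for row in df.itertuples()
    )
    categories = sorted(
        {c.top_category for c in conditions if c.top_category}
        | {c.bottom_category for c in conditions if c.bottom_category}
    )
    locations = {TOP for c in conditions if c.top_category} | {
        BOTTOM for c in conditions if c.bottom_category
    }
    return ConditionTable(
        conditions=conditions, n_categories=len(categories), n_locations=len(locations)
    )


def infer_condition_table(condition_ids) -> ConditionTable:
    """Reconstruct the design from canonical condition ids.

    Works for ids produced by :func:`pairavg.design.enumerate_conditions`
    (``single_<cat>_<loc>`` / ``pair_<top>_<bottom>`` with underscore-free
    category labels); the full factorial design must be present.
    """
    categories = set()
    n_locations = 1
    for cid in condition_ids:
        parts = str(cid).split("_")
        if len(parts) != 3 or parts[0] not in ("single", "pair"):
            raise DatasetFormatError(
                f"cannot infer the design from condition id {cid!r}; "
                "supply a condition table"
            )
        if parts[0] == "single":
            categories.add(parts[1])
            if parts[2] == BOTTOM:
                n_locations = 2
        else:
            categories.update(parts[1:])
            n_locations = 2
    table = enumerate_conditions(len(categories), n_locations, sorted(categories))
    missing = set(table.ids) - set(map(str, condition_ids))
    extra = set(map(str, condition_ids)) - set(table.ids)
    if missing or extra:
        raise DatasetFormatError(
            f"condition ids do not form a full factorial design "
            f"(missing {sorted(missing)[:3]}, unexpected {sorted(extra)[:3]})"
        )
    return table


def write_dataset(datasets, path) -> None:
    """Write one dataset or a cohort to a tidy CSV."""
    if isinstance(datasets, ResponseDataset):
        datasets = [datasets]
    frames = []
    for ds in datasets:
        ids = ds.table.ids
        if ds.has_runs:
            n_u, n_c, n_r = ds.values.shape
            frames.append(
                pd.DataFrame(
                    {
                        "subject": ds.subject_id,
                        "unit": np.repeat(ds.unit_ids, n_c * n_r),
                        "condition": np.tile(np.repeat(ids, n_r), n_u),
                        "run": np.tile(np.arange(1, n_r + 1), n_u * n_c),
                        "value": ds.values.ravel(),
                    }
                )
            )
        else:
            n_u, n_c = ds.values.shape
            frames.append(
                pd.DataFrame(
                    {
                        "subject": ds.subject_id,
                        "unit": np.repeat(ds.unit_ids, n_c),
                        "condition": np.tile(ids, n_u),
                        "value": ds.values.ravel(),
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_dataset(path, table: ConditionTable | None = None) -> dict[str, ResponseDataset]:
    """Read a tidy response CSV into per-subject datasets.

    Returns subjects in file order.  Raises :class:`DatasetFormatError`
    naming offending rows (2-based line numbers, header included) for
    duplicate cells, unknown conditions, non-numeric values, and missing
    (unit, condition) cells.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={"subject": str, "unit": str, "condition": str},
        float_precision="round_trip",
    )
    missing_cols = [c for c in _REQUIRED if c not in df.columns]
    if missing_cols:
        raise DatasetFormatError(f"{path}: missing column(s) {missing_cols}")
    has_runs = "run" in df.columns

    bad = df.index[pd.to_numeric(df["value"], errors="coerce").isna()]
    if len(bad):
        raise DatasetFormatError(f"{path}: non-numeric value at row {bad[0] + 2}")
    df["value"] = df["value"].astype(float)

    if table is None:
        table = infer_condition_table(df["condition"].unique())
    unknown = df.index[~df["condition"].isin(set(table.ids))]
    if len(unknown):
        raise DatasetFormatError(
            f"{path}: unknown condition {df.loc[unknown[0], 'condition']!r} "
            f"at row {unknown[0] + 2}"
        )

    keys = ["subject", "unit", "condition"] + (["run"] if has_runs else [])
    dup = df.index[df.duplicated(subset=keys)]
    if len(dup):
        raise DatasetFormatError(f"{path}: duplicated {tuple(keys)} cell at row {dup[0] + 2}")

    out: dict[str, ResponseDataset] = {}
    for subject, sub in df.groupby("subject", sort=False):
        units = list(dict.fromkeys(sub["unit"]))  # keep file order
        if has_runs:
            runs = np.sort(sub["run"].unique())
            if len(runs) != runs[-1] - runs[0] + 1 or runs[0] != 1:
                logger.warning(
                    "subject %s: run numbering %s is not contiguous from 1", subject, runs
                )
            cube = sub.pivot_table(
                index="unit", columns=["condition", "run"], values="value", sort=False
            )
            cube = cube.reindex(index=units)
            full = pd.MultiIndex.from_product([table.ids, runs], names=["condition", "run"])
            cube = cube.reindex(columns=full)
            if cube.isna().any().any():
                missing = cube.isna().stack(future_stack=True).stack(future_stack=True)
                where = missing[missing].index[0]
                raise DatasetFormatError(
                    f"{path}: subject {subject!r} is missing cell {where}"
                )
            values = cube.to_numpy().reshape(len(units), len(table), len(runs))
        else:
            mat = sub.pivot_table(index="unit", columns="condition", values="value", sort=False)
            mat = mat.reindex(index=units, columns=table.ids)
            if mat.isna().any().any():
                unit = mat.index[mat.isna().any(axis=1)][0]
                cond = mat.columns[mat.isna().any(axis=0)][0]
                raise DatasetFormatError(
                    f"{path}: subject {subject!r} is missing cell (unit {unit!r}, "
                    f"condition {cond!r})"
                )
            values = mat.to_numpy()
        out[str(subject)] = ResponseDataset(
            values=values, table=table, unit_ids=np.array(units), subject_id=str(subject)
        )
    return out
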