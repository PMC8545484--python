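"""Hierarchical averaging of per-image measurements.

Study-shaped summaries: per-image values are averaged (unweighted) within
each slice, and slice means are averaged within each animal — the animal
is the terminal statistical unit.
"""

from __future__ import annotations

import pandas as pd


class MissingLabelError(ValueError):
    """A row lacks one of the hierarchy labels."""


def aggregate(
    rows: pd.DataFrame,
    hierarchy: tuple[str, ...] = ("animal", "slice"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-level unweighted means: (per-slice means, per-animal means).

    ``rows`` holds one record per image with hierarchy label columns
    (default ``animal`` and ``slice``) plus numeric value columns.  Rows
    with missing labels raise :class:`MissingLabelError`.  Aggregation is
    idempotent on already-aggregated data and invariant to row order.
    """
    for col in hierarchy:
        if col not in rows.columns:
            raise MissingLabelError(f"missing hierarchy column: {col}")
        if rows[col].isna().any():
            raise MissingLabelError(f"rows with missing {col} label")
    value_cols = [
        c for c in rows.columns
        if c not in hierarchy and pd.api.types.is_numeric_dtype(rows[c])
    ]
    per_slice = (
        rows.groupby(list(hierarchy), sort=True)[value_cols].mean().reset_index()
    )
    per_animal = (
        per_slice.groupby(hierarchy[0], sort=True)[value_cols].mean().reset_index()
    )
    return per_slice, per_animal
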