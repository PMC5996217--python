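"""CSV ingestion for policy tables.

Input contract: a header row with a ``policy`` column (configurable) naming
each policy, plus numeric columns whose roles — resource input versus
signed outcome — are *declared by the caller*, never inferred from sign
patterns. Numbers may carry thousands separators (plain, thin or no-break
spaces, or commas when a "." decimal is used); these are stripped.
"""

from __future__ import annotations

import re
from os import PathLike
from typing import Sequence

import pandas as pd

from .policy_table import PolicyTable, PolicyTableError

__all__ = ["read_policy_csv", "write_policy_csv"]

_SEPARATORS = re.compile(r"[\s   ]|,(?=\d{3})")


def _parse_number(raw: str, row: str, col: str) -> float:
    cleaned = _SEPARATORS.sub("", str(raw).strip())
    try:
        return float(cleaned)
    except ValueError:
        raise PolicyTableError(
            f"unparseable number {raw!r} at policy {row!r}, column {col!r}"
        ) from None


def read_policy_csv(
    path: str | PathLike,
    input_cols: Sequence[str],
    outcome_cols: Sequence[str],
    policy_col: str = "policy",
    column_scales: dict[str, float] | None = None,
) -> PolicyTable:
    """Read and validate a policy table from CSV.

    Raises :class:`PolicyTableError` naming the missing column, the
    unparseable cell (policy and column), or the violated invariant.
    """
    try:
        frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise PolicyTableError(f"empty table: {path} has no rows") from None
    if frame.empty:
        raise PolicyTableError(f"empty table: {path} has no data rows")

    for col in [policy_col, *input_cols, *outcome_cols]:
        if col not in frame.columns:
            raise PolicyTableError(f"column {col!r} not found in {path}")
    overlap = set(input_cols) & set(outcome_cols)
    if overlap:
        raise PolicyTableError(
            f"columns declared both input and outcome: {sorted(overlap)}"
        )

    parsed = frame[[policy_col]].copy()
    parsed[policy_col] = parsed[policy_col].astype(str).str.strip()
    for col in [*input_cols, *outcome_cols]:
        parsed[col] = [
            _parse_number(v, name, col)
            for v, name in zip(frame[col], parsed[policy_col])
        ]
    return PolicyTable.from_frame(
        parsed,
        input_cols=list(input_cols),
        outcome_cols=list(outcome_cols),
        policy_col=policy_col,
        column_scales=column_scales,
    )


def write_policy_csv(table: PolicyTable, path: str | PathLike) -> None:
    """Write a policy table back to CSV (header + one row per policy)."""
    table.to_frame().to_csv(path, index=False)
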