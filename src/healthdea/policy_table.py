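"""Policy tables and their conversion to nonnegative DEA input/output matrices.

The unit of analysis is a health *policy*: it consumes one or more resource
inputs (cost, personnel, ...) and produces one or more signed outcomes
(deaths averted, cases of impoverishment averted, an equity score, ...).
An outcome may be negative for some policies — e.g. a policy that *creates*
catastrophic health expenditure has a negative "catastrophic expenditure
averted" value.

DEA requires nonnegative data. Rather than linearly shifting outcome columns
(which would silently change what every policy "produces"), each signed
outcome is split per cell: the positive part stays an output, and the
magnitude of any negative part becomes an additional *input* — the adverse
consequence is treated as a cost the policy incurs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PolicyRecord",
    "PolicyTable",
    "ColumnOrigin",
    "DeaMatrix",
    "PolicyTableError",
    "validate_table",
    "split_outcomes",
]


class PolicyTableError(ValueError):
    """A policy table violates a structural invariant."""


@dataclass(frozen=True)
class PolicyRecord:
    """One policy: a name, resource-input values, and signed outcome values."""

    name: str
    inputs: tuple[float, ...]
    outcomes: tuple[float, ...]

    def __init__(self, name: str, inputs: Sequence[float], outcomes: Sequence[float]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "inputs", tuple(float(v) for v in inputs))
        object.__setattr__(self, "outcomes", tuple(float(v) for v in outcomes))


@dataclass(frozen=True)
class PolicyTable:
    """An ordered set of policies sharing input and outcome columns.

    Parameters
    ----------
    policies
        One :class:`PolicyRecord` per policy, order preserved everywhere
        downstream (scores, ranks, reports).
    input_names
        Labels of the resource-input columns (consumed; nonnegative).
    outcome_names
        Labels of the signed outcome columns (produced; may be negative).
    column_scales
        Optional display scale per column label (e.g. a cost column printed
        in thousands carries scale 1000). Radial DEA scores are invariant to
        positive column scaling, so scales matter only when absolute ratios
        such as ICERs are reported.
    """

    policies: tuple[PolicyRecord, ...]
    input_names: tuple[str, ...]
    outcome_names: tuple[str, ...]
    column_scales: dict[str, float] = field(default_factory=dict)

    def __init__(
        self,
        policies: Sequence[PolicyRecord],
        input_names: Sequence[str],
        outcome_names: Sequence[str],
        column_scales: dict[str, float] | None = None,
    ):
        object.__setattr__(self, "policies", tuple(policies))
        object.__setattr__(self, "input_names", tuple(input_names))
        object.__setattr__(self, "outcome_names", tuple(outcome_names))
        object.__setattr__(self, "column_scales", dict(column_scales or {}))

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.policies]

    def __len__(self) -> int:
        return len(self.policies)

    def input_array(self) -> np.ndarray:
        return np.array([p.inputs for p in self.policies], dtype=float)

    def outcome_array(self) -> np.ndarray:
        return np.array([p.outcomes for p in self.policies], dtype=float)

    def column(self, label: str) -> np.ndarray:
        """Return a named column (input or outcome) as an array."""
        if label in self.input_names:
            return self.input_array()[:, self.input_names.index(label)]
        if label in self.outcome_names:
            return self.outcome_array()[:, self.outcome_names.index(label)]
        raise KeyError(f"no column named {label!r}")

    def scale(self, label: str) -> float:
        return float(self.column_scales.get(label, 1.0))

    def to_frame(self) -> pd.DataFrame:
        """Policies as a DataFrame with a leading ``policy`` column."""
        data = {"policy": self.names}
        xs = self.input_array()
        ys = self.outcome_array()
        for j, name in enumerate(self.input_names):
            data[name] = xs[:, j]
        for r, name in enumerate(self.outcome_names):
            data[name] = ys[:, r]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        input_cols: Sequence[str],
        outcome_cols: Sequence[str],
        policy_col: str = "policy",
        column_scales: dict[str, float] | None = None,
    ) -> "PolicyTable":
        for col in [policy_col, *input_cols, *outcome_cols]:
            if col not in frame.columns:
                raise PolicyTableError(f"column {col!r} not found in table")
        records = [
            PolicyRecord(
                name=str(row[policy_col]),
                inputs=[float(row[c]) for c in input_cols],
                outcomes=[float(row[c]) for c in outcome_cols],
            )
            for _, row in frame.iterrows()
        ]
        return validate_table(
            cls(records, input_cols, outcome_cols, column_scales=column_scales)
        )


ColumnKind = Literal["input", "outcome-benefit", "outcome-adverse"]


@dataclass(frozen=True)
class ColumnOrigin:
    """Provenance of one DEA matrix column."""

    kind: ColumnKind
    source: str  # label of the originating policy-table column


@dataclass(frozen=True)
class DeaMatrix:
    """Nonnegative input matrix ``x`` and output matrix ``y`` for DEA.

    ``x_origins`` / ``y_origins`` record, for each column, whether it is a
    resource input copied through, the benefit part of a signed outcome, or
    the adverse part of a signed outcome (magnitude of its negative values).
    """

    x: np.ndarray  # (n_policies, n_x_columns), all >= 0
    y: np.ndarray  # (n_policies, n_y_columns), all >= 0
    x_origins: tuple[ColumnOrigin, ...]
    y_origins: tuple[ColumnOrigin, ...]
    names: tuple[str, ...]

    @property
    def n_policies(self) -> int:
        return self.x.shape[0]


def validate_table(table: PolicyTable) -> PolicyTable:
    """Check every structural invariant; return the table unchanged if valid.

    Raises :class:`PolicyTableError` identifying the first violated invariant
    (empty table, missing columns, duplicate or empty names, length mismatch,
    non-finite or negative inputs, non-finite outcomes, a policy with no
    positive resource input).
    """
    if len(table.policies) == 0:
        raise PolicyTableError("empty table: at least one policy required")
    if len(table.input_names) == 0:
        raise PolicyTableError("at least one resource-input column required")
    if len(table.outcome_names) == 0:
        raise PolicyTableError("at least one outcome column required")

    seen: set[str] = set()
    for i, p in enumerate(table.policies):
        if not p.name or not p.name.strip():
            raise PolicyTableError(f"policy at row {i} has an empty name")
        if p.name in seen:
            raise PolicyTableError(f"duplicate policy name {p.name!r}")
        seen.add(p.name)
        if len(p.inputs) != len(table.input_names):
            raise PolicyTableError(
                f"policy {p.name!r}: {len(p.inputs)} input values for "
                f"{len(table.input_names)} input columns"
            )
        if len(p.outcomes) != len(table.outcome_names):
            raise PolicyTableError(
                f"policy {p.name!r}: {len(p.outcomes)} outcome values for "
                f"{len(table.outcome_names)} outcome columns"
            )
        for label, v in zip(table.input_names, p.inputs):
            if not math.isfinite(v):
                raise PolicyTableError(
                    f"policy {p.name!r}, input {label!r}: non-finite value {v!r}"
                )
            if v < 0:
                raise PolicyTableError(
                    f"policy {p.name!r}, input {label!r}: negative value {v}"
                )
        for label, v in zip(table.outcome_names, p.outcomes):
            if not math.isfinite(v):
                raise PolicyTableError(
                    f"policy {p.name!r}, outcome {label!r}: non-finite value {v!r}"
                )
        if not any(v > 0 for v in p.inputs):
            raise PolicyTableError(
                f"policy {p.name!r}: all resource inputs are zero; each policy "
                "must consume at least one resource"
            )
    return table


def split_outcomes(table: PolicyTable) -> DeaMatrix:
    """Convert signed outcomes into a nonnegative input/output matrix pair.

    Per cell, outcome value ``v`` contributes ``max(v, 0)`` to the outcome's
    output column and ``max(-v, 0)`` to an adverse-part input column. The
    adverse column is created only if at least one policy is negative in that
    outcome (an all-zero input column would be inert in the radial model).
    Resource inputs are copied through unchanged. Column order is
    deterministic: resource inputs first, then adverse parts in outcome
    order; outputs in outcome order.
    """
    validate_table(table)
    xs = table.input_array()
    ys = table.outcome_array()

    x_cols: list[np.ndarray] = [xs[:, j] for j in range(xs.shape[1])]
    x_origins: list[ColumnOrigin] = [
        ColumnOrigin("input", name) for name in table.input_names
    ]
    for r, name in enumerate(table.outcome_names):
        col = ys[:, r]
        if np.any(col < 0):
            x_cols.append(np.maximum(-col, 0.0))
            x_origins.append(ColumnOrigin("outcome-adverse", name))

    y_cols = [np.maximum(ys[:, r], 0.0) for r in range(ys.shape[1])]
    y_origins = [ColumnOrigin("outcome-benefit", name) for name in table.outcome_names]

    return DeaMatrix(
        x=np.column_stack(x_cols),
        y=np.column_stack(y_cols),
        x_origins=tuple(x_origins),
        y_origins=tuple(y_origins),
        names=tuple(table.names),
    )
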