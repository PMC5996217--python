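"""Assemble the decision product: ICER status, DEA score, superefficiency rank.

One row per policy, mirroring the comparison layout used in health-policy
league tables: the ICER column (ratio or "Dominated") as the traditional
cost-effectiveness verdict, the standard DEA score, and the rank-capable
superefficiency score that orders every policy including the dominated ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import pandas as pd

from .engine import RTS, efficiency_all
from .frontier import FrontierResult, cea_frontier
from .policy_table import PolicyTable, split_outcomes, validate_table
from .superefficiency import NonRankableError, superefficiency

__all__ = ["RankRow", "RankReport", "rank_policies"]


@dataclass(frozen=True)
class RankRow:
    name: str
    icer_display: str
    standard_score: float
    super_score: float
    rank: int
    cook_triggered: bool
    rankable: bool = True


@dataclass(frozen=True)
class RankReport:
    """Ranked policies; ranks computed on full-precision superefficiency."""

    rows: tuple[RankRow, ...]
    rts: RTS
    frontier: FrontierResult | None
    precision: int = 2

    def __getitem__(self, name: str) -> RankRow:
        for row in self.rows:
            if row.name == name:
                return row
        raise KeyError(name)

    def to_frame(self, full_precision: bool = False) -> pd.DataFrame:
        ndp = None if full_precision else self.precision
        records = []
        for r in self.rows:
            records.append(
                {
                    "policy": r.name,
                    "icer": r.icer_display,
                    "dea_score": r.standard_score if ndp is None else round(r.standard_score, ndp),
                    "super_score": r.super_score if ndp is None else round(r.super_score, ndp),
                    "rank": r.rank,
                }
            )
        return pd.DataFrame(records)

    def to_csv(self, path, full_precision: bool = False) -> None:
        self.to_frame(full_precision).to_csv(path, index=False)

    def to_text(self, full_precision: bool = False) -> str:
        """Aligned text table in league-table column order."""
        frame = self.to_frame(full_precision)
        fmt = None if full_precision else (lambda v: f"{v:.{self.precision}f}")
        return frame.to_string(
            index=False,
            float_format=fmt,
            justify="left",
        )


def _icer_display(frontier: FrontierResult | None, name: str, effect_label: str) -> str:
    if frontier is None:
        return ""
    entry = frontier[name]
    if entry.status != "on-frontier" or entry.icer is None:
        return "Dominated"
    return f"US$ {entry.icer:,.0f} per {effect_label}".replace(",", " ")


def rank_policies(
    table: PolicyTable,
    rts: RTS = RTS.VRS,
    icer_pair: tuple[str, str] | None = None,
    icer_comparator: Literal["frontier", "previous-survivor"] = "frontier",
    precision: int = 2,
) -> RankReport:
    """Run the full pipeline and rank policies by superefficiency score.

    Splits signed outcomes, computes standard and superefficiency scores
    under ``rts``, optionally the ICER frontier on ``icer_pair``
    = (cost column, effect column), and sorts by superefficiency descending.
    Ties break by lower total resource input, then by name. Policies whose
    fallback is non-rankable are placed last and flagged.
    """
    validate_table(table)
    matrix = split_outcomes(table)
    standard = efficiency_all(matrix, rts)

    supers: list[tuple[float, bool, bool]] = []  # (score, cook_triggered, rankable)
    for o in range(len(table)):
        try:
            res = superefficiency(matrix, o, rts)
            supers.append((res.score, res.cook is not None, True))
        except NonRankableError:
            supers.append((float("-inf"), True, False))

    frontier = None
    if icer_pair is not None:
        frontier = cea_frontier(table, *icer_pair, comparator=icer_comparator)
        effect_label = icer_pair[1].replace("_", " ")

    totals = table.input_array().sum(axis=1)
    order = sorted(
        range(len(table)),
        key=lambda i: (-supers[i][0], totals[i], table.names[i]),
    )
    rank_of = {i: pos + 1 for pos, i in enumerate(order)}

    rows = []
    for i, p in enumerate(table.policies):
        score, cook_flag, rankable = supers[i]
        rows.append(
            RankRow(
                name=p.name,
                icer_display=_icer_display(frontier, p.name, effect_label)
                if frontier is not None
                else "",
                standard_score=standard[i].theta,
                super_score=score,
                rank=rank_of[i],
                cook_triggered=cook_flag,
                rankable=rankable,
            )
        )
    return RankReport(rows=tuple(rows), rts=rts, frontier=frontier, precision=precision)
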