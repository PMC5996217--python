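"""Cost-effectiveness frontier: dominance, extended dominance and ICERs.

The traditional comparator for the DEA ranking: project the policy set onto
a single (cost, effect) pair, discard dominated policies, and walk the
survivors in cost order computing incremental cost-effectiveness ratios
(ICERs). A policy is *dominated* when another costs no more and delivers at
least as much effect (strictly better on one side); it is
*extended-dominated* when it survives pairwise dominance but produces a
non-increasing ICER step, i.e. a mix of its neighbours buys effect more
cheaply.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .policy_table import PolicyTable

__all__ = ["PolicyFrontierStatus", "FrontierResult", "find_dominated", "icers", "cea_frontier"]

Status = Literal["on-frontier", "dominated", "extended-dominated"]


@dataclass
class PolicyFrontierStatus:
    """Dominance status and (for frontier policies) ICER of one policy."""

    name: str
    cost: float
    effect: float
    status: Status
    icer: float | None = None
    comparator: str | None = None  # previous frontier policy, or "do-nothing"
    dominated_by: str | None = None


@dataclass
class FrontierResult:
    """Per-policy frontier statuses plus the (cost, effect) pair used."""

    entries: list[PolicyFrontierStatus]
    cost_col: str
    effect_col: str
    cost_scale: float = 1.0
    effect_scale: float = 1.0
    icers_applied: bool = field(default=False)

    def __getitem__(self, name: str) -> PolicyFrontierStatus:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def frontier(self) -> list[PolicyFrontierStatus]:
        """Surviving policies in increasing cost order."""
        return sorted(
            (e for e in self.entries if e.status == "on-frontier"),
            key=lambda e: (e.cost, e.effect),
        )


def find_dominated(
    table: PolicyTable, cost_col: str, effect_col: str
) -> FrontierResult:
    """Mark strictly dominated policies on the chosen (cost, effect) pair.

    A policy is dominated when some other policy has cost ≤ and effect ≥
    with at least one strict inequality. Two policies with identical
    (cost, effect): the later row is marked dominated (deterministic
    tie-break).
    """
    costs = table.column(cost_col)
    effects = table.column(effect_col)
    names = table.names
    k = len(names)

    entries: list[PolicyFrontierStatus] = []
    for i in range(k):
        dominated_by: str | None = None
        for j in range(k):
            if j == i:
                continue
            tie = costs[j] == costs[i] and effects[j] == effects[i]
            if tie:
                if j < i:  # later duplicate row loses
                    dominated_by = names[j]
                    break
                continue
            if costs[j] <= costs[i] and effects[j] >= effects[i]:
                dominated_by = names[j]
                break
        entries.append(
            PolicyFrontierStatus(
                name=names[i],
                cost=float(costs[i]),
                effect=float(effects[i]),
                status="dominated" if dominated_by else "on-frontier",
                dominated_by=dominated_by,
            )
        )
    return FrontierResult(
        entries=entries,
        cost_col=cost_col,
        effect_col=effect_col,
        cost_scale=table.scale(cost_col),
        effect_scale=table.scale(effect_col),
    )


def icers(frontier: FrontierResult) -> FrontierResult:
    """Compute ICERs along the frontier, applying extended dominance.

    Survivors are walked in cost order. The cheapest survivor's ratio is
    taken against a do-nothing origin at (0, 0); each later ratio is
    Δcost/Δeffect against the previous survivor. A non-increasing ratio
    step means a mix of the two neighbouring policies buys effect more
    cheaply than the intermediate one: that intermediate predecessor is
    marked extended-dominated, removed, and the walk restarts, iterating
    to a fixed point, so the final ICER sequence is strictly increasing.
    ICERs are reported on the display scale of the cost and effect columns.
    A cheapest survivor with effect ≤ 0 has no defined ratio and is flagged
    with ``icer=None``, comparator "undefined".
    """
    ratio_scale = frontier.cost_scale / frontier.effect_scale
    while True:
        surv = frontier.frontier
        demoted = False
        prev: PolicyFrontierStatus | None = None
        prev_cost, prev_effect = 0.0, 0.0
        prev_name = "do-nothing"
        prev_ratio: float | None = None
        for e in surv:
            d_cost = e.cost - prev_cost
            d_eff = e.effect - prev_effect
            if d_eff <= 0:
                if prev_name == "do-nothing":
                    e.icer = None
                    e.comparator = "undefined"
                    prev, prev_cost, prev_effect, prev_name = e, e.cost, e.effect, e.name
                    continue
                raise AssertionError(
                    "non-increasing effect along the frontier after dominance"
                )
            ratio = (d_cost / d_eff) * ratio_scale
            if prev_ratio is not None and ratio <= prev_ratio:
                assert prev is not None
                prev.status = "extended-dominated"
                prev.icer = None
                prev.comparator = None
                demoted = True
                break
            e.icer = ratio
            e.comparator = prev_name
            prev, prev_cost, prev_effect, prev_name = e, e.cost, e.effect, e.name
            prev_ratio = ratio
        if not demoted:
            break
    frontier.icers_applied = True
    return frontier


def cea_frontier(
    table: PolicyTable,
    cost_col: str,
    effect_col: str,
    comparator: Literal["frontier", "previous-survivor"] = "frontier",
) -> FrontierResult:
    """Dominance plus ICERs in one call.

    ``comparator="frontier"`` applies extended dominance (the ICER chain
    runs through frontier policies only, and is strictly increasing).
    ``comparator="previous-survivor"`` skips extended dominance: each
    pairwise-undominated policy's ICER is taken against the previous one in
    cost order, whether or not that predecessor would survive extended
    dominance.
    """
    result = find_dominated(table, cost_col, effect_col)
    if comparator == "frontier":
        return icers(result)
    # previous-survivor: chain through all pairwise survivors, no demotion
    ratio_scale = result.cost_scale / result.effect_scale
    prev_cost, prev_effect, prev_name = 0.0, 0.0, "do-nothing"
    for e in result.frontier:
        d_eff = e.effect - prev_effect
        if d_eff <= 0:
            e.icer = None
            e.comparator = "undefined"
        else:
            e.icer = ((e.cost - prev_cost) / d_eff) * ratio_scale
            e.comparator = prev_name
        prev_cost, prev_effect, prev_name = e.cost, e.effect, e.name
    result.icers_applied = True
    return result
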