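"""Synthetic policy-table generator.

Emulates the structure of published extended cost-effectiveness tables:
strictly positive resource inputs (costs) and signed outcome measures where
a controllable fraction of cells is adverse (negative). Useful for property
tests and for exercising the negative-outcome split and the
infeasible-superefficiency fallback on sets of arbitrary size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .policy_table import PolicyRecord, PolicyTable, validate_table

__all__ = ["SyntheticSpec", "generate_policies"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Dimensions and value ranges for a random policy table.

    ``neg_fraction`` is the per-cell probability that an outcome value is
    adverse (negated). ``cost_range`` and ``outcome_range`` are positive
    (low, high) magnitude ranges. The same seed always yields the same
    table.
    """

    n_policies: int = 8
    n_inputs: int = 1
    n_outcomes: int = 2
    neg_fraction: float = 0.2
    cost_range: tuple[float, float] = (100.0, 10_000.0)
    outcome_range: tuple[float, float] = (1.0, 1_000.0)
    seed: int = 0
    plant_dominator: bool = False

    def __post_init__(self) -> None:
        if self.n_policies < 1 or self.n_inputs < 1 or self.n_outcomes < 1:
            raise ValueError("dimensions must be at least 1")
        if not 0.0 <= self.neg_fraction <= 1.0:
            raise ValueError("neg_fraction must be a probability")
        for lo, hi in (self.cost_range, self.outcome_range):
            if not (0 < lo <= hi):
                raise ValueError("ranges must be positive and ordered")


def generate_policies(spec: SyntheticSpec) -> PolicyTable:
    """Draw a random policy table; reproducible given the seed.

    With ``plant_dominator``, the last policy is constructed to strictly
    dominate all others (10% cheaper than every column minimum, 10% more
    than every outcome-benefit maximum), for rank-1 recovery tests. In that
    mode the first random policy is kept free of adverse outcomes so the
    dominator always has a usable reference composite and stays rankable.
    """
    rng = np.random.default_rng(spec.seed)
    n_random = spec.n_policies - (1 if spec.plant_dominator else 0)
    if spec.plant_dominator and n_random < 1:
        raise ValueError("plant_dominator requires at least 2 policies")

    costs = rng.uniform(*spec.cost_range, size=(n_random, spec.n_inputs))
    magnitudes = rng.uniform(*spec.outcome_range, size=(n_random, spec.n_outcomes))
    signs = np.where(
        rng.random((n_random, spec.n_outcomes)) < spec.neg_fraction, -1.0, 1.0
    )
    if spec.plant_dominator:
        signs[0, :] = 1.0
    outcomes = magnitudes * signs

    records = [
        PolicyRecord(f"policy-{i + 1}", costs[i], outcomes[i]) for i in range(n_random)
    ]
    if spec.plant_dominator:
        records.append(
            PolicyRecord(
                "planted-dominator",
                0.9 * costs.min(axis=0),
                1.1 * np.maximum(outcomes, 0.0).max(axis=0),
            )
        )
    table = PolicyTable(
        policies=records,
        input_names=[f"cost_{j + 1}" for j in range(spec.n_inputs)],
        outcome_names=[f"outcome_{r + 1}" for r in range(spec.n_outcomes)],
    )
    return validate_table(table)
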