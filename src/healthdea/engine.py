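"""Input-oriented radial DEA in envelopment form.

For an evaluated policy *o* with inputs ``x_o`` and outputs ``y_o``, the
envelopment program asks for the smallest uniform contraction θ of *o*'s
inputs such that a composite of reference policies (a nonnegative weighting
λ, convex under variable returns to scale) still produces at least *o*'s
outputs:

    minimize θ
    subject to   Σ_k λ_k x_kj ≤ θ x_oj     for every input column j
                 Σ_k λ_k y_kr ≥ y_or       for every output column r
                 Σ_k λ_k = 1               (VRS only)
                 λ ≥ 0

θ = 1 means no composite of the reference set produces *o*'s outputs with
uniformly fewer inputs; θ < 1 measures how far *o* is from that frontier.
The optimal dual multipliers are the policy-specific preference weights of
the ratio formulation: each policy is scored with the input/output weights
most favourable to it, so a low score cannot be blamed on an externally
imposed weighting.

When ``x_oj = 0`` the input constraint degenerates to ``Σ λ_k x_kj ≤ 0``,
which is enforced: the composite must also consume none of that input.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import TYPE_CHECKING, Iterable, Literal

import numpy as np
from scipy.optimize import linprog

from .policy_table import DeaMatrix

if TYPE_CHECKING:  # pragma: no cover
    from .superefficiency import CookComponents

__all__ = [
    "RTS",
    "LpSpec",
    "MultiplierWeights",
    "EfficiencyResult",
    "SolverError",
    "solve_envelopment",
    "efficiency",
    "efficiency_all",
]


class RTS(str, Enum):
    """Returns-to-scale assumption for the envelopment program."""

    CRS = "crs"  # constant: composites may be scaled arbitrarily
    VRS = "vrs"  # variable: composite weights sum to one (convexity)


class SolverError(RuntimeError):
    """The LP backend failed for a reason other than genuine infeasibility."""


@dataclass(frozen=True)
class LpSpec:
    """One envelopment program: who is evaluated, against whom, under what."""

    evaluated_index: int
    reference_set: tuple[int, ...]
    rts: RTS
    matrix: DeaMatrix
    orientation: Literal["input"] = "input"

    def __post_init__(self) -> None:
        k = self.matrix.n_policies
        if not 0 <= self.evaluated_index < k:
            raise ValueError(f"evaluated_index {self.evaluated_index} out of range")
        if len(self.reference_set) == 0:
            raise ValueError("reference_set must be non-empty")
        if any(not 0 <= i < k for i in self.reference_set):
            raise ValueError("reference_set index out of range")
        if self.orientation != "input":
            raise ValueError("only input-oriented radial DEA is supported")


@dataclass(frozen=True)
class MultiplierWeights:
    """Optimal dual weights: v over input columns, u over output columns."""

    u: np.ndarray
    v: np.ndarray


@dataclass(frozen=True)
class EfficiencyResult:
    """Outcome of one radial efficiency program.

    ``theta`` is the radial score (contractual); ``lambdas`` the composite
    weights over the full policy list (zero outside the reference set);
    ``duals`` the recovered multiplier weights. ``cook`` is set when the
    superefficiency fallback fired (see :mod:`healthdea.superefficiency`),
    in which case ``score`` is the fallback score rather than ``theta``.
    """

    policy: str
    theta: float
    lambdas: np.ndarray
    status: Literal["optimal", "infeasible", "non-comparable"]
    duals: MultiplierWeights | None = None
    cook: "CookComponents | None" = None

    @property
    def feasible(self) -> bool:
        return self.status == "optimal"

    @property
    def score(self) -> float:
        """Rankable score: θ normally, the fallback score when it fired."""
        if self.cook is not None and self.cook.triggered:
            return self.cook.score
        return self.theta


def solve_envelopment(spec: LpSpec) -> EfficiencyResult:
    """Solve one envelopment LP; report θ, λ and dual weights at optimum."""
    mat = spec.matrix
    o = spec.evaluated_index
    ref = list(spec.reference_set)
    x, y = mat.x, mat.y
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise SolverError("non-finite matrix entries")

    n_x, n_y = x.shape[1], y.shape[1]
    m = len(ref)
    # variables: [theta, lambda_1..lambda_m]
    c = np.zeros(m + 1)
    c[0] = 1.0

    a_ub = np.zeros((n_x + n_y, m + 1))
    b_ub = np.zeros(n_x + n_y)
    for j in range(n_x):
        a_ub[j, 0] = -x[o, j]
        a_ub[j, 1:] = x[ref, j]
    for r in range(n_y):
        a_ub[n_x + r, 1:] = -y[ref, r]
        b_ub[n_x + r] = -y[o, r]

    a_eq = b_eq = None
    if spec.rts is RTS.VRS:
        a_eq = np.zeros((1, m + 1))
        a_eq[0, 1:] = 1.0
        b_eq = np.array([1.0])

    res = linprog(
        c,
        A_ub=a_ub,
        b_ub=b_ub,
        A_eq=a_eq,
        b_eq=b_eq,
        bounds=[(0, None)] * (m + 1),
        method="highs",
    )
    if res.status == 2:
        return EfficiencyResult(
            policy=mat.names[o],
            theta=float("nan"),
            lambdas=np.zeros(mat.n_policies),
            status="infeasible",
        )
    if res.status != 0:
        raise SolverError(f"LP solver failed (status {res.status}): {res.message}")

    lambdas = np.zeros(mat.n_policies)
    lambdas[ref] = res.x[1:]
    # duals of the <= rows: input rows yield v, output rows yield u
    marginals = np.asarray(res.ineqlin.marginals)
    duals = MultiplierWeights(
        u=np.maximum(-marginals[n_x:], 0.0),
        v=np.maximum(-marginals[:n_x], 0.0),
    )
    return EfficiencyResult(
        policy=mat.names[o],
        theta=float(res.x[0]),
        lambdas=lambdas,
        status="optimal",
        duals=duals,
    )


def efficiency(matrix: DeaMatrix, o: int, rts: RTS = RTS.VRS) -> EfficiencyResult:
    """Standard efficiency of policy ``o`` against all policies (incl. itself).

    Always feasible (λ_o = 1, θ = 1 is a feasible point); θ ∈ (0, 1].
    """
    spec = LpSpec(
        evaluated_index=o,
        reference_set=tuple(range(matrix.n_policies)),
        rts=rts,
        matrix=matrix,
    )
    return solve_envelopment(spec)


def efficiency_all(matrix: DeaMatrix, rts: RTS = RTS.VRS) -> list[EfficiencyResult]:
    """Standard efficiency for every policy, input order preserved."""
    return [efficiency(matrix, o, rts) for o in range(matrix.n_policies)]
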