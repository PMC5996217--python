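"""Superefficiency scores and the two-stage fallback for infeasible programs.

Standard DEA leaves many policies tied at θ = 1. Superefficiency breaks the
tie: each policy is scored against the frontier formed by the *other*
policies (it is removed from its own reference set), so efficient policies
obtain scores above 1 that measure how far the rest of the set is from
matching them.

Under variable returns to scale the superefficiency program can be
infeasible: if a policy single-handedly holds an output level no convex
combination of the others can reach, no θ exists. Such a policy is on the
frontier by construction, and its rank-capable score comes from a two-stage
fallback:

  stage 1  find the largest retention factor s ∈ (0, 1] such that some
           convex combination of the others produces at least s·y_o
           (inputs unconstrained, except columns where the evaluated policy
           uses zero input, which stay zero-sum);
  stage 2  with s fixed at s*, find the smallest radial input factor θ*
           against the retained outputs s*·y_o;
  score    θ* + 1/s*.

A shortfall in reachable outputs (small s*) thus inflates the score the way
an input surplus does for a feasible superefficient policy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import linprog

from .engine import RTS, EfficiencyResult, LpSpec, SolverError, solve_envelopment
from .policy_table import DeaMatrix

__all__ = [
    "CookComponents",
    "NonRankableError",
    "superefficiency",
    "cook_score",
]

_S_FLOOR = 1e-9  # an optimal s* at zero means no output is reachable at all


class NonRankableError(RuntimeError):
    """Even the stage-1 retention program has no feasible point."""


@dataclass(frozen=True)
class CookComponents:
    """Components of the two-stage fallback score.

    ``s_star`` in (0, 1] is the output-retention factor; ``theta_star`` the
    radial input factor against the retained outputs. When ``triggered``,
    the policy's score is ``theta_star + 1/s_star``.
    """

    s_star: float
    theta_star: float
    triggered: bool = True

    @property
    def score(self) -> float:
        return self.theta_star + 1.0 / self.s_star


def superefficiency(matrix: DeaMatrix, o: int, rts: RTS = RTS.VRS) -> EfficiencyResult:
    """Score policy ``o`` against the other policies only.

    Feasible programs return θ (which may exceed 1). An infeasible VRS
    program delegates to :func:`cook_score`; the returned result carries the
    fallback components and ``score`` reflects them. A single-policy table
    has no reference set: the score is +inf, flagged ``non-comparable``.
    """
    k = matrix.n_policies
    if k < 2:
        return EfficiencyResult(
            policy=matrix.names[o],
            theta=float("inf"),
            lambdas=np.zeros(k),
            status="non-comparable",
        )
    ref = tuple(i for i in range(k) if i != o)
    result = solve_envelopment(LpSpec(o, ref, rts, matrix))
    if result.status == "infeasible" and rts is RTS.VRS:
        cook = cook_score(matrix, o)
        return replace(result, cook=cook)
    return result


def cook_score(matrix: DeaMatrix, o: int) -> CookComponents:
    """Two-stage fallback for an infeasible VRS superefficiency program.

    Stage 1 maximizes the retention factor s; stage 2 minimizes the radial
    input factor θ given s*. Ties within a stage are resolved by the LP
    solver; only s* and θ* are contractual (the split is lexicographic:
    retention first, then inputs).
    """
    x, y = matrix.x, matrix.y
    k = matrix.n_policies
    ref = [i for i in range(k) if i != o]
    m = len(ref)
    n_x, n_y = x.shape[1], y.shape[1]
    zero_cols = [j for j in range(n_x) if x[o, j] == 0.0]

    # stage 1: variables [s, lambda]; maximize s
    c1 = np.zeros(m + 1)
    c1[0] = -1.0
    rows: list[np.ndarray] = []
    rhs: list[float] = []
    for r in range(n_y):
        row = np.zeros(m + 1)
        row[0] = y[o, r]
        row[1:] = -y[ref, r]
        rows.append(row)
        rhs.append(0.0)
    for j in zero_cols:
        row = np.zeros(m + 1)
        row[1:] = x[ref, j]
        rows.append(row)
        rhs.append(0.0)
    a_eq = np.zeros((1, m + 1))
    a_eq[0, 1:] = 1.0
    res1 = linprog(
        c1,
        A_ub=np.array(rows),
        b_ub=np.array(rhs),
        A_eq=a_eq,
        b_eq=np.array([1.0]),
        bounds=[(0.0, 1.0)] + [(0.0, None)] * m,
        method="highs",
    )
    if res1.status == 2:
        raise NonRankableError(
            f"policy {matrix.names[o]!r}: zero-input constraints exclude every "
            "reference composite; no retention factor exists"
        )
    if res1.status != 0:
        raise SolverError(f"stage-1 LP failed (status {res1.status}): {res1.message}")
    s_star = float(res1.x[0])
    if s_star <= _S_FLOOR:
        raise NonRankableError(
            f"policy {matrix.names[o]!r}: no positive fraction of its outputs "
            "is reachable by the reference set"
        )

    # stage 2: variables [theta, lambda]; minimize theta at s = s*
    c2 = np.zeros(m + 1)
    c2[0] = 1.0
    rows2: list[np.ndarray] = []
    rhs2: list[float] = []
    for j in range(n_x):
        row = np.zeros(m + 1)
        row[0] = -x[o, j]
        row[1:] = x[ref, j]
        rows2.append(row)
        rhs2.append(0.0)
    for r in range(n_y):
        row = np.zeros(m + 1)
        row[1:] = -y[ref, r]
        rows2.append(row)
        rhs2.append(-s_star * y[o, r])
    res2 = linprog(
        c2,
        A_ub=np.array(rows2),
        b_ub=np.array(rhs2),
        A_eq=a_eq,
        b_eq=np.array([1.0]),
        bounds=[(0.0, None)] * (m + 1),
        method="highs",
    )
    if res2.status != 0:
        # stage 2 is feasible by construction at s*; anything else is numeric
        raise SolverError(f"stage-2 LP failed (status {res2.status}): {res2.message}")
    return CookComponents(s_star=s_star, theta_star=float(res2.x[0]), triggered=True)
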