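"""Brute-force vertex-enumeration check for the envelopment LP.

Independent of the LP solver: every basic feasible solution of the
envelopment program is enumerated by activating each cardinality-correct
subset of constraints as equalities, solving the square linear system, and
keeping the feasible points. The minimum θ over those vertices is the LP
optimum (θ is bounded below by zero and the feasible region is pointed).
Practical only for tiny programs; used as a test oracle.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .engine import RTS
from .policy_table import DeaMatrix

__all__ = ["oracle_efficiency"]

MAX_REFERENCE = 6
MAX_COLUMNS = 5


def oracle_efficiency(
    matrix: DeaMatrix,
    o: int,
    rts: RTS = RTS.VRS,
    reference_set: tuple[int, ...] | None = None,
) -> float | None:
    """Minimum θ of the envelopment program by vertex enumeration.

    Returns None when no vertex is feasible (the program is infeasible).
    Limits: at most 6 reference policies and 5 total x+y columns.
    """
    x, y = matrix.x, matrix.y
    if reference_set is None:
        reference_set = tuple(range(matrix.n_policies))
    ref = list(reference_set)
    m = len(ref)
    n_x, n_y = x.shape[1], y.shape[1]
    if m > MAX_REFERENCE:
        raise ValueError(f"reference set too large for enumeration ({m} > {MAX_REFERENCE})")
    if n_x + n_y > MAX_COLUMNS:
        raise ValueError(f"too many columns for enumeration ({n_x + n_y} > {MAX_COLUMNS})")

    n = m + 1  # variables: theta, lambda_ref
    # inequality rows a·z <= b
    rows: list[np.ndarray] = []
    rhs: list[float] = []
    for j in range(n_x):
        row = np.zeros(n)
        row[0] = -x[o, j]
        row[1:] = x[ref, j]
        rows.append(row)
        rhs.append(0.0)
    for r in range(n_y):
        row = np.zeros(n)
        row[1:] = -y[ref, r]
        rows.append(row)
        rhs.append(-y[o, r])
    for v in range(n):  # variable nonnegativity
        row = np.zeros(n)
        row[v] = -1.0
        rows.append(row)
        rhs.append(0.0)
    a_ineq = np.array(rows)
    b_ineq = np.array(rhs)

    eq_rows: list[np.ndarray] = []
    eq_rhs: list[float] = []
    if rts is RTS.VRS:
        row = np.zeros(n)
        row[1:] = 1.0
        eq_rows.append(row)
        eq_rhs.append(1.0)
    n_eq = len(eq_rows)

    data_scale = max(1.0, float(np.max(np.abs(a_ineq))), float(np.max(np.abs(b_ineq))))
    best: float | None = None
    for active in combinations(range(len(rows)), n - n_eq):
        a_sys = np.vstack([a_ineq[list(active)]] + eq_rows) if eq_rows else a_ineq[list(active)]
        b_sys = np.concatenate([b_ineq[list(active)], np.array(eq_rhs)]) if eq_rows else b_ineq[list(active)]
        try:
            z = np.linalg.solve(a_sys, b_sys)
        except np.linalg.LinAlgError:
            continue
        scale = data_scale * max(1.0, float(np.max(np.abs(z))))
        if np.all(a_ineq @ z <= b_ineq + 1e-9 * scale):
            theta = float(z[0])
            if best is None or theta < best:
                best = theta
    return best
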