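"""Exact discrete Kantorovich optimal transport via linear programming.

Solves ``min <C, M>`` over couplings ``M >= 0`` whose row sums equal the
source marginal and whose column sums equal the target marginal.  Problem
sizes here are small (tens of labels per layer, at most a few hundred
boundary pixels), so the LP is solved exactly with HiGHS; simplex returns a
basic solution, which makes the downstream argmax tracing deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

#: marginal agreement required between the two input distributions
MARGINAL_TOL = 1e-8


def exact_transport(a: np.ndarray, b: np.ndarray, cost: np.ndarray):
    """Return ``(coupling, objective)`` for the exact OT problem.

    Parameters
    ----------
    a, b : 1D non-negative arrays with equal sums (within ``MARGINAL_TOL``).
    cost : 2D array of shape ``(len(a), len(b))``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    cost = np.asarray(cost, dtype=float)
    m, n = a.size, b.size
    if cost.shape != (m, n):
        raise ValueError(f"cost shape {cost.shape} does not match marginals ({m}, {n})")
    if a.min() < 0 or b.min() < 0:
        raise ValueError("marginals must be non-negative")
    if abs(a.sum() - b.sum()) > MARGINAL_TOL:
        raise ValueError(
            f"infeasible marginals: sums differ by {abs(a.sum() - b.sum()):.3g}"
        )

    # row-sum constraints, plus column sums with the last (redundant) dropped
    rows = sparse.kron(sparse.eye(m, format="csr"), np.ones((1, n)), format="csr")
    cols = sparse.kron(np.ones((1, m)), sparse.eye(n, format="csr"), format="csr")[:-1]
    a_eq = sparse.vstack([rows, cols], format="csr")
    b_eq = np.concatenate([a, b[:-1]])

    res = linprog(
        cost.ravel(),
        A_eq=a_eq,
        b_eq=b_eq,
        bounds=(0, None),
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"optimal transport LP failed: {res.message}")
    coupling = np.clip(res.x.reshape(m, n), 0.0, None)
    objective = float(np.sum(cost * coupling))
    return coupling, objective
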