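"""Internal numerical kernels: LP wrapper and a box/affine projection QP.

Both quadratic programs the pipeline needs — the cone projection that builds
the flux objective, and the l2-norm minimization that picks the unique flux —
are Euclidean projections of a point onto {v : Av = b, lb <= v <= ub}.
They are solved by Dykstra's alternating-projection scheme (projection onto
the affine set via the pseudoinverse, onto the box by clipping), followed by
an active-set polish that solves the equality-constrained KKT system exactly
on the guessed active set.  Problems here are desk-scale (tens to a few
hundred variables), where this is fast and accurate to ~1e-10.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

# Centralized numerical tolerances
FEASIBILITY_TOL = 1e-6      # constraint-residual tolerance for feasibility claims
UNIQUENESS_TOL = 1e-5       # agreement required between independent solves
SOLVER_TOL = 1e-9           # internal convergence target


class SolverError(RuntimeError):
    """LP/QP failed: infeasible, unbounded, or did not converge."""


def solve_lp_max(
    c: np.ndarray,
    A_eq: np.ndarray,
    b_eq: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
):
    """max c.v  s.t.  A_eq v = b_eq, lb <= v <= ub.  Returns (v, optimum)."""
    res = linprog(
        -np.asarray(c, float),
        A_eq=A_eq if A_eq is not None and len(A_eq) else None,
        b_eq=b_eq if A_eq is not None and len(A_eq) else None,
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status == 2:
        raise SolverError("LP infeasible")
    if res.status == 3:
        raise SolverError("LP unbounded — review reaction bounds")
    if not res.success:
        raise SolverError(f"LP solver failure: {res.message}")
    return res.x, -res.fun


def lp_feasible(
    A_eq: np.ndarray,
    b_eq: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    tol: float = FEASIBILITY_TOL,
):
    """Feasibility test for {A_eq v = b_eq, lb <= v <= ub}.

    Returns (feasible, witness_or_None).  Decided by a zero-objective LP at
    the stated tolerance.
    """
    res = linprog(
        np.zeros(len(lb)),
        A_eq=A_eq if len(A_eq) else None,
        b_eq=b_eq if len(A_eq) else None,
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if not res.success:
        return False, None
    resid = np.abs(A_eq @ res.x - b_eq).max() if len(A_eq) else 0.0
    if resid > tol:
        return False, None
    return True, res.x


def project_box_affine(
    target: np.ndarray,
    A: np.ndarray,
    b: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    max_iter: int = 20000,
    tol: float = 1e-12,
    feasible_point: np.ndarray | None = None,
) -> np.ndarray:
    """min ||v - target||^2  s.t.  A v = b, lb <= v <= ub.

    Dykstra alternating projections, then active-set polish (also seeded
    from ``feasible_point`` when supplied, e.g. an LP vertex of the same
    constraint set, which doubles as a guaranteed-feasible fallback).
    Raises SolverError if the intersection appears empty.
    """
    target = np.asarray(target, float)
    lb = np.asarray(lb, float)
    ub = np.asarray(ub, float)
    n = target.size
    if A is None or len(A) == 0:
        return np.clip(target, lb, ub)
    A = np.asarray(A, float)
    b = np.asarray(b, float)
    pinv_A = np.linalg.pinv(A)

    def proj_affine(z):
        return z - pinv_A @ (A @ z - b)

    x = np.clip(target, lb, ub)
    p = np.zeros(n)
    q = np.zeros(n)
    prev = x.copy()
    for it in range(max_iter):
        y = proj_affine(x + p)
        p = x + p - y
        x = np.clip(y + q, lb, ub)
        q = y + q - x
        if it % 25 == 24:
            if np.abs(x - prev).max() < tol and np.abs(A @ x - b).max() < 1e-9:
                break
            prev = x.copy()

    v = proj_affine(x)  # final affine snap (box may be slightly violated)
    polished = _active_set_polish(target, A, b, lb, ub, x)
    candidates = []
    starts = [polished, v, x]
    if feasible_point is not None:
        starts.append(_active_set_polish(target, A, b, lb, ub, feasible_point))
        starts.append(np.asarray(feasible_point, float))
    for cand in starts:
        if cand is None:
            continue
        resid = np.abs(A @ cand - b).max()
        box_viol = max(float((lb - cand).max(initial=0.0)),
                       float((cand - ub).max(initial=0.0)))
        if resid < 1e-8 and box_viol < 1e-8:
            candidates.append((float(np.sum((cand - target) ** 2)), resid, cand))
    if not candidates:
        raise SolverError("projection QP failed: no feasible point found")
    candidates.sort(key=lambda t: (t[0], t[1]))
    best = np.clip(candidates[0][2], lb, ub)
    return best


def _active_set_polish(target, A, b, lb, ub, v0, max_iter: int = 80):
    """Exact KKT solve on the active set guessed from v0; grows the set on
    bound violations.  Returns None if it cannot produce a feasible point."""
    n = v0.size
    eps = 1e-7
    active_lo = v0 <= lb + eps
    active_hi = (v0 >= ub - eps) & ~active_lo
    for _ in range(max_iter):
        fixed = active_lo | active_hi
        vals = np.zeros(n)
        vals[active_lo] = lb[active_lo]
        vals[active_hi] = ub[active_hi]
        free = ~fixed
        rhs = b - A[:, fixed] @ vals[fixed]
        if not free.any():
            v = vals
            if np.abs(A @ v - b).max() < 1e-8:
                return v
            return None
        Af = A[:, free]
        tf = target[free]
        G = Af @ Af.T
        lam, *_ = np.linalg.lstsq(G, Af @ tf - rhs, rcond=None)
        vf = tf - Af.T @ lam
        v = vals.copy()
        v[free] = vf
        viol_lo = free & (v < lb - 1e-10)
        viol_hi = free & (v > ub + 1e-10)
        if not viol_lo.any() and not viol_hi.any():
            if np.abs(A @ v - b).max() < 1e-8:
                return v
            return None
        active_lo |= viol_lo
        active_hi |= viol_hi
    return None
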