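"""Expression-guided flux prediction: SPOT objective and E-Flux2 solve.

The objective direction f' is the feasible flux direction best aligned with
the per-reaction expression scores g — the maximizer of the uncentered
cosine g.v / (||g|| ||v||) over steady-state, sign-split non-negative
fluxes.  Because that feasible set is a convex cone C and the cosine is
scale-invariant, the optimum equals ||P_C(g)|| attained at P_C(g)/||P_C(g)||,
where P_C is Euclidean projection onto the cone — one projection QP.

Flux prediction then runs two stages: (1) FBA — maximize f'.v subject to
S.v = 0 and expression-derived bounds (score g_j caps each reaction at
[0, g_j], or [-g_j, g_j] if reversible; no-GPR and exchange reactions keep
parent bounds); (2) among the stage-1 optima, minimize the Euclidean norm
||v||^2, whose strictly convex objective makes the returned flux unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._solvers import (
    FEASIBILITY_TOL,
    SOLVER_TOL,
    UNIQUENESS_TOL,
    SolverError,
    project_box_affine,
    solve_lp_max,
)
from .context_extraction import ContextModel
from .expression import ReactionScoreVector
from .model_core import MetabolicModel, stoichiometric_matrix

__all__ = [
    "SpotObjective",
    "FluxResult",
    "spot_objective",
    "eflux2_bounds",
    "eflux2_solve",
    "measurable_fluxes",
    "MEASURABLE_FLUX_THRESHOLD",
]

#: |v| above which a flux counts as measurable (mmol/gDW/h), strict inequality
MEASURABLE_FLUX_THRESHOLD = 0.1


@dataclass
class SpotObjective:
    """Unit-norm objective direction aligned with expression scores."""

    f_prime: dict[str, float]
    achieved_cosine: float
    split_map: dict[str, tuple[float, float]] = field(default_factory=dict)
    degenerate: bool = False


@dataclass
class FluxResult:
    """Unique flux vector from the two-stage solve, with diagnostics."""

    state: str
    fluxes: dict[str, float]
    z_star: float
    residual: float
    l2_norm: float
    solver_status: str = "optimal"

    def as_series(self) -> pd.Series:
        return pd.Series(self.fluxes, name=self.state)


def _context_order(parent: MetabolicModel, context: ContextModel) -> list[str]:
    kept = context.kept_reactions
    return [r for r in parent.reaction_ids if r in kept]


def _score_vector(order, scores: ReactionScoreVector) -> np.ndarray:
    return np.array([scores.scores.get(r, 0.0) for r in order])


def spot_objective(
    parent: MetabolicModel,
    context: ContextModel,
    scores: ReactionScoreVector,
    apply_bounds: dict[str, tuple[float, float]] | None = None,
    centered: bool = False,
) -> SpotObjective:
    """Best-aligned feasible flux direction for a context model.

    Reversible reactions are split into non-negative forward/backward
    components, each inheriting the reaction's score; no-GPR reactions get
    weight 0.  ``apply_bounds`` optionally zeroes directions whose
    expression-derived upper bound is 0 (bounding the ratio objective only
    matters through which directions are shut, since it is scale-invariant).
    ``centered`` subtracts the mean score first (a Pearson-flavoured
    variant; the default is the plain cosine).
    """
    order = _context_order(parent, context)
    S, _, _ = stoichiometric_matrix(parent, order)
    g = _score_vector(order, scores)
    reversible = np.array([parent.reaction(r).lower_bound < 0 for r in order])

    # split space: forward columns for all, backward columns for reversibles
    back_idx = np.where(reversible)[0]
    S_split = np.hstack([S, -S[:, back_idx]]) if len(back_idx) else S
    g_split = np.concatenate([g, g[back_idx]]) if len(back_idx) else g.copy()
    if centered:
        g_split = g_split - g_split.mean()
    n_split = S_split.shape[1]
    ub = np.full(n_split, np.inf)
    if apply_bounds is not None:
        for j, r in enumerate(order):
            lo, hi = apply_bounds[r]
            if hi <= 0:
                ub[j] = 0.0
        for k, j in enumerate(back_idx):
            lo, hi = apply_bounds[order[j]]
            if lo >= 0:
                ub[len(order) + k] = 0.0

    g_norm = float(np.linalg.norm(g_split))
    if g_norm < SOLVER_TOL:
        return SpotObjective(
            f_prime={r: 0.0 for r in order}, achieved_cosine=0.0, degenerate=True
        )
    w = project_box_affine(
        g_split, S_split, np.zeros(S_split.shape[0]), np.zeros(n_split), ub
    )
    w_norm = float(np.linalg.norm(w))
    if w_norm < 1e-9:
        return SpotObjective(
            f_prime={r: 0.0 for r in order}, achieved_cosine=0.0, degenerate=True
        )
    cosine = float(np.clip(w @ g_split / (w_norm * g_norm), 0.0, 1.0))

    # map back: net flux per reaction, futile forward/backward overlap cancelled
    v = w[: len(order)].copy()
    split_map: dict[str, tuple[float, float]] = {}
    for k, j in enumerate(back_idx):
        wf, wb = w[j], w[len(order) + k]
        split_map[order[j]] = (float(wf), float(wb))
        v[j] = wf - wb
    v_norm = float(np.linalg.norm(v))
    if v_norm < 1e-12:
        return SpotObjective(
            f_prime={r: 0.0 for r in order},
            achieved_cosine=cosine,
            split_map=split_map,
            degenerate=True,
        )
    v /= v_norm
    return SpotObjective(
        f_prime={r: float(v[j]) for j, r in enumerate(order)},
        achieved_cosine=cosine,
        split_map=split_map,
    )


def eflux2_bounds(
    parent: MetabolicModel,
    context: ContextModel,
    scores: ReactionScoreVector,
) -> dict[str, tuple[float, float]]:
    """Expression-derived flux bounds per kept reaction.

    Scored reaction: [0, g] if irreversible, [-g, g] if reversible.
    No-GPR and exchange reactions keep the parent bounds (no expression
    evidence either way; boundary fluxes stay free).
    """
    out: dict[str, tuple[float, float]] = {}
    for r in _context_order(parent, context):
        rxn = parent.reaction(r)
        if r in scores.no_gpr or parent.is_exchange(r):
            out[r] = (rxn.lower_bound, rxn.upper_bound)
        else:
            gj = scores.scores.get(r, 0.0)
            out[r] = (-gj, gj) if rxn.lower_bound < 0 else (0.0, gj)
    return out


def eflux2_solve(
    parent: MetabolicModel,
    context: ContextModel,
    objective: SpotObjective,
    bounds: dict[str, tuple[float, float]],
) -> FluxResult:
    """Two-stage flux solve: FBA on f', then minimal-l2 flux among its optima.

    Stage 1 (LP): z* = max f'.v subject to S.v = 0 and bounds.
    Stage 2 (QP): min sum v_j^2 subject to the same constraints and
    f'.v = z*.  The stage-2 solution is unique, so independent solves must
    agree to within the uniqueness tolerance.
    """
    order = _context_order(parent, context)
    S, _, _ = stoichiometric_matrix(parent, order)
    f = np.array([objective.f_prime.get(r, 0.0) for r in order])
    lb = np.array([bounds[r][0] for r in order])
    ub = np.array([bounds[r][1] for r in order])
    b0 = np.zeros(S.shape[0])

    v1, z_star = solve_lp_max(f, S, b0, lb, ub)

    A = np.vstack([S, f])
    last_err = None
    for backoff in (0.0, 1e-9, 1e-7):
        zt = z_star - backoff * max(1.0, abs(z_star))
        try:
            v = project_box_affine(
                np.zeros(len(order)), A, np.concatenate([b0, [zt]]), lb, ub,
                feasible_point=v1 if backoff == 0.0 else None,
            )
            break
        except SolverError as exc:  # z* at the boundary of feasibility
            last_err = exc
    else:
        raise last_err
    residual = float(np.abs(S @ v).max()) if S.shape[0] else 0.0
    result = FluxResult(
        state=context.state,
        fluxes={r: float(v[j]) for j, r in enumerate(order)},
        z_star=float(z_star),
        residual=residual,
        l2_norm=float(np.linalg.norm(v)),
    )
    obj_gap = abs(f @ v - z_star)
    if residual > FEASIBILITY_TOL or obj_gap > FEASIBILITY_TOL * max(1.0, abs(z_star)):
        result.solver_status = (
            f"tolerance_warning(residual={residual:.2e}, obj_gap={obj_gap:.2e})"
        )
    return result


def measurable_fluxes(
    results: list[FluxResult],
    threshold: float = MEASURABLE_FLUX_THRESHOLD,
) -> pd.DataFrame:
    """Reactions x states table of signed fluxes, restricted to reactions
    with |v| strictly above ``threshold`` in at least one state.

    A reaction absent from a state's context carries flux 0 in that column.
    Warns if nothing clears the threshold.
    """
    if not results:
        raise ValueError("no flux results supplied")
    cols = {}
    for res in results:
        cols[res.state] = pd.Series(res.fluxes)
    table = pd.DataFrame(cols).fillna(0.0)
    table = table[sorted(table.columns)]
    keep = table.abs().gt(threshold).any(axis=1)
    out = table.loc[keep].sort_index()
    if out.empty:
        import warnings

        warnings.warn(f"no fluxes exceed the measurable threshold {threshold}")
    return out
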