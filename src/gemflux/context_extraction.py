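"""Context-specific model extraction: TPM-threshold rule, tasks, gap-filling.

A context model for a disease state keeps the reactions whose GPR expression
score exceeds a TPM threshold (strict >, default 1 TPM); reactions without a
gene rule are retained by default since the rule only excludes via genes.
A metabolic task list (produce stated outputs from allowed inputs at steady
state) then guards viability: any task the trimmed model cannot perform is
rescued by adding back a minimal set of excluded parent reactions, tagged
``task_rescued`` so structural analyses can separate expression evidence
from viability rescue.

Extraction here implements exactly the published threshold + task-rescue
rule; it deliberately does not optimize a weighted inclusion objective.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from ._solvers import FEASIBILITY_TOL, lp_feasible, solve_lp_max, SolverError
from .expression import ReactionScoreVector
from .model_core import MetabolicModel, Metabolite, Reaction, parse_gpr

__all__ = [
    "MetabolicTask",
    "TaskReport",
    "ContextModel",
    "threshold_extract",
    "check_task",
    "gap_fill",
    "read_tasks",
    "write_tasks",
    "context_to_model",
]

EXPRESSION_SUPPORTED = "expression_supported"
TASK_RESCUED = "task_rescued"
NO_GPR_RETAINED = "no_gpr_retained"

#: above this many excluded-reaction candidates the exact minimal-set search
#: hands over to the documented greedy
EXACT_GAPFILL_CUTOFF = 20

_DEMAND_CAP = 1e4  # upper bound on task demand fluxes (finite for the LP)


@dataclass
class MetabolicTask:
    """A viability requirement: produce outputs from allowed inputs.

    inputs: (metabolite id, max uptake); outputs: (metabolite id, min
    production), with at least one strictly positive minimum.
    """

    id: str
    inputs: list[tuple[str, float]]
    outputs: list[tuple[str, float]]
    description: str = ""

    def validate(self) -> None:
        if not any(m > 0 for _, m in self.outputs):
            raise ValueError(f"task {self.id!r}: no output with min production > 0")


@dataclass
class TaskReport:
    task_id: str
    feasible: bool
    witness: dict[str, float] | None = None


@dataclass
class ContextModel:
    """A state-specific sub-model: kept reactions with provenance tags."""

    parent_id: str
    state: str
    kept_reactions: set[str]
    provenance: dict[str, str]
    threshold: float
    gap_fill_mode: str | None = None

    def reactions_by_tag(self, tag: str) -> set[str]:
        return {r for r, t in self.provenance.items() if t == tag}

    def to_json(self, path) -> None:
        payload = {
            "parent": self.parent_id,
            "state": self.state,
            "threshold": self.threshold,
            "gap_fill_mode": self.gap_fill_mode,
            "kept_reactions": sorted(self.kept_reactions),
            "provenance": {r: self.provenance[r] for r in sorted(self.provenance)},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ContextModel":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            parent_id=raw["parent"],
            state=raw["state"],
            kept_reactions=set(raw["kept_reactions"]),
            provenance=dict(raw["provenance"]),
            threshold=raw["threshold"],
            gap_fill_mode=raw.get("gap_fill_mode"),
        )


def threshold_extract(
    model: MetabolicModel,
    scores: ReactionScoreVector,
    threshold: float = 1.0,
    keep_no_gpr: bool = True,
) -> ContextModel:
    """Keep reactions whose GPR score is strictly above ``threshold`` TPM.

    No-GPR reactions are retained (tag ``no_gpr_retained``) unless
    ``keep_no_gpr`` is False.  Lowering the threshold never shrinks the
    kept set.
    """
    scores.coverage_check(model)
    kept: set[str] = set()
    provenance: dict[str, str] = {}
    for rxn_id, g in scores.scores.items():
        if g > threshold:
            kept.add(rxn_id)
            provenance[rxn_id] = EXPRESSION_SUPPORTED
    if keep_no_gpr:
        for rxn_id in scores.no_gpr:
            kept.add(rxn_id)
            provenance[rxn_id] = NO_GPR_RETAINED
    return ContextModel(
        parent_id=model.model_id,
        state=scores.state,
        kept_reactions=kept,
        provenance=provenance,
        threshold=threshold,
    )


def _task_lp(model: MetabolicModel, task: MetabolicTask, reaction_ids):
    """Assemble the steady-state LP for a task on a reaction subset.

    Temporary uptake columns (one per input, bounds [0, max]) produce the
    input metabolite; temporary demand columns (bounds [min, cap]) consume
    each output.  Returns (A_eq, b_eq, lb, ub, rxn_order).
    """
    task.validate()
    known = {m.id for m in model.metabolites}
    for met_id, _ in task.inputs + task.outputs:
        if met_id not in known:
            raise ValueError(f"task {task.id!r} references unknown metabolite {met_id!r}")
    if reaction_ids is None:
        rxns = list(model.reactions)
    else:
        keep = set(reaction_ids)
        rxns = [r for r in model.reactions if r.id in keep]
    met_pos: dict[str, int] = {}
    for r in rxns:
        for m in r.stoichiometry:
            met_pos.setdefault(m, len(met_pos))
    for met_id, _ in task.inputs + task.outputs:
        met_pos.setdefault(met_id, len(met_pos))
    n_rxn = len(rxns)
    n_in = len(task.inputs)
    n_out = len(task.outputs)
    A = np.zeros((len(met_pos), n_rxn + n_in + n_out))
    lb = np.zeros(n_rxn + n_in + n_out)
    ub = np.zeros(n_rxn + n_in + n_out)
    for j, r in enumerate(rxns):
        for m, coef in r.stoichiometry.items():
            A[met_pos[m], j] = coef
        lb[j], ub[j] = r.lower_bound, r.upper_bound
    for k, (met_id, max_up) in enumerate(task.inputs):
        j = n_rxn + k
        A[met_pos[met_id], j] = 1.0
        lb[j], ub[j] = 0.0, max_up
    for k, (met_id, min_prod) in enumerate(task.outputs):
        j = n_rxn + n_in + k
        A[met_pos[met_id], j] = -1.0
        lb[j], ub[j] = min_prod, _DEMAND_CAP
    return A, np.zeros(len(met_pos)), lb, ub, [r.id for r in rxns]


def check_task(
    model: MetabolicModel,
    task: MetabolicTask,
    reaction_ids=None,
) -> TaskReport:
    """Can the (sub)model perform the task at steady state?

    Feasibility is decided by LP at constraint-residual tolerance 1e-6;
    a witness flux over the sub-model's reactions is returned when feasible.
    ``reaction_ids`` restricts to a context model's kept reactions; None
    tests the full model.
    """
    A, b, lb, ub, order = _task_lp(model, task, reaction_ids)
    feasible, x = lp_feasible(A, b, lb, ub, tol=FEASIBILITY_TOL)
    witness = None
    if feasible:
        witness = {rxn_id: float(x[j]) for j, rxn_id in enumerate(order)}
    return TaskReport(task_id=task.id, feasible=feasible, witness=witness)


def _all_tasks_pass(model, tasks, reaction_ids) -> bool:
    return all(check_task(model, t, reaction_ids).feasible for t in tasks)


def gap_fill(
    context: ContextModel,
    parent: MetabolicModel,
    tasks: list[MetabolicTask],
) -> ContextModel:
    """Add back a minimal set of excluded parent reactions so every task passes.

    Exact minimal-cardinality subset search (increasing cardinality,
    candidates in lexicographic id order so ties resolve to the smallest
    set, then smallest ids) when there are at most EXACT_GAPFILL_CUTOFF
    excluded candidates; otherwise a documented greedy that repeatedly adds
    the excluded reaction carrying the most flux in an L1-relaxed task LP.
    Added reactions are tagged ``task_rescued``.
    """
    for task in tasks:
        if not check_task(parent, task).feasible:
            raise ValueError(
                f"task {task.id!r} is infeasible on the parent model; cannot gap-fill"
            )
    kept = set(context.kept_reactions)
    if _all_tasks_pass(parent, tasks, kept):
        return ContextModel(
            parent_id=context.parent_id,
            state=context.state,
            kept_reactions=kept,
            provenance=dict(context.provenance),
            threshold=context.threshold,
            gap_fill_mode="none_needed",
        )
    candidates = sorted(set(parent.reaction_ids) - kept)
    if len(candidates) <= EXACT_GAPFILL_CUTOFF:
        added, mode = _exact_gap_fill(parent, tasks, kept, candidates), "exact"
    else:
        added, mode = _greedy_gap_fill(parent, tasks, kept, candidates), "greedy"
    if added is None:
        raise SolverError("gap-fill failed to restore task feasibility")
    provenance = dict(context.provenance)
    for r in sorted(added):
        provenance[r] = TASK_RESCUED
    return ContextModel(
        parent_id=context.parent_id,
        state=context.state,
        kept_reactions=kept | added,
        provenance=provenance,
        threshold=context.threshold,
        gap_fill_mode=mode,
    )


def _exact_gap_fill(parent, tasks, kept, candidates):
    for k in range(1, len(candidates) + 1):
        for subset in itertools.combinations(candidates, k):
            if _all_tasks_pass(parent, tasks, kept | set(subset)):
                return set(subset)
    return None


def _greedy_gap_fill(parent, tasks, kept, candidates):
    added: set[str] = set()
    cand_set = set(candidates)
    for _ in range(len(candidates)):
        failing = [t for t in tasks if not check_task(parent, t, kept | added).feasible]
        if not failing:
            return added
        usage = _candidate_usage(parent, failing[0], sorted(cand_set - added))
        if usage is None or not usage:
            return None
        # most-used candidate; ties to the lexicographically smaller id
        best = max(sorted(usage), key=lambda r: usage[r])
        if usage[best] <= 1e-9:
            return None
        added.add(best)
    return added if _all_tasks_pass(parent, tasks, kept | added) else None


def _candidate_usage(parent, task, candidates):
    """L1-relaxed task LP on the full parent: minimize total |flux| through
    candidate reactions; returns candidate -> |flux| at the optimum."""
    A, b, lb, ub, order = _task_lp(parent, task, None)
    n = A.shape[1]
    cand_pos = [order.index(c) for c in candidates]
    # aux t_i >= |v_i| for candidates: minimize sum t
    n_aux = len(cand_pos)
    A_eq = np.hstack([A, np.zeros((A.shape[0], n_aux))])
    A_ub = np.zeros((2 * n_aux, n + n_aux))
    for k, j in enumerate(cand_pos):
        A_ub[2 * k, j] = 1.0
        A_ub[2 * k, n + k] = -1.0
        A_ub[2 * k + 1, j] = -1.0
        A_ub[2 * k + 1, n + k] = -1.0
    c = np.zeros(n + n_aux)
    c[n:] = 1.0
    from scipy.optimize import linprog

    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=b,
        A_ub=A_ub,
        b_ub=np.zeros(2 * n_aux),
        bounds=list(zip(lb, ub)) + [(0, None)] * n_aux,
        method="highs",
    )
    if not res.success:
        return None
    return {candidates[k]: float(abs(res.x[cand_pos[k]])) for k in range(n_aux)}


# ---------------------------------------------------------------------------
# Task list and context-model I/O
# ---------------------------------------------------------------------------

def read_tasks(path) -> list[MetabolicTask]:
    with open(path) as fh:
        raw = json.load(fh)
    tasks = []
    for t in raw:
        task = MetabolicTask(
            id=t["id"],
            inputs=[(i["metabolite"], float(i["max"])) for i in t["inputs"]],
            outputs=[(o["metabolite"], float(o["min"])) for o in t["outputs"]],
            description=t.get("description", ""),
        )
        task.validate()
        tasks.append(task)
    return tasks


def write_tasks(tasks: list[MetabolicTask], path) -> None:
    payload = [
        {
            "id": t.id,
            "description": t.description,
            "inputs": [{"metabolite": m, "max": v} for m, v in t.inputs],
            "outputs": [{"metabolite": m, "min": v} for m, v in t.outputs],
        }
        for t in tasks
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def context_to_model(parent: MetabolicModel, context: ContextModel) -> MetabolicModel:
    """Materialize a context model as a stand-alone MetabolicModel subset."""
    kept = context.kept_reactions
    reactions = [r for r in parent.reactions if r.id in kept]
    used_mets = sorted({m for r in reactions for m in r.stoichiometry})
    metabolites = [parent.metabolite(m) for m in used_mets]
    genes = sorted(
        {
            g
            for r in reactions
            if (tree := parse_gpr(r.gpr)) is not None
            for g in tree.genes()
        }
    )
    comps = sorted({m.compartment for m in metabolites})
    return MetabolicModel(
        model_id=f"{parent.model_id}__{context.state}",
        reactions=reactions,
        metabolites=metabolites,
        genes=genes,
        compartments=comps,
        compartment_names={c: parent.compartment_names.get(c, c) for c in comps},
    )
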