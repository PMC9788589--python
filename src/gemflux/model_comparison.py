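"""Structural comparison of extracted context models.

Context models from one parent are compared as binary presence vectors over
the union of their reactions (1 = kept, 0 = dropped).  Hamming similarity
between two models is the fraction of agreeing rows.  Models are also rank
ordered by reaction / metabolite / gene / unique-gene-rule counts, screened
per subsystem for pairs differing by more than a percentage, and the
differing reactions drilled down to their (canonicalized) gene rules with
z-scored gene expression across states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .context_extraction import ContextModel
from .expression import StateProfile
from .model_core import MetabolicModel, canonical_gpr, parse_gpr

__all__ = [
    "presence_matrix",
    "hamming_similarity",
    "rank_models",
    "differential_subsystems",
    "gene_rule_drilldown",
    "DrilldownReport",
]


def _check_shared_parent(models: list[ContextModel]) -> None:
    if len(models) < 2:
        raise ValueError("need at least two context models to compare")
    parents = {m.parent_id for m in models}
    if len(parents) > 1:
        raise ValueError(f"models come from different parents: {sorted(parents)}")


def presence_matrix(
    models: list[ContextModel],
    parent: MetabolicModel | None = None,
) -> pd.DataFrame:
    """Binary reactions x models matrix over the union reaction set.

    Rows follow the parent model's reaction order when the parent is given,
    otherwise sorted reaction ids; columns are the models' state labels.
    """
    _check_shared_parent(models)
    union = set()
    for m in models:
        union |= m.kept_reactions
    if parent is not None:
        rows = [r for r in parent.reaction_ids if r in union]
    else:
        rows = sorted(union)
    data = {
        m.state: [1 if r in m.kept_reactions else 0 for r in rows] for m in models
    }
    return pd.DataFrame(data, index=rows)


def hamming_similarity(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise model similarity: 1 - (disagreeing rows)/(total rows).

    Symmetric with unit diagonal; 1 - similarity is a scaled Hamming metric.
    """
    if matrix.empty:
        raise ValueError("empty presence matrix")
    X = matrix.values
    n_rows = X.shape[0]
    cols = list(matrix.columns)
    sim = np.zeros((len(cols), len(cols)))
    for i in range(len(cols)):
        for j in range(len(cols)):
            sim[i, j] = 1.0 - np.sum(X[:, i] != X[:, j]) / n_rows
    return pd.DataFrame(sim, index=cols, columns=cols)


def _model_counts(model: ContextModel, parent: MetabolicModel) -> dict[str, int]:
    kept = model.kept_reactions
    mets = set()
    genes = set()
    rules = set()
    for r in parent.reactions:
        if r.id not in kept:
            continue
        mets.update(r.stoichiometry)
        tree = parse_gpr(r.gpr)
        if tree is not None:
            genes.update(tree.genes())
            rules.add(canonical_gpr(tree))
    return {
        "reactions": len(kept),
        "metabolites": len(mets),
        "genes": len(genes),
        "unique_gene_rules": len(rules),
    }


def rank_models(models: list[ContextModel], parent: MetabolicModel) -> pd.DataFrame:
    """Counts and ranks per model for reactions, metabolites, genes and
    unique canonical gene rules.  Rank 1 = largest; ties share the mean rank.
    """
    _check_shared_parent(models)
    counts = pd.DataFrame(
        {m.state: _model_counts(m, parent) for m in models}
    ).T  # models x metrics
    out = counts.copy()
    for col in counts.columns:
        out[f"{col}_rank"] = rankdata(-counts[col].values, method="average")
    return out


def differential_subsystems(
    models: list[ContextModel],
    parent: MetabolicModel,
    pct: float = 10.0,
) -> pd.DataFrame:
    """Per-subsystem reaction counts per model, flagged when some model pair
    differs by more than ``pct`` percent (relative to the larger count).

    Also reports the number of reactions common to all models per subsystem.
    Sorted by total subsystem size (descending), invariant to model order.
    """
    _check_shared_parent(models)
    subsystems = sorted({r.subsystem for r in parent.reactions})
    states = sorted(m.state for m in models)
    by_state = {m.state: m.kept_reactions for m in models}
    rows = []
    for sub in subsystems:
        sub_rxns = [r.id for r in parent.reactions if r.subsystem == sub]
        counts = {s: sum(1 for r in sub_rxns if r in by_state[s]) for s in states}
        common = sum(1 for r in sub_rxns if all(r in by_state[s] for s in states))
        max_rel = 0.0
        vals = [counts[s] for s in states]
        for i in range(len(vals)):
            for j in range(i + 1, len(vals)):
                a, b = vals[i], vals[j]
                if max(a, b) == 0:
                    continue  # 0/0 pair carries no signal
                max_rel = max(max_rel, abs(a - b) / max(a, b))
        rows.append(
            {
                "subsystem": sub,
                **counts,
                "common": common,
                "parent_total": len(sub_rxns),
                "max_rel_diff_pct": 100.0 * max_rel,
                "flagged": max_rel > pct / 100.0,
            }
        )
    out = pd.DataFrame(rows).set_index("subsystem")
    return out.sort_values("parent_total", ascending=False, kind="mergesort")


@dataclass
class DrilldownReport:
    """Gene-rule drill-down of reactions that differ across models."""

    subsystems: list[str]
    differing_reactions: list[str]
    n_with_rules: int
    rule_counts: pd.DataFrame          # canonical rule x model: reaction counts
    gene_zscores: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_unique_rules(self) -> int:
        return len(self.rule_counts)


def gene_rule_drilldown(
    models: list[ContextModel],
    parent: MetabolicModel,
    subsystems: list[str],
    state_profiles: list[StateProfile] | None = None,
) -> DrilldownReport:
    """Collect reactions in the given subsystems NOT common to all models,
    collapse them to unique canonical gene rules, count per-model reactions
    per rule, and z-score the rules' genes across state profiles.
    """
    _check_shared_parent(models)
    parent_subs = {r.subsystem for r in parent.reactions}
    missing = [s for s in subsystems if s not in parent_subs]
    if missing:
        raise ValueError(f"subsystems absent from the parent model: {missing}")
    states = sorted(m.state for m in models)
    by_state = {m.state: m.kept_reactions for m in models}
    differing = []
    for r in parent.reactions:
        if r.subsystem not in subsystems:
            continue
        presence = [r.id in by_state[s] for s in states]
        if any(presence) and not all(presence):
            differing.append(r.id)
    with_rules = [r for r in differing if parent.reaction(r).gpr.strip()]
    rules = sorted({canonical_gpr(parent.reaction(r).gpr) for r in with_rules})
    counts = pd.DataFrame(0, index=rules, columns=states)
    for r in with_rules:
        rule = canonical_gpr(parent.reaction(r).gpr)
        for s in states:
            if r in by_state[s]:
                counts.loc[rule, s] += 1
    genes = sorted(
        {
            g
            for r in with_rules
            for g in parse_gpr(parent.reaction(r).gpr).genes()
        }
    )
    z = pd.DataFrame()
    if state_profiles is not None and genes:
        expr = pd.DataFrame(
            {p.state: [p.gene_values.get(g, 0.0) for g in genes] for p in state_profiles},
            index=genes,
        )
        mu = expr.mean(axis=1)
        sd = expr.std(axis=1, ddof=0)
        z = expr.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    return DrilldownReport(
        subsystems=list(subsystems),
        differing_reactions=differing,
        n_with_rules=len(with_rules),
        rule_counts=counts,
        gene_zscores=z,
    )
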