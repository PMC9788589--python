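"""Downstream flux statistics: subsystem sums, Wilcoxon screens, clustering,
transport-cluster gene rules and import/export mapping.

Subsystem activity per state is the sum of flux magnitudes over the
subsystem's reactions (reversible-flux sign is solver-convention dependent,
so magnitudes are the default; a signed option exists).  State pairs are
screened with two-sided Wilcoxon rank-sum tests using per-reaction fluxes
within a subsystem as replicate units, raw p < alpha with no multiplicity
correction by default (a Benjamini-Hochberg option exists).  Flux or
expression matrices are hierarchically clustered (average linkage on a
1 - Pearson distance between z-scored rows).  For transport clusters, gene
rules are counted per cluster and species are mapped to import/export
relative to a designated interior compartment, keeping only species moved
in exactly one direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu

from .model_core import MetabolicModel, canonical_gpr

__all__ = [
    "SubsystemFluxTable",
    "ClusterAssignment",
    "GeneRuleFrequencyTable",
    "subsystem_flux_sums",
    "wilcoxon_rank_sum",
    "subsystem_screen",
    "hierarchical_cluster",
    "gene_rule_frequency",
    "transport_direction_map",
    "INTERIOR_COMPARTMENT",
]

#: compartment treated as the cell interior when orienting transport
INTERIOR_COMPARTMENT = "c"

#: sample sizes up to which the untied Wilcoxon p-value is computed exactly
EXACT_WILCOXON_MAX_N = 16


@dataclass
class SubsystemFluxTable:
    sums: pd.DataFrame              # subsystem x state summed |v|
    reaction_counts: pd.Series      # subsystem -> number of contributing reactions


@dataclass
class ClusterAssignment:
    assignments: dict[str, int]     # item -> cluster id (1..k)
    k: int
    linkage_method: str
    distance: str
    dendrogram_order: list[str]

    def members(self, cluster_id: int) -> list[str]:
        return sorted(i for i, c in self.assignments.items() if c == cluster_id)


@dataclass
class GeneRuleFrequencyTable:
    per_cluster: dict[int, pd.DataFrame]   # rule, count, fraction (of cluster size)
    most_frequent: dict[int, tuple[str, int, float]]
    no_gpr_counts: dict[int, int] = field(default_factory=dict)
    ties: dict[int, list[str]] = field(default_factory=dict)


def subsystem_flux_sums(
    flux_table: pd.DataFrame,
    model: MetabolicModel,
    signed: bool = False,
) -> SubsystemFluxTable:
    """Sum fluxes per subsystem per state (|v| by default)."""
    unknown = [r for r in flux_table.index if r not in set(model.reaction_ids)]
    if unknown:
        raise ValueError(f"flux table reactions not in model: {unknown[:5]}")
    vals = flux_table if signed else flux_table.abs()
    sub = pd.Series({r: model.subsystem_of(r) for r in flux_table.index})
    sums = vals.groupby(sub).sum()
    counts = sub.groupby(sub).count()
    counts.name = "n_reactions"
    return SubsystemFluxTable(sums=sums.sort_index(), reaction_counts=counts.sort_index())


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum statistic W, p).

    W is the sum of midranks of ``x`` in the pooled sample.  The p-value is
    exact when n + m <= 16 and there are no ties, and a tie- and
    continuity-corrected normal approximation otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size + y.size <= EXACT_WILCOXON_MAX_N and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative=alternative, method=method,
                       use_continuity=True)
    w_stat = float(res.statistic + x.size * (x.size + 1) / 2.0)  # U -> rank sum
    return w_stat, float(res.pvalue)


def subsystem_screen(
    flux_table: pd.DataFrame,
    model: MetabolicModel,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Flag subsystems with differential flux between any pair of states.

    Per subsystem, every state pair is tested with a two-sided Wilcoxon
    rank-sum on the per-reaction flux magnitudes; the subsystem is flagged
    when any pair's p < alpha (raw p by default; ``bh_correct`` applies
    Benjamini-Hochberg across all pairwise tests first).  Subsystems with
    fewer than two reactions are skipped with a warning.  State-averaged
    |flux| per subsystem is returned for display alongside.
    """
    states = sorted(flux_table.columns)
    if len(states) < 2:
        raise ValueError("need at least two states")
    sub_of = {r: model.subsystem_of(r) for r in flux_table.index}
    rows = []
    all_ps: list[float] = []
    p_slots: list[tuple[int, int]] = []   # (row index, p index within row)
    for sub in sorted(set(sub_of.values())):
        rxns = [r for r in flux_table.index if sub_of[r] == sub]
        if len(rxns) < 2:
            warnings.warn(f"subsystem {sub!r} has < 2 reactions; skipped")
            continue
        block = flux_table.loc[rxns].abs()
        ps = []
        for i in range(len(states)):
            for j in range(i + 1, len(states)):
                _, p = wilcoxon_rank_sum(block[states[i]], block[states[j]])
                p_slots.append((len(rows), len(ps)))
                ps.append(p)
                all_ps.append(p)
        rows.append(
            {
                "subsystem": sub,
                "n_reactions": len(rxns),
                "min_p": min(ps),
                "_ps": ps,
                **{f"mean_abs_flux_{s}": float(block[s].mean()) for s in states},
            }
        )
    if bh_correct and all_ps:
        from scipy.stats import false_discovery_control

        adj = false_discovery_control(all_ps, method="bh")
        for (ri, pi), q in zip(p_slots, adj):
            rows[ri]["_ps"][pi] = q
        for row in rows:
            row["min_p"] = min(row["_ps"])
    for row in rows:
        row["significant"] = row["min_p"] < alpha
        del row["_ps"]
    return pd.DataFrame(rows).set_index("subsystem")


def _correlation_distance(Z: np.ndarray) -> np.ndarray:
    """1 - Pearson between rows of a z-scored matrix.

    Zero-variance rows (z-scored to all-zero) get distance 1 to everything,
    0 to each other, instead of NaN.
    """
    n, m = Z.shape
    norms = np.linalg.norm(Z, axis=1)
    D = np.ones((n, n))
    with np.errstate(invalid="ignore", divide="ignore"):
        for i in range(n):
            for j in range(i, n):
                if norms[i] == 0 and norms[j] == 0:
                    d = 0.0
                elif norms[i] == 0 or norms[j] == 0:
                    d = 1.0
                else:
                    r = float(Z[i] @ Z[j] / (norms[i] * norms[j]))
                    d = 1.0 - r
                D[i, j] = D[j, i] = max(d, 0.0)
        np.fill_diagonal(D, 0.0)
    return D


def hierarchical_cluster(
    matrix: pd.DataFrame,
    k: int,
    linkage_method: str = "average",
) -> ClusterAssignment:
    """Agglomerative clustering of rows into k clusters.

    Rows are z-scored internally (constant rows become zero vectors);
    distance is 1 - Pearson correlation; linkage is average by default.
    Duplicate rows have distance 0 and merge first, so they are never
    split across clusters.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds number of rows {len(matrix)}")
    X = matrix.values.astype(float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    Z = np.where(sd > 0, (X - mu) / np.where(sd == 0, 1, sd), 0.0)
    if len(matrix) == 1:
        return ClusterAssignment(
            assignments={matrix.index[0]: 1}, k=1,
            linkage_method=linkage_method, distance="1-pearson",
            dendrogram_order=list(matrix.index),
        )
    D = _correlation_distance(Z)
    link = linkage(squareform(D, checks=False), method=linkage_method)
    labels = fcluster(link, t=k, criterion="maxclust")
    from scipy.cluster.hierarchy import leaves_list

    order = [matrix.index[i] for i in leaves_list(link)]
    return ClusterAssignment(
        assignments={matrix.index[i]: int(labels[i]) for i in range(len(matrix))},
        k=int(labels.max()),
        linkage_method=linkage_method,
        distance="1-pearson",
        dendrogram_order=order,
    )


def gene_rule_frequency(
    clusters: ClusterAssignment,
    model: MetabolicModel,
) -> GeneRuleFrequencyTable:
    """Count canonical gene rules per reaction cluster.

    Fractions are relative to the cluster's total reaction count, so a
    cluster's fractions sum to <= 1 (no-GPR reactions are reported
    separately, not counted under any rule).  The most frequent rule per
    cluster is reported; ties break to the lexicographically smaller rule
    and are flagged.
    """
    per_cluster: dict[int, pd.DataFrame] = {}
    most_frequent: dict[int, tuple[str, int, float]] = {}
    no_gpr_counts: dict[int, int] = {}
    ties: dict[int, list[str]] = {}
    for cid in sorted(set(clusters.assignments.values())):
        rxns = clusters.members(cid)
        total = len(rxns)
        counts: dict[str, int] = {}
        n_no_gpr = 0
        for r in rxns:
            gpr = model.reaction(r).gpr
            if not gpr.strip():
                n_no_gpr += 1
                continue
            rule = canonical_gpr(gpr)
            counts[rule] = counts.get(rule, 0) + 1
        no_gpr_counts[cid] = n_no_gpr
        if not counts:
            per_cluster[cid] = pd.DataFrame(columns=["rule", "count", "fraction"])
            continue
        df = pd.DataFrame(
            [(rule, c, c / total) for rule, c in sorted(counts.items())],
            columns=["rule", "count", "fraction"],
        ).sort_values(["count", "rule"], ascending=[False, True], kind="mergesort")
        df = df.reset_index(drop=True)
        per_cluster[cid] = df
        top_count = df["count"].iloc[0]
        tied = sorted(df.loc[df["count"] == top_count, "rule"])
        if len(tied) > 1:
            ties[cid] = tied
        best = tied[0]
        most_frequent[cid] = (best, int(top_count), top_count / total)
    return GeneRuleFrequencyTable(
        per_cluster=per_cluster,
        most_frequent=most_frequent,
        no_gpr_counts=no_gpr_counts,
        ties=ties,
    )


def transport_direction_map(
    reactions: list[str],
    model: MetabolicModel,
    flux_signs: dict[str, float],
    interior: str = INTERIOR_COMPARTMENT,
) -> pd.DataFrame:
    """Classify transported species as imported or exported (but not both).

    Each transport reaction is oriented by its flux sign; a species is an
    import when its net oriented production in the interior compartment is
    positive, an export when negative.  Species seen in both directions
    within the reaction set are dropped (mixed evidence).
    Returns a species x [direction, n_reactions] table.
    """
    directions: dict[str, set[str]] = {}
    n_by_species: dict[str, int] = {}
    for rxn_id in reactions:
        if not model.is_transport(rxn_id):
            raise ValueError(f"reaction {rxn_id!r} is not a transport reaction")
        v = flux_signs.get(rxn_id, 0.0)
        if v == 0:
            continue
        sign = 1.0 if v > 0 else -1.0
        rxn = model.reaction(rxn_id)
        for species in model.transported_species(rxn_id):
            net_interior = 0.0
            for met_id, coef in rxn.stoichiometry.items():
                met = model.metabolite(met_id)
                if met.species == species and met.compartment == interior:
                    net_interior += sign * coef
            if net_interior == 0:
                continue
            d = "import" if net_interior > 0 else "export"
            directions.setdefault(species, set()).add(d)
            n_by_species[species] = n_by_species.get(species, 0) + 1
    rows = [
        {"species": s, "direction": next(iter(ds)), "n_reactions": n_by_species[s]}
        for s, ds in sorted(directions.items())
        if len(ds) == 1
    ]
    return pd.DataFrame(rows, columns=["species", "direction", "n_reactions"]).set_index(
        "species"
    )
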