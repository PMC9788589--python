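"""Expression handling: TPM normalization, per-state aggregation, GPR scoring.

RNA-seq counts are length-normalized to transcripts-per-million (TPM) so that
every sample column sums to 1e6, aggregated per disease state (max across
samples by default, matching the threshold rule's "maximum TPM" wording; mean
available), and pushed through each reaction's GPR rule to give a per-reaction
expression score g_j: AND = min, OR = max over gene values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import MetabolicModel, evaluate_gpr, parse_gpr

__all__ = [
    "ExpressionMatrix",
    "StateProfile",
    "ReactionScoreVector",
    "tpm_normalize",
    "aggregate_states",
    "score_reactions",
]

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression with a sample-to-state map.

    ``counts`` holds raw counts (with ``lengths`` in bases for TPM
    conversion) or precomputed TPM (``lengths`` None); the two input paths
    are mutually exclusive per run.
    """

    counts: pd.DataFrame                 # genes x samples, non-negative
    sample_state: dict[str, str]         # sample id -> state label
    lengths: pd.Series | None = None     # gene -> effective length (bases)
    is_tpm: bool = False

    def validate(self, model: MetabolicModel | None = None) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("expression matrix contains negative entries")
        unmapped = [s for s in self.counts.columns if s not in self.sample_state]
        if unmapped:
            raise ValueError(f"samples without a state label: {unmapped}")
        if model is not None:
            overlap = set(self.counts.index) & set(model.genes)
            frac_missing = 1 - len(overlap) / max(len(model.genes), 1)
            if frac_missing > 0.5:
                warnings.warn(
                    f"{frac_missing:.0%} of model genes absent from expression data"
                )


@dataclass
class StateProfile:
    """Aggregated expression for one disease state: gene -> TPM."""

    state: str
    gene_values: dict[str, float]


@dataclass
class ReactionScoreVector:
    """Per-reaction GPR expression scores g_j for one state.

    Reactions with an empty rule are listed in ``no_gpr`` and carry no score;
    every model reaction appears in exactly one of the two.  These scores are
    also what the expression-derived flux bounds are built from.
    """

    state: str
    scores: dict[str, float]
    no_gpr: set[str] = field(default_factory=set)

    def coverage_check(self, model: MetabolicModel) -> None:
        covered = set(self.scores) | self.no_gpr
        model_rxns = set(model.reaction_ids)
        if covered != model_rxns:
            missing = sorted(model_rxns - covered)
            extra = sorted(covered - model_rxns)
            raise ValueError(
                f"score vector does not cover the model (missing {missing[:5]}, "
                f"extra {extra[:5]})"
            )


def tpm_normalize(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Convert raw counts to TPM: per sample, 1e6 * (c_i/l_i) / sum_k(c_k/l_k).

    Each sample column of the result sums to 1e6; an all-zero sample yields
    an all-zero column with a warning.  Zero or non-positive gene lengths
    are an error.
    """
    lengths = lengths.reindex(counts.index)
    bad = lengths[(lengths.isna()) | (lengths <= 0)]
    if len(bad):
        raise ValueError(f"non-positive or missing length for genes: {list(bad.index[:5])}")
    if (counts.values < 0).any():
        raise ValueError("negative counts")
    rates = counts.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    zero_cols = totals[totals == 0].index
    if len(zero_cols):
        warnings.warn(f"all-zero samples normalized to all-zero TPM: {list(zero_cols)}")
    totals = totals.replace(0, np.nan)
    tpm = rates.div(totals, axis=1) * 1e6
    return tpm.fillna(0.0)


def aggregate_states(
    tpm: pd.DataFrame,
    sample_state: dict[str, str],
    method: str = "max",
) -> list[StateProfile]:
    """Aggregate per-sample TPM into one profile per state.

    ``method="max"`` takes each gene's maximum TPM across the state's samples
    (the extraction threshold's reading); ``"mean"`` averages.  Sorted by
    state label for determinism.
    """
    if method not in ("max", "mean"):
        raise ValueError(f"unknown aggregation method {method!r}")
    unknown = [s for s in tpm.columns if s not in sample_state]
    if unknown:
        raise ValueError(f"samples with no state mapping: {unknown}")
    groups: dict[str, list[str]] = {}
    for sample in tpm.columns:
        groups.setdefault(sample_state[sample], []).append(sample)
    profiles = []
    for state in sorted(groups):
        block = tpm[groups[state]]
        agg = block.max(axis=1) if method == "max" else block.mean(axis=1)
        profiles.append(StateProfile(state=state, gene_values=agg.to_dict()))
    return profiles


def score_reactions(model: MetabolicModel, profile: StateProfile) -> ReactionScoreVector:
    """Score every model reaction through its GPR against a state profile.

    Genes absent from the profile score 0 (warned once with a count); genes
    present in the profile but absent from the model are simply unused.
    """
    model_genes = set(model.genes)
    extra = len(set(profile.gene_values) - model_genes)
    if extra:
        logger.info(
            "state %s: %d expression genes not in the model (ignored)",
            profile.state, extra,
        )
    scores: dict[str, float] = {}
    no_gpr: set[str] = set()
    n_missing = 0
    for rxn in model.reactions:
        tree = parse_gpr(rxn.gpr)
        if tree is None:
            no_gpr.add(rxn.id)
            continue
        missing = tree.genes() - set(profile.gene_values)
        if missing:
            n_missing += len(missing)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores[rxn.id] = evaluate_gpr(tree, profile.gene_values)
    if n_missing:
        warnings.warn(
            f"state {profile.state}: {n_missing} GPR gene references missing "
            "from the expression profile; scored 0.0"
        )
    return ReactionScoreVector(state=profile.state, scores=scores, no_gpr=no_gpr)
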