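"""Shared fixtures: small hand-built models and score vectors."""

from __future__ import annotations

import pytest

from gemflux.model_core import MetabolicModel, Metabolite, Reaction
from gemflux.expression import ReactionScoreVector
from gemflux.context_extraction import ContextModel, MetabolicTask


def build_model(model_id, reactions, metabolites, genes, compartments=("c",)):
    model = MetabolicModel(
        model_id=model_id,
        reactions=reactions,
        metabolites=metabolites,
        genes=list(genes),
        compartments=list(compartments),
    )
    model.validate()
    return model


@pytest.fixture
def chain_model():
    """Three-reaction chain ->A, A->B, B-> with scores g = (-, 3, 2)."""
    mets = [Metabolite("A_c", "A", "c"), Metabolite("B_c", "B", "c")]
    rxns = [
        Reaction("R_in", {"A_c": 1.0}, 0, 10, "exchange"),
        Reaction("R_ab", {"A_c": -1.0, "B_c": 1.0}, 0, 1000, "core", gpr="G1"),
        Reaction("R_out", {"B_c": -1.0}, 0, 1000, "exchange", gpr="G2"),
    ]
    return build_model("chain", rxns, mets, ["G1", "G2"])


@pytest.fixture
def chain_scores():
    return ReactionScoreVector("s", {"R_ab": 3.0, "R_out": 2.0}, {"R_in"})


@pytest.fixture
def chain_context():
    return ContextModel("chain", "s", {"R_in", "R_ab", "R_out"}, {}, 1.0)


@pytest.fixture
def chain4_model():
    """Four-step chain ->A->B->C-> used for task/gap-fill tests."""
    mets = [
        Metabolite("A_c", "A", "c"),
        Metabolite("B_c", "B", "c"),
        Metabolite("C_c", "C", "c"),
    ]
    rxns = [
        Reaction("R_in", {"A_c": 1.0}, 0, 10, "exchange"),
        Reaction("R_ab", {"A_c": -1.0, "B_c": 1.0}, 0, 1000, "core", gpr="G1"),
        Reaction("R_bc", {"B_c": -1.0, "C_c": 1.0}, 0, 1000, "core", gpr="G2"),
        Reaction("R_out", {"C_c": -1.0}, 0, 1000, "exchange"),
    ]
    return build_model("chain4", rxns, mets, ["G1", "G2"])


@pytest.fixture
def produce_c_task():
    return MetabolicTask("produce_C", inputs=[("A_c", 10.0)], outputs=[("C_c", 0.5)])
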