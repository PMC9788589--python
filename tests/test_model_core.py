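"""Model core: GPR parsing/evaluation, JSON round-trips, derived flags."""

import json

import numpy as np
import pytest

from gemflux.model_core import (
    GprParseError,
    GprTree,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    canonical_gpr,
    evaluate_gpr,
    model_from_dict,
    parse_gpr,
    read_model,
    write_model,
)


# -- independent oracle: brute-force recursive evaluator ---------------------

def brute_eval(tree, values):
    if tree.is_leaf:
        return float(values.get(tree.gene, 0.0))
    vals = [brute_eval(c, values) for c in tree.children]
    return min(vals) if tree.op == "AND" else max(vals)


def random_tree(rng, genes, depth):
    if depth == 0 or rng.random() < 0.35:
        return GprTree(gene=str(rng.choice(genes)))
    op = "AND" if rng.random() < 0.5 else "OR"
    n = int(rng.integers(2, 4))
    return GprTree(op=op, children=tuple(
        random_tree(rng, genes, depth - 1) for _ in range(n)
    ))


def fully_parenthesized(tree):
    if tree.is_leaf:
        return tree.gene
    return "(" + f" {tree.op} ".join(fully_parenthesized(c) for c in tree.children) + ")"


class TestGprParsing:
    @pytest.mark.parametrize("rule,expected", [
        ("G1 AND G2", ("AND", ["G1", "G2"])),
        ("(G1 AND G2) OR G3", ("OR", None)),
        ("G1 AND G2 OR G3", ("OR", None)),  # AND binds tighter
        ("g1 and g2", ("AND", ["g1", "g2"])),  # case-insensitive operators
    ])
    def test_structure(self, rule, expected):
        tree = parse_gpr(rule)
        op, leaves = expected
        assert tree.op == op
        if leaves is not None:
            assert [c.gene for c in tree.children] == leaves

    def test_and_precedence_nests_under_or(self):
        tree = parse_gpr("G1 AND G2 OR G3")
        assert tree.op == "OR"
        assert tree.children[0].op == "AND"
        assert tree.children[1].gene == "G3"

    def test_empty_rule_is_no_gpr_marker(self):
        assert parse_gpr("") is None
        assert parse_gpr("   ") is None

    @pytest.mark.parametrize("rule", ["(G1 AND", "G1 AND", "AND G1", "G1)"])
    def test_malformed_rules_raise_with_position(self, rule):
        with pytest.raises(GprParseError):
            parse_gpr(rule)

    def test_unparse_reparse_idempotent_on_random_rules(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(6)]
        for _ in range(300):
            tree = random_tree(rng, genes, 3)
            text = tree.unparse()
            again = parse_gpr(text)
            assert again.unparse() == text

    def test_precedence_matches_fully_parenthesized_oracle(self):
        """Minimal-paren rendering parses to the same function as the
        explicit fully parenthesized form, on 1,000 random rules."""
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(6)]
        for _ in range(1000):
            tree = random_tree(rng, genes, 4)
            values = {g: float(rng.uniform(0, 10)) for g in genes}
            t1 = parse_gpr(tree.unparse())
            t2 = parse_gpr(fully_parenthesized(tree))
            expected = brute_eval(tree, values)
            assert evaluate_gpr(t1, values) == expected
            assert evaluate_gpr(t2, values) == expected


class TestGprEvaluation:
    @pytest.mark.parametrize("rule,values,expected", [
        ("G1 AND G2", {"G1": 5.0, "G2": 0.5}, 0.5),
        ("G1 OR G2", {"G1": 5.0, "G2": 0.5}, 5.0),
        ("(G1 AND G2) OR G3", {"G1": 2, "G2": 3, "G3": 0.2}, 2.0),
    ])
    def test_min_max_semantics(self, rule, values, expected):
        assert evaluate_gpr(parse_gpr(rule), values) == expected

    def test_missing_gene_scores_zero_with_warning(self):
        with pytest.warns(UserWarning, match="G9"):
            assert evaluate_gpr(parse_gpr("G9"), {"G1": 5.0}) == 0.0

    def test_monotone_in_every_gene(self):
        rng = np.random.default_rng(2)
        genes = [f"G{i}" for i in range(6)]
        for _ in range(200):
            tree = random_tree(rng, genes, 3)
            values = {g: float(rng.uniform(0, 5)) for g in genes}
            base = evaluate_gpr(tree, values)
            bump = dict(values)
            g = str(rng.choice(genes))
            bump[g] = values[g] + float(rng.uniform(0, 5))
            assert evaluate_gpr(tree, bump) >= base

    def test_canonicalization_sorts_operands(self):
        assert canonical_gpr("G1 AND G2") == canonical_gpr("G2 AND G1")
        assert canonical_gpr("(G2 OR G1) AND G3") == canonical_gpr("G3 AND (G1 OR G2)")
        assert canonical_gpr("G1 AND G2") != canonical_gpr("G1 OR G2")


def _toy_model_dict():
    return {
        "id": "toy",
        "compartments": [{"id": "c", "name": "cytosol"}],
        "metabolites": [
            {"id": "A_c", "name": "A", "compartment": "c"},
            {"id": "B_c", "name": "B", "compartment": "c"},
        ],
        "reactions": [
            {"id": "R1", "name": "", "stoichiometry": {"A_c": 1.0},
             "lower_bound": 0.0, "upper_bound": 10.0, "subsystem": "exchange", "gpr": ""},
            {"id": "R2", "name": "", "stoichiometry": {"A_c": -1.0, "B_c": 1.0},
             "lower_bound": 0.0, "upper_bound": 5.0, "subsystem": "core", "gpr": "G1"},
            {"id": "R3", "name": "", "stoichiometry": {"B_c": -1.0},
             "lower_bound": 0.0, "upper_bound": 10.0, "subsystem": "exchange", "gpr": ""},
        ],
        "genes": ["G1"],
    }


class TestModelIO:
    def test_round_trip_byte_identical(self, tmp_path):
        p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
        p1.write_text(json.dumps(_toy_model_dict()))
        model = read_model(p1)
        assert len(model.reactions) == 3 and len(model.metabolites) == 2
        write_model(model, p2)
        model2 = read_model(p2)
        p3 = tmp_path / "m3.json"
        write_model(model2, p3)
        assert p2.read_bytes() == p3.read_bytes()

    def test_dangling_metabolite_named_in_error(self):
        raw = _toy_model_dict()
        raw["reactions"][1]["stoichiometry"]["X"] = -1.0
        with pytest.raises(ModelValidationError, match="X"):
            model_from_dict(raw)

    def test_inverted_bounds_rejected(self):
        raw = _toy_model_dict()
        raw["reactions"][0]["lower_bound"] = 20.0
        with pytest.raises(ModelValidationError, match="lower_bound"):
            model_from_dict(raw)

    def test_duplicate_reaction_ids_rejected(self):
        raw = _toy_model_dict()
        raw["reactions"].append(dict(raw["reactions"][0]))
        with pytest.raises(ModelValidationError, match="duplicate"):
            model_from_dict(raw)

    def test_dangling_gene_rejected(self):
        raw = _toy_model_dict()
        raw["reactions"][1]["gpr"] = "G1 AND G7"
        with pytest.raises(ModelValidationError, match="G7"):
            model_from_dict(raw)

    def test_malformed_json_parse_error(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{not json")
        with pytest.raises(ValueError, match="malformed"):
            read_model(p)


class TestDerivedFlags:
    def test_transport_and_exchange_derived_from_stoichiometry(self):
        mets = [
            Metabolite("A_e", "A", "e"),
            Metabolite("A_c", "A", "c"),
            Metabolite("B_c", "B", "c"),
        ]
        rxns = [
            Reaction("EX", {"A_e": 1.0}, 0, 10, "exchange"),
            Reaction("T", {"A_e": -1.0, "A_c": 1.0}, 0, 10, "transport"),
            Reaction("C", {"A_c": -1.0, "B_c": 1.0}, 0, 10, "core"),
        ]
        m = MetabolicModel("t", rxns, mets, [], ["e", "c"])
        m.validate()
        assert m.is_exchange("EX") and not m.is_transport("EX")
        assert m.is_transport("T") and not m.is_exchange("T")
        assert not m.is_transport("C") and not m.is_exchange("C")
        assert m.transported_species("T") == ["A"]
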