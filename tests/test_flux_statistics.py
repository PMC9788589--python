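"""Subsystem statistics, Wilcoxon tests, clustering, transport mapping."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from gemflux.flux_statistics import (
    gene_rule_frequency,
    hierarchical_cluster,
    subsystem_flux_sums,
    subsystem_screen,
    transport_direction_map,
    wilcoxon_rank_sum,
)
from gemflux.model_core import Metabolite, Reaction

from conftest import build_model


# -- independent oracle: full enumeration of rank assignments ----------------

def enumerated_wilcoxon_p(x, y):
    """Two-sided exact p by enumerating all C(n+m, n) group assignments."""
    pooled = sorted(x) + sorted(y)
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
    n = len(x)
    w_obs = sum(ranks[v] for v in x)
    mean = n * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), n):
        w = sum(combo)
        total += 1
        if abs(w - mean) >= abs(w_obs - mean) - 1e-12:
            count += 1
    return count / total


def _stats_model(subsystems):
    mets, rxns, genes = [], [], []
    for i, sub in enumerate(subsystems):
        a, b = f"A{i}_c", f"B{i}_c"
        mets += [Metabolite(a, f"A{i}", "c"), Metabolite(b, f"B{i}", "c")]
        rxns.append(Reaction(f"R{i}", {a: -1.0, b: 1.0}, 0, 10, sub))
    return build_model("stats", rxns, mets, genes)


class TestSubsystemSums:
    def test_magnitude_convention(self):
        model = _stats_model(["s1", "s1", "s2"])
        table = pd.DataFrame({"st": [1.0, -2.0, 0.5]}, index=["R0", "R1", "R2"])
        out = subsystem_flux_sums(table, model)
        assert out.sums.loc["s1", "st"] == 3.0
        assert out.sums.loc["s2", "st"] == 0.5
        assert out.reaction_counts["s1"] == 2

    def test_signed_option_and_permutation_invariance(self):
        model = _stats_model(["s1", "s1", "s2"])
        table = pd.DataFrame({"st": [1.0, -2.0, 0.5]}, index=["R0", "R1", "R2"])
        signed = subsystem_flux_sums(table, model, signed=True)
        assert signed.sums.loc["s1", "st"] == -1.0
        shuffled = subsystem_flux_sums(table.iloc[[2, 0, 1]], model)
        assert shuffled.sums.equals(subsystem_flux_sums(table, model).sums)

    def test_unknown_reaction_raises(self):
        model = _stats_model(["s1"])
        with pytest.raises(ValueError, match="R9"):
            subsystem_flux_sums(pd.DataFrame({"st": [1.0]}, index=["R9"]), model)


class TestWilcoxon:
    def test_separated_samples_exact_p(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("n,m", [(2, 3), (3, 3), (4, 4), (3, 5)])
    def test_matches_enumeration_on_untied_data(self, n, m):
        rng = np.random.default_rng(n * 10 + m)
        for _ in range(20):
            pool = rng.choice(1000, size=n + m, replace=False).astype(float)
            x, y = pool[:n], pool[n:]
            _, p = wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(enumerated_wilcoxon_p(x, y), abs=1e-10)

    def test_large_sample_normal_branch_close_to_exact(self):
        rng = np.random.default_rng(5)
        pool = rng.choice(10000, size=18, replace=False).astype(float)
        x, y = pool[:9], pool[9:]
        _, p_norm = wilcoxon_rank_sum(x, y)   # n+m=18 -> asymptotic branch
        p_exact = enumerated_wilcoxon_p(x, y)
        assert p_norm == pytest.approx(p_exact, abs=0.02)


class TestSubsystemScreen:
    def _flux_table(self, rng, n=10, doubled_state=None):
        base = rng.uniform(1, 2, n)
        data = {}
        for s in ("s1", "s2"):
            vals = base * (2.0 if s == doubled_state else 1.0)
            data[s] = vals
        return pd.DataFrame(data, index=[f"R{i}" for i in range(n)])

    def test_identical_states_never_flagged(self):
        model = _stats_model(["sub"] * 10)
        rng = np.random.default_rng(0)
        table = self._flux_table(rng)
        out = subsystem_screen(table, model)
        assert not out.loc["sub", "significant"]

    def test_planted_doubling_flagged(self):
        model = _stats_model(["sub"] * 10)
        rng = np.random.default_rng(1)
        table = self._flux_table(rng, doubled_state="s2")
        out = subsystem_screen(table, model, alpha=0.05)
        assert out.loc["sub", "significant"]
        assert out.loc["sub", "min_p"] < 0.05

    def test_alpha_zero_flags_nothing(self):
        model = _stats_model(["sub"] * 10)
        rng = np.random.default_rng(2)
        table = self._flux_table(rng, doubled_state="s2")
        out = subsystem_screen(table, model, alpha=0.0)
        assert not out["significant"].any()

    def test_small_subsystem_skipped_with_warning(self):
        model = _stats_model(["lonely", "big", "big"])
        table = pd.DataFrame({"s1": [1.0, 1, 2], "s2": [1.0, 3, 4]},
                             index=["R0", "R1", "R2"])
        with pytest.warns(UserWarning, match="lonely"):
            out = subsystem_screen(table, model)
        assert "lonely" not in out.index


class TestHierarchicalCluster:
    def test_two_orthogonal_patterns_separate(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [4.0, 3.0, 2.0, 1.0]
        mat = pd.DataFrame([a, a, b, b], index=["a1", "a2", "b1", "b2"])
        out = hierarchical_cluster(mat, k=2)
        assert out.assignments["a1"] == out.assignments["a2"]
        assert out.assignments["b1"] == out.assignments["b2"]
        assert out.assignments["a1"] != out.assignments["b1"]

    def test_k_one_single_cluster(self):
        mat = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 4)))
        out = hierarchical_cluster(mat, k=1)
        assert set(out.assignments.values()) == {1}

    def test_duplicate_rows_never_split(self):
        rng = np.random.default_rng(3)
        rows = rng.normal(size=(4, 6))
        mat = pd.DataFrame(
            np.vstack([rows, rows[1]]), index=["r0", "r1", "r2", "r3", "r1copy"]
        )
        out = hierarchical_cluster(mat, k=3)
        assert out.assignments["r1"] == out.assignments["r1copy"]

    def test_permutation_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(rng.normal(size=(8, 5)),
                           index=[f"r{i}" for i in range(8)])
        out1 = hierarchical_cluster(mat, k=3)
        perm = mat.iloc[rng.permutation(8)]
        out2 = hierarchical_cluster(perm, k=3)
        # same partition of row labels
        def partition(assign):
            groups = {}
            for item, c in assign.items():
                groups.setdefault(c, set()).add(item)
            return {frozenset(g) for g in groups.values()}
        assert partition(out1.assignments) == partition(out2.assignments)

    def test_k_exceeding_rows_raises(self):
        mat = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError, match="exceeds"):
            hierarchical_cluster(mat, k=5)


class TestGeneRuleFrequency:
    def _model_with_rules(self, rules):
        mets, rxns, genes = [], [], set()
        for i, rule in enumerate(rules):
            a, b = f"A{i}_c", f"B{i}_c"
            mets += [Metabolite(a, f"A{i}", "c"), Metabolite(b, f"B{i}", "c")]
            rxns.append(Reaction(f"R{i}", {a: -1.0, b: 1.0}, 0, 10, "s", gpr=rule))
            if rule:
                from gemflux.model_core import parse_gpr
                genes |= parse_gpr(rule).genes()
        return build_model("freq", rxns, mets, sorted(genes))

    def test_counting_and_fraction(self):
        model = self._model_with_rules(["GA", "GA", "GB"])
        from gemflux.flux_statistics import ClusterAssignment
        clusters = ClusterAssignment({"R0": 1, "R1": 1, "R2": 1}, 1, "average",
                                     "1-pearson", ["R0", "R1", "R2"])
        out = gene_rule_frequency(clusters, model)
        rule, count, frac = out.most_frequent[1]
        assert (rule, count) == ("GA", 2)
        assert frac == pytest.approx(2 / 3)

    def test_rule_canonicalization_merges_permuted_operands(self):
        model = self._model_with_rules(["GA AND GB", "GB AND GA", "GC"])
        from gemflux.flux_statistics import ClusterAssignment
        clusters = ClusterAssignment({"R0": 1, "R1": 1, "R2": 1}, 1, "average",
                                     "1-pearson", ["R0", "R1", "R2"])
        out = gene_rule_frequency(clusters, model)
        assert out.most_frequent[1][1] == 2

    def test_no_gpr_reported_separately_and_shuffle_invariant(self):
        model = self._model_with_rules(["GA", "", "GA", "GB"])
        from gemflux.flux_statistics import ClusterAssignment
        order1 = {"R0": 1, "R1": 1, "R2": 1, "R3": 1}
        order2 = {k: order1[k] for k in reversed(list(order1))}
        o1 = gene_rule_frequency(
            ClusterAssignment(order1, 1, "a", "d", list(order1)), model)
        o2 = gene_rule_frequency(
            ClusterAssignment(order2, 1, "a", "d", list(order2)), model)
        assert o1.no_gpr_counts[1] == 1
        assert o1.most_frequent == o2.most_frequent
        # fractions computed over cluster size including no-GPR reactions
        assert o1.most_frequent[1][2] == pytest.approx(2 / 4)


class TestTransportDirectionMap:
    def _transport_model(self):
        mets = [
            Metabolite("A_e", "A", "e"), Metabolite("A_c", "A", "c"),
            Metabolite("B_e", "B", "e"), Metabolite("B_c", "B", "c"),
        ]
        rxns = [
            Reaction("TA", {"A_e": -1.0, "A_c": 1.0}, -10, 10, "transport"),
            Reaction("TB1", {"B_e": -1.0, "B_c": 1.0}, -10, 10, "transport"),
            Reaction("TB2", {"B_c": -1.0, "B_e": 1.0}, -10, 10, "transport"),
            Reaction("NC", {"A_c": -1.0, "B_c": 1.0}, 0, 10, "core"),
        ]
        return build_model("tr", rxns, mets, [], ["e", "c"])

    def test_positive_flux_is_import(self):
        model = self._transport_model()
        out = transport_direction_map(["TA"], model, {"TA": 1.0})
        assert out.loc["A", "direction"] == "import"

    def test_negative_flux_flips_to_export(self):
        model = self._transport_model()
        out = transport_direction_map(["TA"], model, {"TA": -1.0})
        assert out.loc["A", "direction"] == "export"

    def test_mixed_direction_species_excluded(self):
        model = self._transport_model()
        # TB1 imports B (v>0); TB2 also written c->e with v>0 exports B
        out = transport_direction_map(["TB1", "TB2"], model,
                                      {"TB1": 1.0, "TB2": 1.0})
        assert "B" not in out.index

    def test_non_transport_reaction_rejected(self):
        model = self._transport_model()
        with pytest.raises(ValueError, match="NC"):
            transport_direction_map(["NC"], model, {"NC": 1.0})
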