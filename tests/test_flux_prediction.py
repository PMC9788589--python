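"""SPOT objective and two-stage E-Flux2 flux prediction."""

import numpy as np
import pandas as pd
import pytest

from gemflux.context_extraction import ContextModel
from gemflux.expression import ReactionScoreVector
from gemflux.flux_prediction import (
    FluxResult,
    eflux2_bounds,
    eflux2_solve,
    measurable_fluxes,
    spot_objective,
)
from gemflux.model_core import Metabolite, Reaction, stoichiometric_matrix

from conftest import build_model


class TestSpotObjective:
    def test_chain_cosine_matches_hand_derivation(
        self, chain_model, chain_context, chain_scores
    ):
        # feasible cone is the ray (1,1,1); cos = (g.1/sqrt3)/||g|| = 5/sqrt39
        obj = spot_objective(chain_model, chain_context, chain_scores)
        assert obj.achieved_cosine == pytest.approx(5 / np.sqrt(39), abs=1e-6)
        for r in ("R_in", "R_ab", "R_out"):
            assert obj.f_prime[r] == pytest.approx(1 / np.sqrt(3), abs=1e-6)

    def test_scale_invariance_of_scores(self, chain_model, chain_context, chain_scores):
        obj1 = spot_objective(chain_model, chain_context, chain_scores)
        scaled = ReactionScoreVector(
            "s", {k: 10 * v for k, v in chain_scores.scores.items()},
            set(chain_scores.no_gpr),
        )
        obj2 = spot_objective(chain_model, chain_context, scaled)
        assert obj2.achieved_cosine == pytest.approx(obj1.achieved_cosine, abs=1e-6)
        for r in obj1.f_prime:
            assert obj2.f_prime[r] == pytest.approx(obj1.f_prime[r], abs=1e-6)

    def test_zero_scores_degenerate(self, chain_model, chain_context):
        sv = ReactionScoreVector("s", {"R_ab": 0.0, "R_out": 0.0}, {"R_in"})
        obj = spot_objective(chain_model, chain_context, sv)
        assert obj.degenerate and obj.achieved_cosine == 0.0
        assert all(v == 0.0 for v in obj.f_prime.values())

    def test_unit_norm_direction(self, chain_model, chain_context, chain_scores):
        obj = spot_objective(chain_model, chain_context, chain_scores)
        norm = np.linalg.norm(list(obj.f_prime.values()))
        assert norm == pytest.approx(1.0, abs=1e-8)


class TestEflux2Bounds:
    def test_bound_conventions(self):
        mets = [Metabolite("A_e", "A", "e"), Metabolite("A_c", "A", "c"),
                Metabolite("B_c", "B", "c")]
        rxns = [
            Reaction("EX", {"A_e": 1.0}, -1000, 1000, "exchange"),
            Reaction("T", {"A_e": -1.0, "A_c": 1.0}, -1000, 1000, "transport", gpr="G1"),
            Reaction("C", {"A_c": -1.0, "B_c": 1.0}, 0, 1000, "core", gpr="G2"),
            Reaction("D", {"B_c": -1.0}, 0, 500, "core"),
        ]
        model = build_model("b", rxns, mets, ["G1", "G2"], ["e", "c"])
        ctx = ContextModel("b", "s", {"EX", "T", "C", "D"}, {}, 1.0)
        sv = ReactionScoreVector("s", {"T": 2.5, "C": 2.5}, {"EX", "D"})
        bounds = eflux2_bounds(model, ctx, sv)
        assert bounds["C"] == (0.0, 2.5)           # irreversible scored
        assert bounds["T"] == (-2.5, 2.5)          # reversible scored
        assert bounds["EX"] == (-1000, 1000)       # exchange: parent bounds
        assert bounds["D"] == (0, 500)             # no-GPR: parent bounds


class TestEflux2Solve:
    def test_chain_hand_case(self, chain_model, chain_context, chain_scores):
        obj = spot_objective(chain_model, chain_context, chain_scores)
        bounds = {"R_in": (0, 10), "R_ab": (0, 3.0), "R_out": (0, 2.0)}
        res = eflux2_solve(chain_model, chain_context, obj, bounds)
        for r in ("R_in", "R_ab", "R_out"):
            assert res.fluxes[r] == pytest.approx(2.0, abs=1e-6)
        assert res.z_star == pytest.approx(6 / np.sqrt(3), abs=1e-6)
        assert res.residual <= 1e-6

    def test_zero_upper_bounds_force_zero_flux(
        self, chain_model, chain_context, chain_scores
    ):
        obj = spot_objective(chain_model, chain_context, chain_scores)
        bounds = {r: (0.0, 0.0) for r in ("R_in", "R_ab", "R_out")}
        res = eflux2_solve(chain_model, chain_context, obj, bounds)
        assert all(abs(v) <= 1e-9 for v in res.fluxes.values())
        assert res.z_star == pytest.approx(0.0, abs=1e-9)

    def test_diamond_degeneracy_resolved_to_equal_split(self):
        # two parallel A->B routes with equal scores: stage-1 optimum is a
        # face; the l2 stage must return the symmetric split
        mets = [Metabolite("A_c", "A", "c"), Metabolite("B_c", "B", "c")]
        rxns = [
            Reaction("R_in", {"A_c": 1.0}, 0, 4, "exchange"),
            Reaction("R_p1", {"A_c": -1.0, "B_c": 1.0}, 0, 10, "core", gpr="G1"),
            Reaction("R_p2", {"A_c": -1.0, "B_c": 1.0}, 0, 10, "core", gpr="G2"),
            Reaction("R_out", {"B_c": -1.0}, 0, 10, "exchange", gpr="G3"),
        ]
        model = build_model("d", rxns, mets, ["G1", "G2", "G3"])
        ctx = ContextModel("d", "s", {r.id for r in rxns}, {}, 1.0)
        sv = ReactionScoreVector("s", {"R_p1": 2.0, "R_p2": 2.0, "R_out": 4.0},
                                 {"R_in"})
        obj = spot_objective(model, ctx, sv)
        bounds = eflux2_bounds(model, ctx, sv)
        res = eflux2_solve(model, ctx, obj, bounds)
        assert res.fluxes["R_p1"] == pytest.approx(res.fluxes["R_p2"], abs=1e-6)
        assert res.residual <= 1e-6

    def test_objective_preserved_through_l2_stage(
        self, chain_model, chain_context, chain_scores
    ):
        obj = spot_objective(chain_model, chain_context, chain_scores)
        bounds = eflux2_bounds(chain_model, chain_context, chain_scores)
        res = eflux2_solve(chain_model, chain_context, obj, bounds)
        f_dot_v = sum(obj.f_prime[r] * res.fluxes[r] for r in res.fluxes)
        assert abs(f_dot_v - res.z_star) <= 1e-6 * max(1.0, abs(res.z_star))


class TestSpotOptimalityAgainstSampling:
    def test_no_random_feasible_direction_beats_spot(self):
        from gemflux import synthetic_data as sd
        from gemflux import expression as ex
        from gemflux.context_extraction import threshold_extract
        from gemflux._solvers import solve_lp_max

        rng = np.random.default_rng(7)
        for seed in range(3):
            sim = sd.SimulationConfig(seed=seed + 1, n_reactions=36)
            model, _ = sd.generate_model(sim)
            truth = sd.generate_state_fluxes(model, sim)
            expr = sd.generate_expression(model, truth, sim)
            tpm = ex.tpm_normalize(expr.counts, expr.lengths)
            profile = ex.aggregate_states(tpm, expr.sample_state, "mean")[0]
            sv = ex.score_reactions(model, profile)
            ctx = threshold_extract(model, sv)
            obj = spot_objective(model, ctx, sv)
            order = [r for r in model.reaction_ids if r in ctx.kept_reactions]
            S, _, _ = stoichiometric_matrix(model, order)
            g = np.array([sv.scores.get(r, 0.0) for r in order])
            lb = np.zeros(len(order))
            ub = np.ones(len(order))
            for _ in range(30):
                c = rng.normal(size=len(order))
                u, _opt = solve_lp_max(c, S, np.zeros(S.shape[0]), lb, ub)
                nu = np.linalg.norm(u)
                if nu < 1e-9:
                    continue
                cos_u = g @ u / (np.linalg.norm(g) * nu)
                assert obj.achieved_cosine >= cos_u - 1e-7


class TestMeasurableFluxes:
    def _results(self, values):
        return [FluxResult("s1", values, 0.0, 0.0, 0.0)]

    def test_strict_magnitude_threshold(self):
        table = measurable_fluxes(
            self._results({"a": 0.05, "b": 0.1, "c": 0.2, "d": -0.5})
        )
        assert set(table.index) == {"c", "d"}
        assert table.loc["d", "s1"] == -0.5

    def test_all_below_threshold_warns_empty(self):
        with pytest.warns(UserWarning, match="threshold"):
            table = measurable_fluxes(self._results({"a": 0.01}))
        assert table.empty

    def test_union_rule_retains_row_across_states(self):
        res = [
            FluxResult("s1", {"a": 0.0, "b": 0.5}, 0, 0, 0),
            FluxResult("s2", {"a": 0.05, "b": 0.01}, 0, 0, 0),
        ]
        table = measurable_fluxes(res)
        assert list(table.index) == ["b"]
        assert list(table.columns) == ["s1", "s2"]
        assert table.loc["b", "s2"] == 0.01
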