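"""End-to-end orchestration: simulate -> extract -> compare -> flux -> stats
-> trajectory, with a declarative config, per-stage outputs and a run
manifest.

Stage outputs are pure functions of (config, inputs, seed): every table is
written with sorted labels and fixed float formatting, so a rerun with the
same config is byte-identical (the manifest's timestamp aside).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    context_extraction as ce,
    expression as ex,
    flux_prediction as fp,
    flux_statistics as fs,
    model_comparison as mc,
    model_core as core,
    synthetic_data as sd,
    trajectory as tj,
)

__all__ = ["PipelineConfig", "AnalysisResult", "run_synthetic_analysis", "run_pipeline"]

_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "seed", "simulate", "simulate_options", "inputs", "aggregation_method",
    "flux_aggregation_method", "threshold", "alpha", "k_fluxes", "k_transport",
    "interior_compartment", "trajectory_root", "measurable_threshold",
    "keep_no_gpr",
}


@dataclass
class PipelineConfig:
    seed: int = 1
    simulate: bool = True
    simulate_options: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    #: per-gene aggregation feeding the extraction threshold (max-TPM rule)
    aggregation_method: str = "max"
    #: aggregation feeding the flux stage's scores/bounds (state-averaged)
    flux_aggregation_method: str = "mean"
    threshold: float = 1.0
    alpha: float = 0.05
    k_fluxes: int = 2
    k_transport: int = 4
    interior_compartment: str = "c"
    trajectory_root: str = "healthy"
    measurable_threshold: float = 0.1
    keep_no_gpr: bool = True

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_opts = raw.get("simulate_options", {})
        valid_sim = {f.name for f in dc_fields(sd.SimulationConfig)}
        bad = set(sim_opts) - valid_sim
        if bad:
            raise ValueError(f"unknown simulate_options keys: {sorted(bad)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def simulation_config(self) -> sd.SimulationConfig:
        opts = dict(self.simulate_options)
        opts.setdefault("seed", self.seed)
        return sd.SimulationConfig(**opts)

    def canonical_json(self) -> str:
        d = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        return json.dumps(d, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# In-memory analysis (the pipeline's computational core)
# ---------------------------------------------------------------------------

@dataclass
class AnalysisResult:
    model: core.MetabolicModel
    tasks: list[ce.MetabolicTask]
    truth: sd.GroundTruth | None
    expr: ex.ExpressionMatrix
    tpm: pd.DataFrame
    profiles: list[ex.StateProfile]
    scores: dict[str, ex.ReactionScoreVector]
    contexts: dict[str, ce.ContextModel]
    objectives: dict[str, fp.SpotObjective]
    bounds: dict[str, dict[str, tuple[float, float]]]
    flux_results: dict[str, fp.FluxResult]
    flux_table: pd.DataFrame            # all reactions x states (0 where absent)
    measurable: pd.DataFrame
    gene_trajectory: tj.TrajectoryResult
    flux_trajectory: tj.TrajectoryResult


def _flux_frame(results: dict[str, fp.FluxResult]) -> pd.DataFrame:
    table = pd.DataFrame({s: pd.Series(r.fluxes) for s, r in sorted(results.items())})
    return table.fillna(0.0).sort_index()


def run_synthetic_analysis(
    sim_config: sd.SimulationConfig,
    cfg: PipelineConfig | None = None,
) -> AnalysisResult:
    """Run the whole method on freshly generated synthetic data, in memory."""
    cfg = cfg or PipelineConfig(seed=sim_config.seed)
    model, tasks = sd.generate_model(sim_config)
    truth = sd.generate_state_fluxes(model, sim_config)
    expr = sd.generate_expression(model, truth, sim_config)
    return _analyze(model, tasks, expr, cfg, truth=truth)


def _analyze(model, tasks, expr, cfg: PipelineConfig, truth=None) -> AnalysisResult:
    tpm = ex.tpm_normalize(expr.counts, expr.lengths) if not expr.is_tpm else expr.counts
    profiles = ex.aggregate_states(tpm, expr.sample_state, method=cfg.aggregation_method)
    flux_profiles = ex.aggregate_states(
        tpm, expr.sample_state, method=cfg.flux_aggregation_method
    )
    scores: dict[str, ex.ReactionScoreVector] = {}
    contexts: dict[str, ce.ContextModel] = {}
    objectives: dict[str, fp.SpotObjective] = {}
    bounds_by_state: dict[str, dict[str, tuple[float, float]]] = {}
    flux_results: dict[str, fp.FluxResult] = {}
    for profile, flux_profile in zip(profiles, flux_profiles):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sv = ex.score_reactions(model, profile)
            sv_flux = ex.score_reactions(model, flux_profile)
        scores[profile.state] = sv
        ctx = ce.threshold_extract(model, sv, threshold=cfg.threshold,
                                   keep_no_gpr=cfg.keep_no_gpr)
        ctx = ce.gap_fill(ctx, model, tasks)
        contexts[profile.state] = ctx
        obj = fp.spot_objective(model, ctx, sv_flux)
        objectives[profile.state] = obj
        bounds = fp.eflux2_bounds(model, ctx, sv_flux)
        bounds_by_state[profile.state] = bounds
        flux_results[profile.state] = fp.eflux2_solve(model, ctx, obj, bounds)
    flux_table = _flux_frame(flux_results)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        measurable = fp.measurable_fluxes(
            list(flux_results.values()), threshold=cfg.measurable_threshold
        )
    gene_matrix = pd.DataFrame(
        {p.state: p.gene_values for p in profiles}
    ).T.sort_index()  # states x genes
    gene_traj = _trajectory_for(tj.StateMatrix(gene_matrix, "genes"), cfg)
    flux_traj = _trajectory_for(tj.StateMatrix(flux_table.T.sort_index(), "fluxes"), cfg)
    return AnalysisResult(
        model=model, tasks=tasks, truth=truth, expr=expr, tpm=tpm,
        profiles=profiles, scores=scores, contexts=contexts,
        objectives=objectives, bounds=bounds_by_state, flux_results=flux_results,
        flux_table=flux_table, measurable=measurable,
        gene_trajectory=gene_traj, flux_trajectory=flux_traj,
    )


def _trajectory_for(matrix: tj.StateMatrix, cfg: PipelineConfig) -> tj.TrajectoryResult:
    res = tj.pca(matrix)
    n_keep = tj.pc_variance_cutoff(res.variance_explained)
    coords = res.pc_coordinates.iloc[:, :n_keep]
    edges = tj.minimum_spanning_tree(points=coords)
    result = tj.TrajectoryResult(
        pc_coordinates=res.pc_coordinates,
        variance_explained=res.variance_explained,
        mst_edges=edges,
    )
    root = cfg.trajectory_root
    if root in matrix.observations:
        ordering, branches = tj.extract_trajectory(edges, root)
        result.orderings[root] = ordering
        result.branch_points = branches
    return result


# ---------------------------------------------------------------------------
# File-based pipeline
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path, index_label="id") -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label=index_label)


def run_pipeline(
    cfg: PipelineConfig,
    outdir,
    seed: int | None = None,
    resume: bool = False,
) -> Path:
    """Execute every stage and write outputs + manifest under ``outdir``.

    With ``resume``, an outdir whose outputs already exist is left alone
    stage by stage (inputs are regenerated deterministically either way).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        cfg.seed = seed
    manifest = {
        "config_hash": hashlib.sha256(cfg.canonical_json().encode()).hexdigest(),
        "seed": cfg.seed,
        "tolerances": {
            "feasibility": 1e-6, "uniqueness": 1e-5, "solver": 1e-9,
        },
        "stages": [],
        "status": "running",
        "started": datetime.now(timezone.utc).isoformat(),
    }
    try:
        inputs_dir = outdir / "inputs"
        if cfg.simulate:
            if not (resume and (inputs_dir / "model.json").exists()):
                sd.simulate(cfg.simulation_config(), inputs_dir)
            manifest["stages"].append("simulate")
            model = core.read_model(inputs_dir / "model.json")
            tasks = ce.read_tasks(inputs_dir / "tasks.json")
            counts = pd.read_csv(inputs_dir / "counts.tsv", sep="\t", index_col="gene")
            lengths = pd.read_csv(
                inputs_dir / "lengths.tsv", sep="\t", index_col="gene"
            )["length"]
            state_map = pd.read_csv(
                inputs_dir / "state_map.tsv", sep="\t", index_col="sample"
            )["state"].to_dict()
            expr = ex.ExpressionMatrix(counts=counts, sample_state=state_map,
                                       lengths=lengths)
        else:
            model, tasks, expr = _load_external_inputs(cfg)
        expr.validate(model)

        result = _analyze(model, tasks, expr, cfg)
        manifest["stages"] += ["expression", "extract", "flux", "trajectory"]

        # expression outputs
        profile_df = pd.DataFrame({p.state: p.gene_values for p in result.profiles})
        _write_tsv(profile_df.sort_index(), outdir / "state_profiles.tsv", "gene")

        # context models + provenance
        ctx_dir = outdir / "contexts"
        ctx_dir.mkdir(exist_ok=True)
        for state in sorted(result.contexts):
            ctx = result.contexts[state]
            ctx.to_json(ctx_dir / f"{state}.provenance.json")
            core.write_model(
                ce.context_to_model(model, ctx), ctx_dir / f"{state}.model.json"
            )

        # comparison
        ctx_list = [result.contexts[s] for s in sorted(result.contexts)]
        pm = mc.presence_matrix(ctx_list, model)
        _write_tsv(pm, outdir / "presence_matrix.tsv", "reaction")
        _write_tsv(mc.hamming_similarity(pm), outdir / "hamming_similarity.tsv", "model")
        _write_tsv(mc.rank_models(ctx_list, model), outdir / "rank_table.tsv", "model")
        _write_tsv(
            mc.differential_subsystems(ctx_list, model),
            outdir / "differential_subsystems.tsv", "subsystem",
        )
        manifest["stages"].append("compare")

        # fluxes
        sub_col = pd.Series(
            {r: model.subsystem_of(r) for r in result.flux_table.index},
            name="subsystem",
        )
        flux_out = pd.concat([sub_col, result.flux_table], axis=1)
        _write_tsv(flux_out, outdir / "fluxes.tsv", "reaction")
        meas_out = pd.concat(
            [sub_col.reindex(result.measurable.index), result.measurable], axis=1
        )
        _write_tsv(meas_out, outdir / "measurable_fluxes.tsv", "reaction")
        meta = {
            s: {
                "z_star": result.flux_results[s].z_star,
                "achieved_cosine": result.objectives[s].achieved_cosine,
                "residual": result.flux_results[s].residual,
                "l2_norm": result.flux_results[s].l2_norm,
                "solver_status": result.flux_results[s].solver_status,
            }
            for s in sorted(result.flux_results)
        }
        (outdir / "flux_metadata.json").write_text(json.dumps(meta, indent=2) + "\n")

        # statistics
        _run_stats_stage(result, model, cfg, outdir)
        manifest["stages"].append("stats")

        # trajectory outputs
        for kind, traj in (("fluxes", result.flux_trajectory),
                           ("genes", result.gene_trajectory)):
            _write_tsv(traj.pc_coordinates, outdir / f"pca_{kind}.tsv", "state")
            edges = pd.DataFrame(traj.mst_edges, columns=["from", "to", "weight"])
            edges.to_csv(outdir / f"mst_{kind}.tsv", sep="\t", index=False,
                         float_format=_FLOAT_FMT)
            payload = {
                "variance_explained": [float(x) for x in traj.variance_explained],
                "orderings": traj.orderings,
                "branch_points": traj.branch_points,
            }
            (outdir / f"trajectory_{kind}.json").write_text(
                json.dumps(payload, indent=2) + "\n"
            )
        manifest["status"] = "success"
    except Exception as exc:
        manifest["status"] = f"failed: {type(exc).__name__}: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir


def _load_external_inputs(cfg: PipelineConfig):
    paths = cfg.inputs
    for key in ("model", "state_map"):
        if key not in paths:
            raise ValueError(f"config inputs missing required path {key!r}")
    model = core.read_model(paths["model"])
    tasks = ce.read_tasks(paths["tasks"]) if "tasks" in paths else []
    state_map = pd.read_csv(paths["state_map"], sep="\t", index_col="sample")[
        "state"
    ].to_dict()
    if "tpm" in paths:
        if "counts" in paths:
            raise ValueError("provide either tpm or counts+lengths, not both")
        tpm = pd.read_csv(paths["tpm"], sep="\t", index_col="gene")
        expr = ex.ExpressionMatrix(counts=tpm, sample_state=state_map, is_tpm=True)
    else:
        counts = pd.read_csv(paths["counts"], sep="\t", index_col="gene")
        lengths = pd.read_csv(paths["lengths"], sep="\t", index_col="gene")["length"]
        expr = ex.ExpressionMatrix(counts=counts, sample_state=state_map,
                                   lengths=lengths)
    return model, tasks, expr


def _run_stats_stage(result: AnalysisResult, model, cfg: PipelineConfig, outdir: Path):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sums = fs.subsystem_flux_sums(result.flux_table, model)
        _write_tsv(sums.sums, outdir / "subsystem_flux_sums.tsv", "subsystem")
        screen = fs.subsystem_screen(result.flux_table, model, alpha=cfg.alpha)
        _write_tsv(screen, outdir / "subsystem_screen.tsv", "subsystem")

        if len(result.measurable) >= cfg.k_fluxes:
            clusters = fs.hierarchical_cluster(result.measurable, k=cfg.k_fluxes)
            pd.Series(clusters.assignments).sort_index().to_csv(
                outdir / "flux_clusters.tsv", sep="\t", header=["cluster"],
                index_label="reaction",
            )
        transport_rxns = [
            r for r in result.measurable.index if model.is_transport(r)
        ]
        if len(transport_rxns) >= cfg.k_transport:
            tmat = result.measurable.loc[transport_rxns]
            tclusters = fs.hierarchical_cluster(tmat, k=cfg.k_transport)
            pd.Series(tclusters.assignments).sort_index().to_csv(
                outdir / "transport_clusters.tsv", sep="\t", header=["cluster"],
                index_label="reaction",
            )
            freq = fs.gene_rule_frequency(tclusters, model)
            freq_rows = []
            for cid in sorted(freq.per_cluster):
                df = freq.per_cluster[cid].copy()
                df.insert(0, "cluster", cid)
                freq_rows.append(df)
            if freq_rows:
                pd.concat(freq_rows, ignore_index=True).to_csv(
                    outdir / "transport_rule_frequency.tsv", sep="\t", index=False,
                    float_format=_FLOAT_FMT,
                )
            signs = result.measurable.mean(axis=1).to_dict()
            dir_rows = []
            for cid in sorted(set(tclusters.assignments.values())):
                dmap = fs.transport_direction_map(
                    tclusters.members(cid), model, signs,
                    interior=cfg.interior_compartment,
                )
                dmap = dmap.reset_index()
                dmap.insert(0, "cluster", cid)
                dir_rows.append(dmap)
            pd.concat(dir_rows, ignore_index=True).to_csv(
                outdir / "transport_direction.tsv", sep="\t", index=False,
            )
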