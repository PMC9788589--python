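"""Synthetic toy models, ground-truth fluxes, and noisy expression data.

The generator emulates the study design every pipeline stage is exercised
on: 8 liver-state labels (4 with increasing alcohol-associated severity —
healthy, early_ASH, nonsevere_AH, severe_AH, explant_AH — plus a
non-alcohol branch of comp_cirrhosis, HCV and NASH), ~10 RNA-seq samples
per state, and a toy metabolic network of metabolite-disjoint pathway
modules, each an import -> conversion -> export chain through external,
cytosolic and organelle compartments.

Two modules are planted: a glutathione-like chain whose flux rises
monotonically with alcohol-disease severity (sequential dysregulation),
and a lipid-like chain perturbed only in the non-alcohol states, so the
state geometry has a recoverable two-branch trajectory.  Gene expression
tracks ground-truth reaction activity through the GPR rules: every gene's
state-mean TPM is proportional to its reaction's flux, converted to
expected fragment counts via gene lengths and sampled with
negative-binomial noise.  A single integer seed fixes everything.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .context_extraction import MetabolicTask, write_tasks
from .expression import ExpressionMatrix
from .model_core import MetabolicModel, Metabolite, Reaction, parse_gpr, write_model

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_model",
    "generate_state_fluxes",
    "generate_expression",
    "simulate",
    "ALD_PATH",
    "NALD_PATH",
]

#: alcohol-disease severity path (trajectory ground truth), root first
ALD_PATH = ["healthy", "early_ASH", "nonsevere_AH", "severe_AH", "explant_AH"]
#: non-alcohol branch, root first
NALD_PATH = ["healthy", "comp_cirrhosis", "HCV", "NASH"]

_RXN_PER_MODULE = 6  # exchange-in, transport-in, 2 conversions, transport-out, exchange-out


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, fixed by one seed.

    ALD multipliers scale the planted glutathione-like chain and are
    strictly increasing with severity; NALD multipliers scale the
    lipid-like chain in the non-alcohol states only.  Dispersion is the
    negative-binomial overdispersion (var = mu + dispersion * mu^2);
    0 means noiseless expected counts.
    """

    seed: int = 1
    states: tuple[str, ...] = (
        "explant_AH", "severe_AH", "nonsevere_AH", "early_ASH",
        "healthy", "comp_cirrhosis", "HCV", "NASH",
    )
    samples_per_state: int = 10
    n_reactions: int = 60
    compartments: tuple[str, ...] = ("e", "c", "m")
    ald_multipliers: dict[str, float] = field(
        default_factory=lambda: {
            "early_ASH": 1.5, "nonsevere_AH": 2.2,
            "severe_AH": 3.1, "explant_AH": 4.2,
        }
    )
    nald_multipliers: dict[str, float] = field(
        default_factory=lambda: {"comp_cirrhosis": 2.0, "HCV": 3.0, "NASH": 4.0}
    )
    dispersion: float = 0.05
    total_fragments: float = 2e7
    n_background_genes: int = 400
    tpm_per_flux: float = 5.0        # active gene state-mean TPM per unit |v|
    inactive_tpm: float = 0.2        # state-mean TPM of genes of inactive reactions
    gpr_mix: tuple[float, float, float] = (0.5, 0.25, 0.25)  # single / AND / OR
    module_jitter_sd: float = 0.05   # lognormal sd of filler-module state scales
    subsystem_palette: tuple[str, ...] = (
        "fatty acid oxidation", "pentose phosphate pathway",
        "bile acid biosynthesis", "amino acid metabolism",
        "carnitine shuttle", "prostaglandin biosynthesis",
        "galactose metabolism", "glycolysis",
    )

    @property
    def n_modules(self) -> int:
        return self.n_reactions // _RXN_PER_MODULE

    def validate(self) -> None:
        if self.n_modules < 3:
            raise ValueError(
                "n_reactions too small: need at least 3 six-reaction modules "
                "(two planted chains plus one filler) to form a connected design"
            )
        if self.samples_per_state < 1:
            raise ValueError("need at least one sample per state")
        mults = [self.ald_multipliers[s] for s in ALD_PATH[1:]]
        if not all(b > a for a, b in zip(mults, mults[1:])):
            raise ValueError("ALD multipliers must increase with severity")


@dataclass
class GroundTruth:
    """Planted truth the recovery tests score against."""

    state_fluxes: dict[str, dict[str, float]]
    active_reactions: dict[str, list[str]]
    ald_chain: list[str]             # reaction ids of the planted ALD module
    nald_chain: list[str]
    ald_path: list[str] = field(default_factory=lambda: list(ALD_PATH))
    nald_path: list[str] = field(default_factory=lambda: list(NALD_PATH))
    branch_state: str = "healthy"

    def flux_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.state_fluxes).fillna(0.0).sort_index()

    def to_json(self, path) -> None:
        payload = {
            "state_fluxes": {
                s: {r: self.state_fluxes[s][r] for r in sorted(self.state_fluxes[s])}
                for s in sorted(self.state_fluxes)
            },
            "active_reactions": {
                s: sorted(self.active_reactions[s]) for s in sorted(self.active_reactions)
            },
            "ald_chain": self.ald_chain,
            "nald_chain": self.nald_chain,
            "ald_path": self.ald_path,
            "nald_path": self.nald_path,
            "branch_state": self.branch_state,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            state_fluxes=raw["state_fluxes"],
            active_reactions={s: list(v) for s, v in raw["active_reactions"].items()},
            ald_chain=raw["ald_chain"],
            nald_chain=raw["nald_chain"],
            ald_path=raw["ald_path"],
            nald_path=raw["nald_path"],
            branch_state=raw["branch_state"],
        )


# ---------------------------------------------------------------------------
# Model generation
# ---------------------------------------------------------------------------

def _module_subsystem(config: SimulationConfig, m: int) -> str:
    if m == 0:
        return "glutathione metabolism"
    if m == 1:
        return "lipid metabolism"
    palette = config.subsystem_palette
    return palette[(m - 2) % len(palette)]


def generate_model(config: SimulationConfig) -> tuple[MetabolicModel, list[MetabolicTask]]:
    """Build the toy network and its viability task list.

    Each module ``Mxx`` is a chain: exchange-in of species Pxx, transport
    into the cytosol, two conversions (organelle-routed for even filler
    modules), transport of the product Qxx back out, exchange-out.
    Transport reactions sit in the "transport" subsystem, exchanges in
    "exchange", conversions in the module's pathway subsystem.  Every
    non-exchange reaction gets a GPR — a single gene, an AND pair (enzyme
    complex) or an OR pair (isozymes) in the configured proportions — with
    genes private to one reaction so expression maps cleanly onto activity.
    One viability task per planted chain requires producing the product
    from the substrate.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    genes: list[str] = []
    gene_counter = [0]

    def new_genes(n: int) -> list[str]:
        out = [f"G{gene_counter[0] + i:04d}" for i in range(n)]
        gene_counter[0] += n
        genes.extend(out)
        return out

    def make_gpr(rng) -> str:
        p_single, p_and, _ = config.gpr_mix
        u = rng.random()
        if u < p_single:
            return new_genes(1)[0]
        if u < p_single + p_and:
            g = new_genes(2)
            return f"{g[0]} AND {g[1]}"
        g = new_genes(2)
        return f"{g[0]} OR {g[1]}"

    def add_met(species: str, comp: str) -> str:
        met_id = f"{species}_{comp}"
        metabolites.append(Metabolite(id=met_id, name=species, compartment=comp))
        return met_id

    for m in range(config.n_modules):
        tag = f"M{m:02d}"
        sub = _module_subsystem(config, m)
        P, X, Q = f"P{m:02d}", f"X{m:02d}", f"Q{m:02d}"
        p_e = add_met(P, "e")
        p_c = add_met(P, "c")
        organelle_route = m >= 2 and m % 2 == 0
        x_comp = "m" if organelle_route else "c"
        x_id = add_met(X, x_comp)
        q_c = add_met(Q, "c")
        q_e = add_met(Q, "e")
        # every third filler module gets a reversible importer for coverage
        rev_import = m >= 2 and m % 3 == 0
        reactions.append(Reaction(
            id=f"{tag}_EXIN", stoichiometry={p_e: 1.0},
            lower_bound=0.0, upper_bound=1000.0, subsystem="exchange",
            name=f"{P} exchange in",
        ))
        reactions.append(Reaction(
            id=f"{tag}_TIN", stoichiometry={p_e: -1.0, p_c: 1.0},
            lower_bound=-1000.0 if rev_import else 0.0, upper_bound=1000.0,
            subsystem="transport", gpr=make_gpr(rng), name=f"{P} import",
        ))
        reactions.append(Reaction(
            id=f"{tag}_C1", stoichiometry={p_c: -1.0, x_id: 1.0},
            lower_bound=0.0, upper_bound=1000.0, subsystem=sub,
            gpr=make_gpr(rng), name=f"{P} -> {X}",
        ))
        reactions.append(Reaction(
            id=f"{tag}_C2", stoichiometry={x_id: -1.0, q_c: 1.0},
            lower_bound=0.0, upper_bound=1000.0, subsystem=sub,
            gpr=make_gpr(rng), name=f"{X} -> {Q}",
        ))
        reactions.append(Reaction(
            id=f"{tag}_TOUT", stoichiometry={q_c: -1.0, q_e: 1.0},
            lower_bound=0.0, upper_bound=1000.0, subsystem="transport",
            gpr=make_gpr(rng), name=f"{Q} export",
        ))
        reactions.append(Reaction(
            id=f"{tag}_EXOUT", stoichiometry={q_e: -1.0},
            lower_bound=0.0, upper_bound=1000.0, subsystem="exchange",
            name=f"{Q} exchange out",
        ))

    model = MetabolicModel(
        model_id=f"toy_liver_seed{config.seed}",
        reactions=reactions,
        metabolites=metabolites,
        genes=genes,
        compartments=list(config.compartments),
        compartment_names={"e": "external", "c": "cytosol", "m": "organelle"},
    )
    model.validate()
    tasks = [
        MetabolicTask(
            id=f"task_M{m:02d}",
            inputs=[(f"P{m:02d}_e", 10.0)],
            outputs=[(f"Q{m:02d}_e", 0.1)],
            description=f"produce Q{m:02d} from P{m:02d} (module M{m:02d} viability)",
        )
        for m in (0, 1)
    ]
    return model, tasks


def _module_of(rxn_id: str) -> int:
    return int(rxn_id[1:3])


# ---------------------------------------------------------------------------
# Ground-truth fluxes
# ---------------------------------------------------------------------------

def generate_state_fluxes(model: MetabolicModel, config: SimulationConfig) -> GroundTruth:
    """Feasible per-state flux vectors with the planted dysregulation.

    Each module chain carries a uniform flux (automatically steady-state
    for a metabolite-disjoint chain): a seeded per-module base rate —
    log-uniform in [0.4, 2.5] for filler pathways, mirroring the orders-of-
    magnitude spread of real pathway activities, and fixed (1.2 / 1.0) for
    the two planted chains so their effect sizes are stated conditions —
    times a per-state lognormal jitter for filler modules, times the
    planted ALD / NALD severity multipliers for the two planted chains
    (no jitter there, so the severity ordering is exact).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    n_mod = config.n_modules
    base = np.exp(rng.uniform(np.log(0.4), np.log(2.5), size=n_mod))
    base[0], base[1] = 1.2, 1.0
    states = list(config.states)
    jitter = {
        s: np.exp(rng.normal(0.0, config.module_jitter_sd, size=n_mod)) for s in states
    }
    state_fluxes: dict[str, dict[str, float]] = {}
    active: dict[str, list[str]] = {}
    for s in states:
        scale = np.empty(n_mod)
        for m in range(n_mod):
            if m == 0:
                scale[m] = base[0] * config.ald_multipliers.get(s, 1.0)
            elif m == 1:
                scale[m] = base[1] * config.nald_multipliers.get(s, 1.0)
            else:
                scale[m] = base[m] * jitter[s][m]
        v = {r.id: float(scale[_module_of(r.id)]) for r in model.reactions}
        state_fluxes[s] = v
        active[s] = sorted(r for r, val in v.items() if abs(val) > 0.1)
    ald_chain = sorted(r.id for r in model.reactions if _module_of(r.id) == 0)
    nald_chain = sorted(r.id for r in model.reactions if _module_of(r.id) == 1)
    return GroundTruth(
        state_fluxes=state_fluxes,
        active_reactions=active,
        ald_chain=ald_chain,
        nald_chain=nald_chain,
    )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def generate_expression(
    model: MetabolicModel,
    truth: GroundTruth,
    config: SimulationConfig,
) -> ExpressionMatrix:
    """Noisy counts whose GPR scores track ground-truth reaction activity.

    Every model gene's state-mean TPM is ``tpm_per_flux * |v|`` of its
    reaction when active (above the 1-TPM extraction threshold by
    construction) and ``inactive_tpm`` otherwise.  Background genes (not in
    the model) absorb the rest of the library so that per-state target
    TPMs sum to 1e6 and realized TPM matches the target in the noiseless
    limit.  Counts are negative-binomial around the expected fragment
    counts; dispersion 0 returns the expectations exactly.
    """
    rng = np.random.default_rng(config.seed + 2)
    gene_rxn: dict[str, str] = {}
    for r in model.reactions:
        tree = parse_gpr(r.gpr)
        if tree is None:
            continue
        for g in tree.genes():
            gene_rxn[g] = r.id
    model_genes = list(model.genes)
    bg_genes = [f"B{i:04d}" for i in range(config.n_background_genes)]
    all_genes = model_genes + bg_genes
    lengths = pd.Series(
        np.exp(rng.uniform(np.log(500), np.log(5000), size=len(all_genes))),
        index=all_genes, name="length",
    ).round(0)
    bg_base = np.exp(rng.uniform(np.log(1.0), np.log(100.0), size=len(bg_genes)))

    states = list(config.states)
    samples, sample_state = [], {}
    columns = {}
    for s in states:
        active = set(truth.active_reactions[s])
        t_model = np.array([
            config.tpm_per_flux * abs(truth.state_fluxes[s][gene_rxn[g]])
            if gene_rxn[g] in active else config.inactive_tpm
            for g in model_genes
        ])
        bg_scale = (1e6 - t_model.sum()) / bg_base.sum()
        targets = np.concatenate([t_model, bg_base * bg_scale])
        weights = targets * lengths.values
        mu = config.total_fragments * weights / weights.sum()
        for i in range(config.samples_per_state):
            name = f"{s}_s{i:02d}"
            samples.append(name)
            sample_state[name] = s
            if config.dispersion <= 0:
                columns[name] = mu.copy()
            else:
                r_nb = 1.0 / config.dispersion
                p_nb = r_nb / (r_nb + mu)
                columns[name] = rng.negative_binomial(r_nb, p_nb).astype(float)
    counts = pd.DataFrame(columns, index=all_genes)
    expr = ExpressionMatrix(counts=counts, sample_state=sample_state, lengths=lengths)
    expr.validate(model)
    return expr


# ---------------------------------------------------------------------------
# One-call emitter
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Generate everything and write it to ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model, tasks = generate_model(config)
    truth = generate_state_fluxes(model, config)
    expr = generate_expression(model, truth, config)
    paths = {
        "model": outdir / "model.json",
        "tasks": outdir / "tasks.json",
        "counts": outdir / "counts.tsv",
        "lengths": outdir / "lengths.tsv",
        "state_map": outdir / "state_map.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_model(model, paths["model"])
    write_tasks(tasks, paths["tasks"])
    expr.counts.to_csv(paths["counts"], sep="\t", index_label="gene")
    expr.lengths.to_frame().to_csv(paths["lengths"], sep="\t", index_label="gene")
    pd.Series(expr.sample_state, name="state").to_csv(
        paths["state_map"], sep="\t", index_label="sample"
    )
    truth.to_json(paths["ground_truth"])
    return paths
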