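"""Constraint-based metabolic model core: data types, JSON I/O, GPR rules.

A metabolic model is a stoichiometric reconstruction: reactions convert
metabolites (each living in one compartment) at rates ("fluxes", mmol/gDW/h)
bounded below and above.  Each reaction belongs to exactly one biological
subsystem and may carry a gene-protein-reaction (GPR) rule — a boolean
expression over gene identifiers in which AND encodes an enzyme complex
(every subunit required) and OR encodes isozymes (any one suffices).

The canonical interchange format is a small documented JSON dialect::

    {"id": ..., "compartments": [{"id", "name"}],
     "metabolites": [{"id", "name", "compartment"}],
     "reactions": [{"id", "name", "stoichiometry": {met_id: coef},
                    "lower_bound", "upper_bound", "subsystem", "gpr"}],
     "genes": [id, ...]}

Negative stoichiometric coefficients are consumed, positive produced.
Transport and exchange flags are always derived from stoichiometry, never
read from the file, so downstream transport analyses are reproducible from
structure alone.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "GprTree",
    "GprParseError",
    "ModelValidationError",
    "parse_gpr",
    "evaluate_gpr",
    "canonical_gpr",
    "read_model",
    "write_model",
    "stoichiometric_matrix",
]


class ModelValidationError(ValueError):
    """A model violates a structural invariant (dangling reference, bad bounds...)."""


class GprParseError(ValueError):
    """A GPR string is not a well-formed boolean expression."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


# ---------------------------------------------------------------------------
# GPR trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GprTree:
    """Node of a GPR expression tree.

    Either a leaf (``gene`` set, ``op`` None) or an operator node with
    ``op`` in {"AND", "OR"} and >= 2 children.  AND binds tighter than OR.
    """

    op: str | None = None
    gene: str | None = None
    children: tuple["GprTree", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return self.op is None

    def genes(self) -> set[str]:
        if self.is_leaf:
            return {self.gene}
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def unparse(self) -> str:
        if self.is_leaf:
            return self.gene
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            s = c.unparse()
            # parenthesize an OR child under AND (AND binds tighter)
            if self.op == "AND" and c.op == "OR":
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)


_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(rule: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    while pos < len(rule):
        m = _TOKEN_RE.match(rule, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(rule: str) -> GprTree | None:
    """Parse a GPR string into a :class:`GprTree`.

    Operators AND/OR are case-insensitive; AND binds tighter than OR;
    parentheses override precedence.  The empty string (no rule) returns
    ``None`` as the explicit no-GPR marker.

    Raises
    ------
    GprParseError
        On unbalanced parentheses or dangling operators, with the
        character position of the offending token.
    """
    if rule is None or rule.strip() == "":
        return None
    tokens = _tokenize(rule)
    idx = 0

    def peek():
        return tokens[idx][0] if idx < len(tokens) else None

    def parse_or() -> GprTree:
        nonlocal idx
        children = [parse_and()]
        while peek() is not None and peek().upper() == "OR":
            idx += 1
            children.append(parse_and())
        if len(children) == 1:
            return children[0]
        return GprTree(op="OR", children=tuple(children))

    def parse_and() -> GprTree:
        nonlocal idx
        children = [parse_atom()]
        while peek() is not None and peek().upper() == "AND":
            idx += 1
            children.append(parse_atom())
        if len(children) == 1:
            return children[0]
        return GprTree(op="AND", children=tuple(children))

    def parse_atom() -> GprTree:
        nonlocal idx
        if idx >= len(tokens):
            raise GprParseError("unexpected end of rule (dangling operator)", len(rule))
        tok, pos = tokens[idx]
        if tok == "(":
            idx += 1
            node = parse_or()
            if peek() != ")":
                raise GprParseError("unbalanced parentheses", pos)
            idx += 1
            return node
        if tok == ")":
            raise GprParseError("unbalanced parentheses", pos)
        if tok.upper() in ("AND", "OR"):
            raise GprParseError(f"dangling operator {tok!r}", pos)
        idx += 1
        return GprTree(gene=tok)

    tree = parse_or()
    if idx < len(tokens):
        raise GprParseError(f"unexpected token {tokens[idx][0]!r}", tokens[idx][1])
    return tree


def evaluate_gpr(tree: GprTree | None, gene_values: dict[str, float]) -> float:
    """Evaluate a GPR tree against non-negative per-gene expression values.

    AND -> min over children (complex limited by scarcest subunit),
    OR -> max (any isozyme suffices), leaf -> the gene's value.  A gene
    missing from ``gene_values`` scores 0.0 and emits a warning: absent
    evidence excludes.
    """
    if tree is None:
        raise ValueError("cannot evaluate the no-GPR marker (None)")
    if tree.is_leaf:
        if tree.gene not in gene_values:
            warnings.warn(
                f"gene {tree.gene!r} missing from expression values; scored 0.0",
                stacklevel=2,
            )
            return 0.0
        return float(gene_values[tree.gene])
    vals = [evaluate_gpr(c, gene_values) for c in tree.children]
    return min(vals) if tree.op == "AND" else max(vals)


def canonical_gpr(rule: str | GprTree | None) -> str:
    """Canonical string form of a GPR rule: operands sorted recursively.

    Makes "G1 AND G2" and "G2 AND G1" identical for unique-rule counting.
    Empty rule canonicalizes to the empty string.
    """
    if rule is None:
        return ""
    tree = parse_gpr(rule) if isinstance(rule, str) else rule
    if tree is None:
        return ""

    def canon(node: GprTree) -> str:
        if node.is_leaf:
            return node.gene
        parts = sorted(canon(c) for c in node.children)
        joined = f" {node.op} ".join(
            f"({p})" if (node.op == "AND" and " OR " in p) else p for p in parts
        )
        return joined

    return canon(tree)


# ---------------------------------------------------------------------------
# Model data types
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    id: str
    name: str
    compartment: str

    @property
    def species(self) -> str:
        """Compartment-free chemical species key (used to detect transport)."""
        if self.name:
            return self.name
        suffix = f"_{self.compartment}"
        return self.id[: -len(suffix)] if self.id.endswith(suffix) else self.id


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    subsystem: str
    gpr: str = ""
    name: str = ""

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def gpr_tree(self) -> GprTree | None:
        return parse_gpr(self.gpr)


@dataclass
class MetabolicModel:
    model_id: str
    reactions: list[Reaction]
    metabolites: list[Metabolite]
    genes: list[str]
    compartments: list[str]
    compartment_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}

    # -- lookups ------------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_index[rxn_id]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def subsystem_of(self, rxn_id: str) -> str:
        return self._rxn_index[rxn_id].subsystem

    # -- derived structural flags ------------------------------------------
    def is_exchange(self, rxn_id: str) -> bool:
        """True for single-metabolite boundary reactions (system in/outflows)."""
        return len(self.reaction(rxn_id).stoichiometry) == 1

    def is_transport(self, rxn_id: str) -> bool:
        """True iff the reaction moves a chemical species between compartments.

        Derived from stoichiometry: some species appears in the reaction in
        two or more distinct compartments.
        """
        rxn = self.reaction(rxn_id)
        comps_by_species: dict[str, set[str]] = {}
        for met_id in rxn.stoichiometry:
            met = self._met_index[met_id]
            comps_by_species.setdefault(met.species, set()).add(met.compartment)
        return any(len(c) > 1 for c in comps_by_species.values())

    def transported_species(self, rxn_id: str) -> list[str]:
        """Species moved between compartments by a transport reaction."""
        rxn = self.reaction(rxn_id)
        comps_by_species: dict[str, set[str]] = {}
        for met_id in rxn.stoichiometry:
            met = self._met_index[met_id]
            comps_by_species.setdefault(met.species, set()).add(met.compartment)
        return sorted(s for s, c in comps_by_species.items() if len(c) > 1)

    def validate(self) -> None:
        """Enforce all structural invariants; raise ModelValidationError."""
        rxn_ids = [r.id for r in self.reactions]
        met_ids = [m.id for m in self.metabolites]
        dup_r = _duplicates(rxn_ids)
        if dup_r:
            raise ModelValidationError(f"duplicate reaction ids: {sorted(dup_r)}")
        dup_m = _duplicates(met_ids)
        if dup_m:
            raise ModelValidationError(f"duplicate metabolite ids: {sorted(dup_m)}")
        met_set = set(met_ids)
        gene_set = set(self.genes)
        comp_set = set(self.compartments)
        dangling_mets = set()
        dangling_genes = set()
        for rxn in self.reactions:
            for met_id in rxn.stoichiometry:
                if met_id not in met_set:
                    dangling_mets.add((rxn.id, met_id))
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelValidationError(
                    f"reaction {rxn.id!r}: lower_bound {rxn.lower_bound} > "
                    f"upper_bound {rxn.upper_bound}"
                )
            if not rxn.subsystem:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} has no subsystem label"
                )
            tree = parse_gpr(rxn.gpr)
            if tree is not None:
                missing = tree.genes() - gene_set
                if missing:
                    dangling_genes.update((rxn.id, g) for g in missing)
        if dangling_mets:
            raise ModelValidationError(
                "reactions reference undeclared metabolites: "
                + ", ".join(f"{r}->{m}" for r, m in sorted(dangling_mets))
            )
        if dangling_genes:
            raise ModelValidationError(
                "GPR rules reference undeclared genes: "
                + ", ".join(f"{r}->{g}" for r, g in sorted(dangling_genes))
            )
        bad_comp = {m.id for m in self.metabolites if m.compartment not in comp_set}
        if bad_comp:
            raise ModelValidationError(
                f"metabolites in undeclared compartments: {sorted(bad_comp)}"
            )


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for x in items:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups


# ---------------------------------------------------------------------------
# JSON dialect I/O
# ---------------------------------------------------------------------------

def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.model_id,
        "compartments": [
            {"id": c, "name": model.compartment_names.get(c, c)}
            for c in model.compartments
        ],
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "subsystem": r.subsystem,
                "gpr": r.gpr,
            }
            for r in model.reactions
        ],
        "genes": list(model.genes),
    }


def write_model(model: MetabolicModel, path) -> None:
    """Write a model to the JSON dialect (canonical form: sorted stoichiometry,
    2-space indent) so that read/write round-trips are byte-identical."""
    with open(path, "w") as fh:
        json.dump(_model_to_dict(model), fh, indent=2, sort_keys=False)
        fh.write("\n")


def read_model(path) -> MetabolicModel:
    """Read and validate a model from the JSON dialect.

    Raises a parse error naming the offending field on malformed input and
    :class:`ModelValidationError` on invariant violations.
    """
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed model JSON in {path}: {exc}") from exc
    return model_from_dict(raw)


def model_from_dict(raw: dict) -> MetabolicModel:
    for key in ("id", "compartments", "metabolites", "reactions", "genes"):
        if key not in raw:
            raise ValueError(f"model JSON missing required field {key!r}")
    compartments = [c["id"] for c in raw["compartments"]]
    comp_names = {c["id"]: c.get("name", c["id"]) for c in raw["compartments"]}
    metabolites = [
        Metabolite(id=m["id"], name=m.get("name", ""), compartment=m["compartment"])
        for m in raw["metabolites"]
    ]
    reactions = []
    for r in raw["reactions"]:
        try:
            reactions.append(
                Reaction(
                    id=r["id"],
                    name=r.get("name", ""),
                    stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                    lower_bound=float(r["lower_bound"]),
                    upper_bound=float(r["upper_bound"]),
                    subsystem=r["subsystem"],
                    gpr=r.get("gpr", ""),
                )
            )
        except KeyError as exc:
            raise ValueError(
                f"reaction entry {r.get('id', '<no id>')!r} missing field {exc}"
            ) from exc
    model = MetabolicModel(
        model_id=raw["id"],
        reactions=reactions,
        metabolites=metabolites,
        genes=list(raw["genes"]),
        compartments=compartments,
        compartment_names=comp_names,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Stoichiometric matrix
# ---------------------------------------------------------------------------

def stoichiometric_matrix(
    model: MetabolicModel, reaction_ids: list[str] | None = None
) -> tuple[np.ndarray, list[str], list[str]]:
    """Dense stoichiometric matrix S (metabolites x reactions).

    Restricted to ``reaction_ids`` if given (parent order preserved); rows
    cover only metabolites touched by the included reactions.
    Returns (S, metabolite_ids, reaction_ids).
    """
    if reaction_ids is None:
        rxns = model.reactions
    else:
        keep = set(reaction_ids)
        rxns = [r for r in model.reactions if r.id in keep]
    met_ids: list[str] = []
    met_pos: dict[str, int] = {}
    for r in rxns:
        for m in r.stoichiometry:
            if m not in met_pos:
                met_pos[m] = len(met_ids)
                met_ids.append(m)
    S = np.zeros((len(met_ids), len(rxns)))
    for j, r in enumerate(rxns):
        for m, coef in r.stoichiometry.items():
            S[met_pos[m], j] = coef
    return S, met_ids, [r.id for r in rxns]
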