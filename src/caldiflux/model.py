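"""Domain types for stoichiometric metabolic models.

A :class:`Model` is a catalog of compartmentalized :class:`Compound` objects
plus a catalog of :class:`Reaction` objects, one of which is designated the
biomass pseudo-reaction.  Stoichiometric coefficients are stored as exact
rationals (:class:`fractions.Fraction`) so that mass/charge balance checks can
be performed without floating-point slop; they are converted to floats only at
the LP boundary.

Strain engineering is expressed declaratively with :class:`StrainDesign`
(gene/reaction deletions, knock-in insertions, directionality overrides) and
applied with :func:`apply_design`, which never mutates its input.  Gene
deletions are realized by zeroing flux bounds rather than removing reactions,
so downstream FVA/MOMA reports keep a stable reaction index.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence, Union

from scipy import sparse as sp

__all__ = [
    "Compound",
    "GeneAssociation",
    "Reaction",
    "Model",
    "MediumSpec",
    "StrainDesign",
    "ModelValidationError",
    "parse_gene_association",
    "evaluate_gene_association",
    "apply_design",
    "stoichiometric_matrix",
]

COMPARTMENTS = ("c", "e")

#: Reaction categories.  ``cytosolic``/``transmembrane``/``extracellular``
#: follow the compartments a reaction touches; ``exchange`` reactions move a
#: single species across the system boundary; ``biomass`` and ``sink`` are
#: pseudo-reactions excluded from balance checks.
REACTION_KINDS = (
    "cytosolic",
    "transmembrane",
    "extracellular",
    "exchange",
    "biomass",
    "sink",
)


class ModelValidationError(ValueError):
    """Raised when a model or one of its components violates an invariant."""


# ---------------------------------------------------------------------------
# Gene associations
# ---------------------------------------------------------------------------

# A gene association is a boolean expression tree over locus-tag leaves.
# Internal nodes are ("and", children) / ("or", children); leaves are strings.
GeneExpr = Union[str, tuple]


@dataclass(frozen=True)
class GeneAssociation:
    """Boolean gene-protein-reaction rule.

    The reaction is active iff the expression evaluates true when deleted
    genes are false and all other genes are true.
    """

    expr: GeneExpr

    def evaluate(self, deleted: Iterable[str]) -> bool:
        return evaluate_gene_association(self, deleted)

    def genes(self) -> frozenset[str]:
        out: set[str] = set()

        def walk(node: GeneExpr) -> None:
            if isinstance(node, str):
                out.add(node)
            else:
                for child in node[1]:
                    walk(child)

        walk(self.expr)
        return frozenset(out)

    def to_string(self) -> str:
        def render(node: GeneExpr, parent_op: Optional[str] = None) -> str:
            if isinstance(node, str):
                return node
            op, children = node
            joined = f" {op} ".join(render(c, op) for c in children)
            if parent_op is not None and parent_op != op:
                return f"({joined})"
            return joined

        return render(self.expr)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


_GENE_TOKEN = re.compile(r"\(|\)|\band\b|\bor\b|[^\s()]+", re.IGNORECASE)


def parse_gene_association(text: str) -> GeneAssociation:
    """Parse a gene rule like ``"gA and (gB or gC)"``.

    ``and`` binds tighter than ``or``; keywords are case-insensitive;
    parentheses group.  Raises :class:`ModelValidationError` on malformed
    input (unbalanced parentheses, dangling operators, empty rule).
    """

    tokens = _GENE_TOKEN.findall(text)
    if not tokens:
        raise ModelValidationError(f"empty gene association: {text!r}")
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GeneExpr:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else ("or", tuple(terms))

    def parse_and() -> GeneExpr:
        factors = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else ("and", tuple(factors))

    def parse_atom() -> GeneExpr:
        tok = peek()
        if tok is None:
            raise ModelValidationError(f"truncated gene association: {text!r}")
        if tok == "(":
            take()
            inner = parse_or()
            if peek() != ")":
                raise ModelValidationError(
                    f"unbalanced parentheses in gene association: {text!r}"
                )
            take()
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ModelValidationError(f"malformed gene association: {text!r}")
        return take()

    expr = parse_or()
    if pos != len(tokens):
        raise ModelValidationError(f"trailing tokens in gene association: {text!r}")
    return GeneAssociation(expr)


def evaluate_gene_association(
    assoc: Union[GeneAssociation, GeneExpr], deleted: Iterable[str]
) -> bool:
    """Evaluate a gene rule with ``deleted`` genes set false, others true."""

    deleted = frozenset(deleted)
    expr = assoc.expr if isinstance(assoc, GeneAssociation) else assoc

    def walk(node: GeneExpr) -> bool:
        if isinstance(node, str):
            if not node:
                raise ModelValidationError("empty locus tag in gene association")
            return node not in deleted
        if not (isinstance(node, tuple) and len(node) == 2):
            raise ModelValidationError(f"malformed gene expression node: {node!r}")
        op, children = node
        if op == "and":
            return all(walk(c) for c in children)
        if op == "or":
            return any(walk(c) for c in children)
        raise ModelValidationError(f"unknown boolean operator: {op!r}")

    return walk(expr)


# ---------------------------------------------------------------------------
# Compounds and reactions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Compound:
    """A metabolite in a specific compartment.

    ``formula`` may be absent or contain the generic groups ``R``/``X``; such
    compounds are auto-excluded from formula/charge balance checks.
    """

    id: str
    name: str = ""
    formula: Optional[str] = None
    charge: Optional[int] = None
    compartment: str = "c"

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"compound {self.id!r}: unknown compartment {self.compartment!r}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.id, self.compartment)


SpeciesKey = tuple[str, str]  # (compound id, compartment)


@dataclass
class Reaction:
    """Signed stoichiometry over compartmentalized species plus flux bounds.

    Negative coefficients denote substrates.  Bounds are in flux units
    (mmol gDW^-1 h^-1 by convention).  ``genes`` is the boolean association
    driving knockouts; ``kind`` is one of :data:`REACTION_KINDS`.
    """

    id: str
    stoichiometry: dict[SpeciesKey, Fraction]
    lower_bound: float
    upper_bound: float
    genes: Optional[GeneAssociation] = None
    subsystem: str = ""
    kind: str = "cytosolic"
    name: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if self.kind not in REACTION_KINDS:
            raise ModelValidationError(
                f"reaction {self.id!r}: unknown kind {self.kind!r}"
            )
        clean = {}
        for key, coef in self.stoichiometry.items():
            frac = Fraction(coef)
            if frac == 0:
                raise ModelValidationError(
                    f"reaction {self.id!r}: zero coefficient for {key}"
                )
            clean[key] = frac
        self.stoichiometry = clean
        if self.kind == "exchange" and len(self.stoichiometry) != 1:
            raise ModelValidationError(
                f"exchange reaction {self.id!r} must touch exactly one compound"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def species(self) -> frozenset[SpeciesKey]:
        return frozenset(self.stoichiometry)

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            genes=self.genes,
            subsystem=self.subsystem,
            kind=self.kind,
            name=self.name,
        )


def infer_kind(stoich: Mapping[SpeciesKey, Fraction], biomass: bool = False) -> str:
    """Classify a reaction from the compartments of its participants."""

    if biomass:
        return "biomass"
    if len(stoich) == 1:
        return "exchange"
    comps = {comp for (_, comp) in stoich}
    if comps == {"e"}:
        return "extracellular"
    if len(comps) > 1:
        return "transmembrane"
    return "cytosolic"


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


@dataclass
class Model:
    """A stoichiometric network: compound catalog, reaction catalog, biomass.

    ``default_bound`` is the magnitude applied where bounds are unstated:
    reversible reactions get (-default, +default), irreversible (0, +default).
    """

    name: str = "model"
    compounds: dict[SpeciesKey, Compound] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    biomass_id: Optional[str] = None
    default_bound: float = 1000.0

    # -- construction -------------------------------------------------------

    def add_compound(self, compound: Compound) -> None:
        if compound.key in self.compounds:
            raise ModelValidationError(f"duplicate compound {compound.key}")
        self.compounds[compound.key] = compound

    def add_reaction(self, reaction: Reaction) -> None:
        if reaction.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {reaction.id!r}")
        for key in reaction.stoichiometry:
            if key not in self.compounds:
                raise ModelValidationError(
                    f"reaction {reaction.id!r} references unknown compound {key}"
                )
        self.reactions[reaction.id] = reaction

    def validate(self) -> None:
        """Check model-level invariants; raise on the first violation."""

        if self.biomass_id is not None and self.biomass_id not in self.reactions:
            raise ModelValidationError(
                f"biomass reaction {self.biomass_id!r} not in catalog"
            )
        for rxn in self.reactions.values():
            for key in rxn.stoichiometry:
                if key not in self.compounds:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references unknown compound {key}"
                    )

    def copy(self) -> "Model":
        out = Model(
            name=self.name,
            biomass_id=self.biomass_id,
            default_bound=self.default_bound,
        )
        out.compounds = dict(self.compounds)
        out.reactions = {rid: rxn.copy() for rid, rxn in self.reactions.items()}
        return out

    # -- queries ------------------------------------------------------------

    def reaction_ids(self) -> list[str]:
        return sorted(self.reactions)

    def species_keys(self) -> list[SpeciesKey]:
        return sorted(self.compounds)

    def exchange_ids(self) -> list[str]:
        return sorted(r.id for r in self.reactions.values() if r.kind == "exchange")

    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            if rxn.genes is not None:
                out |= rxn.genes.genes()
        return frozenset(out)

    def category_counts(self) -> dict[str, int]:
        counts = {k: 0 for k in REACTION_KINDS}
        for rxn in self.reactions.values():
            counts[rxn.kind] += 1
        return {k: v for k, v in counts.items() if v}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Model):
            return NotImplemented
        return (
            self.name == other.name
            and self.biomass_id == other.biomass_id
            and self.default_bound == other.default_bound
            and self.compounds == other.compounds
            and {r.id: _reaction_state(r) for r in self.reactions.values()}
            == {r.id: _reaction_state(r) for r in other.reactions.values()}
        )


def _reaction_state(r: Reaction) -> tuple:
    return (
        tuple(sorted(r.stoichiometry.items())),
        r.lower_bound,
        r.upper_bound,
        r.genes,
        r.subsystem,
        r.kind,
    )


# ---------------------------------------------------------------------------
# Medium
# ---------------------------------------------------------------------------


@dataclass
class MediumSpec:
    """Exchange-reaction bounds representing a growth medium.

    Sign convention: a negative lower bound on an exchange reaction permits
    uptake of that compound; upper bound caps secretion.  Exchange reactions
    not listed keep their catalog bounds (the reader defaults unlisted
    exchanges to secretion-only).
    """

    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ModelValidationError(
                    f"medium entry {rid!r}: lower bound {lo} exceeds upper {hi}"
                )

    def apply(self, model: Model) -> Model:
        """Return a copy of ``model`` with the medium bounds installed."""

        out = model.copy()
        for rid, (lo, hi) in self.bounds.items():
            if rid not in out.reactions:
                raise ModelValidationError(f"medium references unknown exchange {rid!r}")
            rxn = out.reactions[rid]
            rxn.lower_bound = float(lo)
            rxn.upper_bound = float(hi)
        return out


# ---------------------------------------------------------------------------
# Strain designs
# ---------------------------------------------------------------------------

DIRECTION_MODES = ("reversible", "forward_only", "reverse_only", "blocked")


@dataclass
class StrainDesign:
    """A set of genetic edits: deletions, knock-ins, directionality overrides.

    ``direction_overrides`` maps reaction id to one of
    ``reversible | forward_only | reverse_only | blocked``; ``reversible``
    restores the catalog default bounds of the base model.
    """

    deleted_genes: frozenset[str] = frozenset()
    deleted_reactions: frozenset[str] = frozenset()
    insertions: Sequence[Reaction] = ()
    new_compounds: Sequence[Compound] = ()
    direction_overrides: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.deleted_genes = frozenset(self.deleted_genes)
        self.deleted_reactions = frozenset(self.deleted_reactions)
        seen = set()
        for rxn in self.insertions:
            if rxn.id in seen:
                raise ModelValidationError(f"duplicate insertion id {rxn.id!r}")
            seen.add(rxn.id)
        for rid, mode in self.direction_overrides.items():
            if mode not in DIRECTION_MODES:
                raise ModelValidationError(
                    f"unknown direction override {mode!r} for {rid!r}"
                )

    def merged(self, other: "StrainDesign") -> "StrainDesign":
        """Combine two designs (other's overrides win on conflict)."""

        ids = {r.id for r in self.insertions}
        extra = [r for r in other.insertions if r.id not in ids]
        keys = {c.key for c in self.new_compounds}
        extra_cpds = [c for c in other.new_compounds if c.key not in keys]
        return StrainDesign(
            deleted_genes=self.deleted_genes | other.deleted_genes,
            deleted_reactions=self.deleted_reactions | other.deleted_reactions,
            insertions=tuple(self.insertions) + tuple(extra),
            new_compounds=tuple(self.new_compounds) + tuple(extra_cpds),
            direction_overrides={**self.direction_overrides, **other.direction_overrides},
        )


def apply_design(base: Model, design: StrainDesign) -> Model:
    """Apply a strain design to a model, returning an edited copy.

    Order of operations: gene deletions zero the bounds of reactions whose
    association evaluates false; explicitly deleted reactions are zeroed;
    insertions (plus any new compounds they need) are appended; direction
    overrides are applied last, with ``reversible`` restoring the base-model
    catalog bounds.
    """

    for gene in design.deleted_genes:
        if gene not in base.genes():
            raise ModelValidationError(f"unknown gene {gene!r} in design")
    model = base.copy()

    if design.deleted_genes:
        for rxn in model.reactions.values():
            if rxn.genes is not None and not rxn.genes.evaluate(design.deleted_genes):
                rxn.lower_bound = 0.0
                rxn.upper_bound = 0.0

    for rid in design.deleted_reactions:
        if rid not in model.reactions:
            raise ModelValidationError(f"unknown reaction {rid!r} in design")
        model.reactions[rid].lower_bound = 0.0
        model.reactions[rid].upper_bound = 0.0

    for cpd in design.new_compounds:
        if cpd.key not in model.compounds:
            model.add_compound(cpd)
    for rxn in design.insertions:
        if rxn.id in model.reactions:
            raise ModelValidationError(f"insertion duplicates reaction id {rxn.id!r}")
        model.add_reaction(rxn.copy())

    inserted = {r.id for r in design.insertions}
    for rid, mode in design.direction_overrides.items():
        if rid not in model.reactions:
            raise ModelValidationError(f"direction override on unknown reaction {rid!r}")
        rxn = model.reactions[rid]
        if mode == "forward_only":
            rxn.lower_bound = max(0.0, rxn.lower_bound)
        elif mode == "reverse_only":
            rxn.upper_bound = min(0.0, rxn.upper_bound)
        elif mode == "blocked":
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
        elif mode == "reversible":
            # Restore the catalog default bounds for a reversible reaction,
            # undoing any prior directional clamp.
            rxn.lower_bound = -model.default_bound
            rxn.upper_bound = model.default_bound
    return model


# ---------------------------------------------------------------------------
# Stoichiometric matrix
# ---------------------------------------------------------------------------


def stoichiometric_matrix(
    model: Model, reactions: Optional[Sequence[str]] = None
) -> tuple[sp.csr_matrix, list[SpeciesKey], list[str]]:
    """Build the sparse stoichiometric matrix S.

    Rows are compartmentalized compounds, columns reactions, both in
    deterministic lexicographic order (unless an explicit reaction order is
    given).  Entry (i, j) is the signed coefficient of species i in reaction
    j, as a float.
    """

    species = model.species_keys()
    rxn_ids = list(reactions) if reactions is not None else model.reaction_ids()
    row_index = {key: i for i, key in enumerate(species)}
    rows, cols, vals = [], [], []
    for j, rid in enumerate(rxn_ids):
        for key, coef in model.reactions[rid].stoichiometry.items():
            rows.append(row_index[key])
            cols.append(j)
            vals.append(float(coef))
    mat = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(species), len(rxn_ids))
    )
    return mat, species, rxn_ids
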