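"""Readers and writers for the model formats.

Two on-disk representations are supported:

* a YAML dialect (central document with ``compounds`` / ``reactions`` /
  ``limits`` / ``medium`` includes, following the conventions of
  PSAMM-style model repositories), and
* flat TSV sheets (one reaction sheet, one compound sheet) matching a
  one-step export of the published supplementary workbook.

Reaction equations use the grammar::

    term (+ term)* ARROW term (+ term)*
    term  = [(coef)] compoundId[compartment]
    ARROW = "=>" (irreversible) | "<=>" (reversible)

with an omitted coefficient meaning 1.  ``cpd[c]`` is the canonical
compartment notation; the ``cpd_c`` suffix form is accepted on read.
Round-tripping a model through write/read is the identity, including exact
rational coefficients.
"""

from __future__ import annotations

import re
from fractions import Fraction
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .model import (
    COMPARTMENTS,
    Compound,
    MediumSpec,
    Model,
    ModelValidationError,
    Reaction,
    infer_kind,
    parse_gene_association,
)

__all__ = [
    "EquationParseError",
    "parse_equation",
    "format_equation",
    "read_yaml_model",
    "write_yaml_model",
    "read_table_model",
    "read_medium",
]


class EquationParseError(ValueError):
    """Raised when a reaction equation string is outside the grammar."""


_TERM = re.compile(
    r"^(?:\((?P<coef>\d+(?:/\d+)?(?:\.\d+)?)\)\s*)?"
    r"(?P<cpd>[A-Za-z0-9][A-Za-z0-9_\-]*?)"
    r"(?:\[(?P<comp>[a-z])\]|_(?P<comp2>[ce]))$"
)


def _parse_term(term: str, context: str) -> tuple[Fraction, tuple[str, str]]:
    m = _TERM.match(term.strip())
    if m is None:
        raise EquationParseError(f"bad term {term!r} in equation {context!r}")
    raw = m.group("coef")
    if raw is None:
        coef = Fraction(1)
    elif "." in raw:
        coef = Fraction(raw).limit_denominator(10**9)
    else:
        coef = Fraction(raw)
    if coef <= 0:
        raise EquationParseError(f"non-positive coefficient in {context!r}")
    comp = m.group("comp") or m.group("comp2")
    if comp not in COMPARTMENTS:
        raise EquationParseError(
            f"unknown compartment {comp!r} in equation {context!r}"
        )
    return coef, (m.group("cpd"), comp)


def parse_equation(text: str) -> tuple[dict, bool]:
    """Parse an equation string into (stoichiometry, reversible).

    Substrates get negative coefficients.  A species appearing on both sides
    is net-summed; a zero net coefficient is rejected (the grammar forbids
    vacuous terms).
    """

    if "<=>" in text:
        arrow, reversible = "<=>", True
    elif "=>" in text:
        arrow, reversible = "=>", False
    else:
        raise EquationParseError(f"no arrow ('=>' or '<=>') in equation {text!r}")
    left_s, right_s = text.split(arrow, 1)
    if arrow == "=>" and left_s.endswith("<"):
        raise EquationParseError(f"malformed arrow in equation {text!r}")

    stoich: dict = {}

    def add_side(side: str, sign: int) -> None:
        side = side.strip()
        if not side:
            return  # empty side: boundary reaction (exchange/sink)
        for term in side.split(" + "):
            coef, key = _parse_term(term, text)
            stoich[key] = stoich.get(key, Fraction(0)) + sign * coef

    add_side(left_s, -1)
    add_side(right_s, +1)
    stoich = {k: v for k, v in stoich.items() if v != 0}
    if not stoich:
        raise EquationParseError(f"equation {text!r} has empty net stoichiometry")
    return stoich, reversible


def _format_coef(coef: Fraction) -> str:
    if coef == 1:
        return ""
    if coef.denominator == 1:
        return f"({coef.numerator}) "
    return f"({coef.numerator}/{coef.denominator}) "


def format_equation(stoich: dict, reversible: bool) -> str:
    """Render stoichiometry back to the canonical equation string."""

    subs = sorted((k, -v) for k, v in stoich.items() if v < 0)
    prods = sorted((k, v) for k, v in stoich.items() if v > 0)
    render = lambda items: " + ".join(
        f"{_format_coef(c)}{cid}[{comp}]" for (cid, comp), c in items
    )
    arrow = "<=>" if reversible else "=>"
    return f"{render(subs)} {arrow} {render(prods)}".strip()


# ---------------------------------------------------------------------------
# YAML dialect
# ---------------------------------------------------------------------------


def _resolve_includes(entry, base: Path) -> list:
    """A section is either an inline list or a list of {include: path}."""

    out = []
    for item in entry or []:
        if isinstance(item, dict) and "include" in item:
            path = base / item["include"]
            if not path.exists():
                raise FileNotFoundError(f"included file not found: {path}")
            with open(path) as fh:
                sub = yaml.safe_load(fh) or []
            out.extend(sub)
        else:
            out.append(item)
    return out


def read_yaml_model(path: Union[str, Path]) -> Model:
    """Read the central YAML model document and its includes.

    Keys: ``name``, ``biomass``, ``default_flux_limit``, ``compounds``,
    ``reactions``, ``limits``, ``medium``.  Limits entries override the
    default bounds implied by equation reversibility; medium entries set
    exchange bounds.
    """

    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    base = path.parent
    model = Model(
        name=doc.get("name", path.stem),
        biomass_id=doc.get("biomass"),
        default_bound=float(doc.get("default_flux_limit", 1000.0)),
    )

    dup: list[str] = []
    for entry in _resolve_includes(doc.get("compounds"), base):
        cpd = Compound(
            id=entry["id"],
            name=entry.get("name", ""),
            formula=entry.get("formula"),
            charge=entry.get("charge"),
            compartment=entry.get("compartment", "c"),
        )
        if cpd.key in model.compounds:
            dup.append(f"{cpd.id}[{cpd.compartment}]")
        else:
            model.add_compound(cpd)
    if dup:
        raise ModelValidationError(f"duplicate compound ids: {', '.join(sorted(dup))}")

    dup = []
    for entry in _resolve_includes(doc.get("reactions"), base):
        rid = entry["id"]
        if rid in model.reactions:
            dup.append(rid)
            continue
        try:
            stoich, reversible = parse_equation(entry["equation"])
        except EquationParseError as exc:
            raise EquationParseError(f"reaction {rid!r}: {exc}") from exc
        lb = -model.default_bound if reversible else 0.0
        ub = model.default_bound
        genes_s = entry.get("genes")
        genes = parse_gene_association(genes_s) if genes_s else None
        kind = entry.get("kind") or infer_kind(stoich, biomass=(rid == model.biomass_id))
        model.add_reaction(
            Reaction(
                id=rid,
                name=entry.get("name", ""),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                genes=genes,
                subsystem=entry.get("subsystem", ""),
                kind=kind,
            )
        )
    if dup:
        raise ModelValidationError(f"duplicate reaction ids: {', '.join(sorted(dup))}")

    for entry in _resolve_includes(doc.get("limits"), base):
        rid = entry["reaction"]
        if rid not in model.reactions:
            raise ModelValidationError(f"limits entry for unknown reaction {rid!r}")
        rxn = model.reactions[rid]
        lo = entry.get("lower", rxn.lower_bound)
        hi = entry.get("upper", rxn.upper_bound)
        if lo > hi:
            raise ModelValidationError(f"limits entry {rid!r}: lower > upper")
        rxn.lower_bound = float(lo)
        rxn.upper_bound = float(hi)

    for entry in _resolve_includes(doc.get("medium"), base):
        rid = entry["reaction"]
        if rid not in model.reactions:
            raise ModelValidationError(f"medium entry for unknown exchange {rid!r}")
        rxn = model.reactions[rid]
        rxn.lower_bound = float(entry.get("lower", 0.0))
        rxn.upper_bound = float(entry.get("upper", model.default_bound))

    model.validate()
    return model


def write_yaml_model(model: Model, path: Union[str, Path]) -> None:
    """Write a model as a single self-contained YAML document.

    Ordering is deterministic (lexicographic ids) so identical models yield
    byte-identical files.  Bounds that differ from the reversibility defaults
    are emitted as ``limits`` entries, preserving full round-trip fidelity.
    """

    path = Path(path)
    compounds = []
    for key in model.species_keys():
        cpd = model.compounds[key]
        entry: dict = {"id": cpd.id, "compartment": cpd.compartment}
        if cpd.name:
            entry["name"] = cpd.name
        if cpd.formula is not None:
            entry["formula"] = cpd.formula
        if cpd.charge is not None:
            entry["charge"] = cpd.charge
        compounds.append(entry)

    reactions, limits = [], []
    for rid in model.reaction_ids():
        rxn = model.reactions[rid]
        reversible = rxn.lower_bound < 0  # serialization arrow choice
        entry = {"id": rid, "equation": format_equation(rxn.stoichiometry, reversible)}
        if rxn.name:
            entry["name"] = rxn.name
        if rxn.genes is not None:
            entry["genes"] = rxn.genes.to_string()
        if rxn.subsystem:
            entry["subsystem"] = rxn.subsystem
        entry["kind"] = rxn.kind
        reactions.append(entry)
        default_lb = -model.default_bound if reversible else 0.0
        if rxn.lower_bound != default_lb or rxn.upper_bound != model.default_bound:
            limits.append(
                {"reaction": rid, "lower": rxn.lower_bound, "upper": rxn.upper_bound}
            )

    doc = {
        "name": model.name,
        "default_flux_limit": model.default_bound,
        "compounds": compounds,
        "reactions": reactions,
    }
    if model.biomass_id is not None:
        doc["biomass"] = model.biomass_id
    if limits:
        doc["limits"] = limits
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, default_flow_style=False)


# ---------------------------------------------------------------------------
# Tabular sheets
# ---------------------------------------------------------------------------

_REACTION_COLUMNS = ("id", "equation")
_COMPOUND_COLUMNS = ("id", "compartment")


def read_table_model(
    reaction_sheet: Union[str, Path],
    compound_sheet: Union[str, Path],
    biomass_id: Optional[str] = None,
    default_bound: float = 1000.0,
) -> Model:
    """Read a model from tab-delimited reaction and compound sheets.

    The reaction sheet requires columns ``id`` and ``equation`` and honors
    optional ``genes``, ``subsystem``, ``lower``, ``upper``.  The compound
    sheet requires ``id`` and ``compartment`` and honors ``name``,
    ``formula``, ``charge``.  This matches a plain export of the
    supplementary workbook sheets to TSV.
    """

    rxn_df = pd.read_csv(reaction_sheet, sep="\t", dtype=str)
    cpd_df = pd.read_csv(compound_sheet, sep="\t", dtype=str)
    for col in _REACTION_COLUMNS:
        if col not in rxn_df.columns:
            raise ModelValidationError(f"reaction sheet missing column {col!r}")
    for col in _COMPOUND_COLUMNS:
        if col not in cpd_df.columns:
            raise ModelValidationError(f"compound sheet missing column {col!r}")

    model = Model(name="table-model", biomass_id=biomass_id, default_bound=default_bound)
    for row in cpd_df.itertuples(index=False):
        charge = getattr(row, "charge", None)
        if isinstance(charge, str) and charge.strip():
            charge = int(float(charge))
        elif charge is None or (isinstance(charge, float) and pd.isna(charge)) or charge == "":
            charge = None
        formula = getattr(row, "formula", None)
        if isinstance(formula, float) and pd.isna(formula):
            formula = None
        name = getattr(row, "name", "")
        model.add_compound(
            Compound(
                id=row.id,
                name="" if pd.isna(name) else str(name),
                formula=formula,
                charge=charge,
                compartment=row.compartment,
            )
        )

    for row in rxn_df.itertuples(index=False):
        stoich, reversible = parse_equation(row.equation)
        lb = getattr(row, "lower", None)
        ub = getattr(row, "upper", None)
        lower = float(lb) if isinstance(lb, str) and lb.strip() else (
            -default_bound if reversible else 0.0
        )
        upper = float(ub) if isinstance(ub, str) and ub.strip() else default_bound
        genes_s = getattr(row, "genes", None)
        genes = (
            parse_gene_association(genes_s)
            if isinstance(genes_s, str) and genes_s.strip()
            else None
        )
        subsystem = getattr(row, "subsystem", "")
        model.add_reaction(
            Reaction(
                id=row.id,
                stoichiometry=stoich,
                lower_bound=lower,
                upper_bound=upper,
                genes=genes,
                subsystem="" if pd.isna(subsystem) else str(subsystem),
                kind=infer_kind(stoich, biomass=(row.id == biomass_id)),
            )
        )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Medium files
# ---------------------------------------------------------------------------


def read_medium(path: Union[str, Path]) -> MediumSpec:
    """Read a medium from TSV (reaction, lower, upper) or YAML.

    A TSV row like ``EX_glc\t-25\t1000`` allows uptake of up to 25 flux
    units of glucose.  Exchanges not listed are left to the reader's
    secretion-only default of (0, default_bound) when the medium is applied
    through :meth:`MediumSpec.apply` on a model whose catalog defaults say so.
    """

    path = Path(path)
    bounds: dict[str, tuple[float, float]] = {}
    if path.suffix in (".yaml", ".yml"):
        with open(path) as fh:
            doc = yaml.safe_load(fh) or []
        for entry in doc:
            bounds[entry["reaction"]] = (
                float(entry.get("lower", 0.0)),
                float(entry.get("upper", 1000.0)),
            )
    else:
        try:
            df = pd.read_csv(
                path, sep="\t", header=None, names=["reaction", "lower", "upper"],
                comment="#",
            )
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=["reaction", "lower", "upper"])
        for row in df.itertuples(index=False):
            bounds[str(row.reaction)] = (float(row.lower), float(row.upper))
    return MediumSpec(bounds=bounds)
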