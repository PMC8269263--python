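"""Model quality checks: stoichiometric consistency, formula balance,
charge balance, and metabolite connectivity.

These are re-implementations of the four standard curation checks run on
genome-scale reconstructions.  Boundary pseudo-reactions (exchanges, sinks,
biomass) are excluded throughout, as are reactions touching compounds whose
formula contains a generic ``R``/``X`` group or is missing — such exclusions
are reported, never silently dropped.

Stoichiometric consistency follows the mass-assignment formulation: a set of
internal reactions is consistent iff every compound can be assigned a
strictly positive molecular mass m with S^T m = 0.  The reported percentage
is the maximal fraction of compounds that admit such a mass, found with a
single LP (maximize the number of compounds whose relaxed indicator reaches
1, with z <= m and z <= 1).

Formula and charge balance are computed in exact rational arithmetic from
the parsed chemical formulas, so a reaction is flagged iff it is truly
imbalanced, with the offending element and delta recorded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import numpy as np
from scipy import optimize, sparse as sp

from .model import Model, Reaction, stoichiometric_matrix

__all__ = [
    "FormulaError",
    "parse_formula",
    "formula_is_generic",
    "check_stoichiometric_consistency",
    "check_formula_balance",
    "check_charge_balance",
    "check_connectivity",
    "ConsistencyReport",
    "consistency_report",
]

BOUNDARY_KINDS = ("exchange", "biomass", "sink")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\()|(\))(\d*)")


class FormulaError(ValueError):
    """Raised for a chemical formula string that cannot be parsed."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse ``C10H12N5O13P3`` (or with parenthesized groups) to counts."""

    if not formula or not formula.strip():
        raise FormulaError("empty formula")
    pos = 0
    stack: list[dict[str, int]] = [{}]
    while pos < len(formula):
        ch = formula[pos]
        if ch == "(":
            stack.append({})
            pos += 1
        elif ch == ")":
            pos += 1
            m = re.match(r"\d+", formula[pos:])
            mult = int(m.group()) if m else 1
            pos += m.end() if m else 0
            group = stack.pop()
            if not stack:
                raise FormulaError(f"unbalanced parentheses in {formula!r}")
            for el, cnt in group.items():
                stack[-1][el] = stack[-1].get(el, 0) + cnt * mult
        else:
            m = re.match(r"([A-Z][a-z]?)(\d*)", formula[pos:])
            if m is None or m.start() != 0 or not m.group(1):
                raise FormulaError(f"cannot parse formula {formula!r} at {pos}")
            el = m.group(1)
            cnt = int(m.group(2)) if m.group(2) else 1
            stack[-1][el] = stack[-1].get(el, 0) + cnt
            pos += m.end()
    if len(stack) != 1:
        raise FormulaError(f"unbalanced parentheses in {formula!r}")
    return stack[0]


def formula_is_generic(formula: Optional[str]) -> bool:
    """True if the formula is absent or contains a generic R/X group."""

    if formula is None:
        return True
    try:
        counts = parse_formula(formula)
    except FormulaError:
        return True
    return "R" in counts or "X" in counts


def _internal_reactions(model: Model) -> list[Reaction]:
    return [r for r in model.reactions.values() if r.kind not in BOUNDARY_KINDS]


# ---------------------------------------------------------------------------
# Stoichiometric consistency
# ---------------------------------------------------------------------------


def check_stoichiometric_consistency(
    model: Model, mass_floor: float = 1e-6
) -> tuple[float, list[str]]:
    """Percent of compounds assignable a strictly positive consistent mass.

    Returns ``(percent, inconsistent_species)`` where species are rendered
    as ``id[compartment]``.  Exchange, biomass, and sink reactions do not
    constrain the mass assignment.
    """

    internal = sorted(r.id for r in _internal_reactions(model))
    species = model.species_keys()
    if not species:
        return 100.0, []
    if not internal:
        return 100.0, []
    S, species, _ = stoichiometric_matrix(model, reactions=internal)
    m_count = len(species)
    # Variables: [m (masses), z (relaxed indicators)]; maximize sum z
    # s.t. S^T m = 0, z <= m, mass_floor <= m, 0 <= z <= 1.
    c = np.concatenate([np.zeros(m_count), -np.ones(m_count)])
    A_eq = sp.hstack([S.T, sp.csr_matrix((S.shape[1], m_count))], format="csr")
    I = sp.identity(m_count, format="csr")
    A_ub = sp.hstack([-I, I], format="csr")  # z - m <= 0
    bounds = [(mass_floor, None)] * m_count + [(0.0, 1.0)] * m_count
    res = optimize.linprog(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(S.shape[1]),
        A_ub=A_ub,
        b_ub=np.zeros(m_count),
        bounds=bounds,
        method="highs",
    )
    if not res.success:
        # No strictly positive assignment at all => relax the floor to zero
        # and count compounds that still reach a positive mass.
        bounds = [(0.0, None)] * m_count + [(0.0, 1.0)] * m_count
        res = optimize.linprog(
            c,
            A_eq=A_eq,
            b_eq=np.zeros(S.shape[1]),
            A_ub=A_ub,
            b_ub=np.zeros(m_count),
            bounds=bounds,
            method="highs",
        )
        if not res.success:  # pragma: no cover - degenerate model
            return 0.0, [f"{cid}[{comp}]" for cid, comp in species]
    z = res.x[m_count:]
    consistent = z > 0.5
    bad = [
        f"{cid}[{comp}]"
        for (cid, comp), ok in zip(species, consistent)
        if not ok
    ]
    percent = 100.0 * float(np.count_nonzero(consistent)) / m_count
    return percent, bad


# ---------------------------------------------------------------------------
# Formula / charge balance
# ---------------------------------------------------------------------------


@dataclass
class BalanceResult:
    imbalanced: dict[str, dict] = field(default_factory=dict)
    excluded: dict[str, str] = field(default_factory=dict)


def check_formula_balance(model: Model) -> BalanceResult:
    """Compare element totals of substrates and products, reaction by reaction.

    Exact rational arithmetic; reactions touching compounds with generic or
    missing formulas are excluded and listed with the reason.
    """

    result = BalanceResult()
    for rxn in sorted(_internal_reactions(model), key=lambda r: r.id):
        skip_reason = None
        totals: dict[str, Fraction] = {}
        for key, coef in rxn.stoichiometry.items():
            cpd = model.compounds[key]
            if formula_is_generic(cpd.formula):
                reason = (
                    "missing formula"
                    if cpd.formula is None
                    else f"generic/unparsable formula {cpd.formula!r}"
                )
                skip_reason = f"{cpd.id}[{cpd.compartment}]: {reason}"
                break
            for el, cnt in parse_formula(cpd.formula).items():
                totals[el] = totals.get(el, Fraction(0)) + coef * cnt
        if skip_reason is not None:
            result.excluded[rxn.id] = skip_reason
            continue
        deltas = {el: v for el, v in totals.items() if v != 0}
        if deltas:
            result.imbalanced[rxn.id] = {
                el: float(v) for el, v in sorted(deltas.items())
            }
    return result


def check_charge_balance(model: Model) -> BalanceResult:
    """Compare substrate and product charge totals per reaction.

    Reactions touching R/X-group compounds are excluded here too, matching
    the curation convention that such reactions are inspected manually rather
    than flagged.
    """

    result = BalanceResult()
    for rxn in sorted(_internal_reactions(model), key=lambda r: r.id):
        total = Fraction(0)
        skip_reason = None
        for key, coef in rxn.stoichiometry.items():
            cpd = model.compounds[key]
            if cpd.charge is None:
                skip_reason = f"{cpd.id}[{cpd.compartment}]: missing charge"
                break
            if formula_is_generic(cpd.formula):
                skip_reason = (
                    f"{cpd.id}[{cpd.compartment}]: generic or missing formula"
                )
                break
            total += coef * cpd.charge
        if skip_reason is not None:
            result.excluded[rxn.id] = skip_reason
            continue
        if total != 0:
            result.imbalanced[rxn.id] = {"charge": float(total)}
    return result


def check_connectivity(model: Model) -> list[str]:
    """Species that participate in no reaction (orphan metabolites)."""

    used = set()
    for rxn in model.reactions.values():
        used |= set(rxn.stoichiometry)
    return sorted(
        f"{cid}[{comp}]" for (cid, comp) in model.compounds if (cid, comp) not in used
    )


# ---------------------------------------------------------------------------
# Combined report
# ---------------------------------------------------------------------------


@dataclass
class ConsistencyReport:
    """The four curation-check outcomes for one model."""

    percent_stoichiometrically_consistent: float
    inconsistent_species: list[str]
    imbalanced_formula_reactions: list[str]
    imbalanced_charge_reactions: list[str]
    unconnected_compounds: list[str]
    excluded_reactions: dict[str, str]
    percent_connected: float

    def summary(self) -> dict:
        return {
            "stoichiometric_consistency_pct": self.percent_stoichiometrically_consistent,
            "formula_imbalances": len(self.imbalanced_formula_reactions),
            "charge_imbalances": len(self.imbalanced_charge_reactions),
            "unconnected_compounds": len(self.unconnected_compounds),
            "excluded_reactions": len(self.excluded_reactions),
            "connectivity_pct": self.percent_connected,
        }


def consistency_report(model: Model) -> ConsistencyReport:
    percent, bad_species = check_stoichiometric_consistency(model)
    formulas = check_formula_balance(model)
    charges = check_charge_balance(model)
    orphans = check_connectivity(model)
    excluded = dict(formulas.excluded)
    for rid, why in charges.excluded.items():
        excluded.setdefault(rid, why)
    n_species = max(len(model.compounds), 1)
    report = ConsistencyReport(
        percent_stoichiometrically_consistent=percent,
        inconsistent_species=bad_species,
        imbalanced_formula_reactions=sorted(formulas.imbalanced),
        imbalanced_charge_reactions=sorted(charges.imbalanced),
        unconnected_compounds=orphans,
        excluded_reactions=excluded,
        percent_connected=100.0 * (n_species - len(orphans)) / n_species,
    )
    overlap = set(report.excluded_reactions) & (
        set(report.imbalanced_formula_reactions)
        | set(report.imbalanced_charge_reactions)
    )
    assert not overlap, f"excluded reactions also reported imbalanced: {overlap}"
    return report
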