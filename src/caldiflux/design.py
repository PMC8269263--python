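"""In-silico strain design: knock-in catalog, design-matrix evaluation,
and production envelopes.

The knock-in catalog carries the engineering candidates considered for
*C. bescii* ethanol strains, each with explicit element- and charge-balanced
stoichiometry (ferredoxin is a two-electron couple):

* **AdhE** — bifunctional acetaldehyde/alcohol dehydrogenase, the ethanol
  route from acetyl-CoA (2 NADH per ethanol);
* **Rnf_Na** — sodium-pumping ferredoxin:NAD+ oxidoreductase; without a
  sodium return path it cannot carry steady-state flux;
* **Mrp** — Na+/H+ antiporter providing that return path (and converting the
  sodium gradient into proton-motive force);
* **Rnf_H** — the proton-translocating Rnf variant;
* **SH1 / SH2** — soluble hydrogenases re-assimilating H2 into NADPH or
  NADH, respectively.

Design evaluation asks one question per row: the maximum product (ethanol)
flux under a biomass floor, for a given combination of deletions/insertions
and BF-H2ase directionality.  Carbon and degree-of-reduction balance audits
are provided for every optimal solution.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .analysis import FluxProblem, FluxRange, FluxSolution, fba
from .checks import parse_formula
from .model import (
    Compound,
    MediumSpec,
    Model,
    Reaction,
    StrainDesign,
    apply_design,
    infer_kind,
)
from .io import parse_equation

__all__ = [
    "KnockinDef",
    "knockin_catalog",
    "ProductionResult",
    "max_product",
    "DesignMatrixResult",
    "evaluate_designs",
    "production_envelope",
    "carbon_balance",
    "electron_balance",
]


@dataclass(frozen=True)
class KnockinDef:
    """One knock-in: reactions, any new species, and its provenance note."""

    name: str
    reactions: tuple[Reaction, ...]
    compounds: tuple[Compound, ...]
    provenance: str

    def as_design(self) -> StrainDesign:
        return StrainDesign(insertions=self.reactions, new_compounds=self.compounds)


_NA_C = Compound(id="na", name="sodium ion", formula="Na", charge=1, compartment="c")
_NA_E = Compound(id="na", name="sodium ion", formula="Na", charge=1, compartment="e")


def _reaction(rid: str, equation: str, default_bound: float = 1000.0) -> Reaction:
    stoich, reversible = parse_equation(equation)
    return Reaction(
        id=rid,
        stoichiometry=stoich,
        lower_bound=-default_bound if reversible else 0.0,
        upper_bound=default_bound,
        kind=infer_kind(stoich),
        subsystem="Knock-in",
    )


def knockin_catalog(
    rnf_ions: int = 1, default_bound: float = 1000.0
) -> dict[str, KnockinDef]:
    """The engineering knock-in catalog, keyed by canonical name.

    ``rnf_ions`` sets the ions translocated per oxidized ferredoxin by the
    Rnf variants (the published reconstruction does not state this; small
    integers keep the balances hand-checkable and the qualitative behavior
    is insensitive to the value).
    """

    k = rnf_ions
    na_c = f"({k}) na[c]" if k != 1 else "na[c]"
    na_e = f"({k}) na[e]" if k != 1 else "na[e]"
    h_in = f"({1 + k}) h[c]" if k != 1 else "(2) h[c]"
    h_out = f"({k}) h[e]" if k != 1 else "h[e]"
    catalog = {
        "AdhE": KnockinDef(
            name="AdhE",
            reactions=(
                _reaction(
                    "ADHE",
                    "accoa[c] + (2) nadh[c] + (2) h[c] => etoh[c] + coa[c] + (2) nad[c]",
                    default_bound,
                ),
            ),
            compounds=(),
            provenance="bifunctional acetaldehyde/alcohol dehydrogenase "
            "(Clostridium thermocellum)",
        ),
        "Rnf_Na": KnockinDef(
            name="Rnf_Na",
            reactions=(
                _reaction(
                    "RNF_NA",
                    f"fdred[c] + nad[c] + h[c] + {na_c} => fdox[c] + nadh[c] + {na_e}",
                    default_bound,
                ),
            ),
            compounds=(_NA_C, _NA_E),
            provenance="sodium-pumping reduced ferredoxin:NAD+ oxidoreductase "
            "(Thermoanaerobacter sp. X514)",
        ),
        "Rnf_H": KnockinDef(
            name="Rnf_H",
            reactions=(
                _reaction(
                    "RNF_H",
                    f"fdred[c] + nad[c] + {h_in} => fdox[c] + nadh[c] + {h_out}",
                    default_bound,
                ),
            ),
            compounds=(),
            provenance="proton-pumping reduced ferredoxin:NAD+ oxidoreductase",
        ),
        "Mrp": KnockinDef(
            name="Mrp",
            reactions=(_reaction("MRP", "na[e] + h[c] => na[c] + h[e]", default_bound),),
            compounds=(_NA_C, _NA_E),
            provenance="multi-subunit Na+/H+ antiporter (Pyrococcus furiosus)",
        ),
        "SH1": KnockinDef(
            name="SH1",
            reactions=(
                _reaction("SH1", "h2[c] + nadp[c] => nadph[c] + h[c]", default_bound),
            ),
            compounds=(),
            provenance="NADPH-producing soluble hydrogenase (Thermococcales)",
        ),
        "SH2": KnockinDef(
            name="SH2",
            reactions=(
                _reaction("SH2", "h2[c] + nad[c] => nadh[c] + h[c]", default_bound),
            ),
            compounds=(),
            provenance="NADH-producing soluble hydrogenase (Thermococcales)",
        ),
    }
    return catalog


# ---------------------------------------------------------------------------
# Product maximization
# ---------------------------------------------------------------------------


@dataclass
class ProductionResult:
    """Outcome of one product-maximization solve.

    ``yield_mol_per_mol`` is product flux per glucose-equivalent substrate
    consumed; ``millimolar`` converts it to a batch concentration given the
    substrate consumed in mM glucose equivalents.
    """

    status: str
    product_flux: Optional[float] = None
    biomass_flux: Optional[float] = None
    substrate_flux: Optional[float] = None
    yield_mol_per_mol: Optional[float] = None

    def millimolar(self, substrate_mm: float) -> Optional[float]:
        if self.yield_mol_per_mol is None:
            return None
        return self.yield_mol_per_mol * substrate_mm


def max_product(
    model: Model,
    product_exchange: str,
    medium: Optional[MediumSpec] = None,
    biomass_min: float = 0.0,
    substrate_exchange: Optional[str] = None,
    glucose_equivalents: float = 1.0,
) -> ProductionResult:
    """Maximize a product exchange flux under a biomass floor.

    The substrate basis for the yield is the flux through
    ``substrate_exchange`` at the optimum (uptake is negative, so its
    magnitude is used), scaled by ``glucose_equivalents`` per substrate unit.
    """

    problem = FluxProblem(model, medium=medium)
    overrides = {}
    if biomass_min > 0 and model.biomass_id is not None:
        j = problem.index[model.biomass_id]
        overrides[model.biomass_id] = (biomass_min, problem.ub[j])
    sol = problem.solve({product_exchange: 1.0}, maximize=True, overrides=overrides)
    if not sol.optimal:
        return ProductionResult(status=sol.status)
    biomass = (
        sol.fluxes.get(model.biomass_id) if model.biomass_id is not None else None
    )
    substrate = None
    yield_ = None
    if substrate_exchange is not None:
        substrate = -sol.fluxes[substrate_exchange] * glucose_equivalents
        if substrate > 1e-12:
            yield_ = sol.objective_value / substrate
        elif abs(sol.objective_value) < 1e-9:
            yield_ = 0.0
    return ProductionResult(
        status="optimal",
        product_flux=sol.objective_value,
        biomass_flux=biomass,
        substrate_flux=substrate,
        yield_mol_per_mol=yield_,
    )


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrixResult:
    table: pd.DataFrame


def evaluate_designs(
    base: Model,
    designs: Mapping[str, StrainDesign],
    bfh2ase_mode: str = "forward_only",
    medium: Optional[MediumSpec] = None,
    biomass_min: float = 0.0,
    product_exchange: str = "EX_etoh",
    substrate_exchange: Optional[str] = None,
    glucose_equivalents: float = 1.0,
    bfh2ase_id: str = "BFH2",
) -> DesignMatrixResult:
    """Evaluate a named family of designs under one BF-H2ase directionality.

    Each row reports the maximum product flux, the biomass flux at that
    optimum, and the solve status; all rows share the same medium.  Rows that
    are infeasible are still returned (status recorded).
    """

    if bfh2ase_mode not in ("reversible", "forward_only"):
        raise ValueError(f"unknown BF-H2ase mode {bfh2ase_mode!r}")
    rows = []
    for name, design in designs.items():
        if bfh2ase_id in base.reactions:
            mode_override = {bfh2ase_id: bfh2ase_mode}
            design = design.merged(
                StrainDesign(direction_overrides=mode_override)
            ) if bfh2ase_id not in design.direction_overrides else design
        edited = apply_design(base, design)
        res = max_product(
            edited,
            product_exchange,
            medium=medium,
            biomass_min=biomass_min,
            substrate_exchange=substrate_exchange,
            glucose_equivalents=glucose_equivalents,
        )
        rows.append(
            {
                "design": name,
                "bfh2ase_mode": design.direction_overrides.get(bfh2ase_id, bfh2ase_mode),
                "status": res.status,
                "max_product_flux": res.product_flux,
                "yield_mol_per_mol": res.yield_mol_per_mol,
                "biomass_flux": res.biomass_flux,
            }
        )
    return DesignMatrixResult(table=pd.DataFrame(rows))


def production_envelope(
    model: Model,
    product_exchange: str,
    steps: int = 100,
    medium: Optional[MediumSpec] = None,
    biomass_min: float = 0.0,
    watch: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Flux-variability sweep over product-production levels.

    At each step s in 0..steps the product flux is fixed to
    ``(s/steps) * max`` and the min/max flux of every watched reaction is
    computed.  Step 0 therefore reproduces the unconstrained variability.
    """

    problem = FluxProblem(model, medium=medium)
    overrides: dict[str, tuple[float, float]] = {}
    if biomass_min > 0 and model.biomass_id is not None:
        j = problem.index[model.biomass_id]
        overrides[model.biomass_id] = (biomass_min, problem.ub[j])
    base = problem.solve({product_exchange: 1.0}, maximize=True, overrides=overrides)
    if not base.optimal:
        raise RuntimeError(f"envelope base problem {base.status}")
    vmax = base.objective_value

    if watch is None:
        watch = [r for r in ("GAPDH", "GOR", "MBH", "BFH2", "NFN", "ATPS", "ACK",
                             "RNF_NA", "RNF_H", "MRP", "SH1", "SH2", "EX_h2")
                 if r in problem.index]
    records = []
    for s in range(steps + 1):
        target = vmax * s / steps
        step_over = dict(overrides)
        step_over[product_exchange] = (target, target)
        for rid in watch:
            lo = problem.solve({rid: 1.0}, maximize=False, overrides=step_over)
            hi = problem.solve({rid: 1.0}, maximize=True, overrides=step_over)
            records.append(
                {
                    "step": s,
                    "product_flux": target,
                    "reaction": rid,
                    "min_flux": lo.objective_value if lo.optimal else float("nan"),
                    "max_flux": hi.objective_value if hi.optimal else float("nan"),
                }
            )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Balance audits
# ---------------------------------------------------------------------------


def _element_count(model: Model, key: tuple[str, str], element: str) -> Fraction:
    cpd = model.compounds[key]
    if cpd.formula is None:
        raise ValueError(f"compound {key} has no formula")
    return Fraction(parse_formula(cpd.formula).get(element, 0))


def _degree_of_reduction(model: Model, key: tuple[str, str]) -> Fraction:
    """Electron equivalents per molecule: 4C + H - 2O - 3N + 5P + 6S - charge."""

    cpd = model.compounds[key]
    counts = parse_formula(cpd.formula)
    weights = {"C": 4, "H": 1, "O": -2, "N": -3, "P": 5, "S": 6}
    gamma = sum(weights.get(el, 0) * n for el, n in counts.items())
    charge = cpd.charge if cpd.charge is not None else 0
    return Fraction(gamma - charge)


def _boundary_net(model: Model, fluxes: Mapping[str, float], per_species) -> float:
    """Net export of a species-weighted quantity over all boundary reactions.

    Exchanges/sinks export (positive flux = secretion of the substrate
    species); the biomass reaction's net consumption counts as fixed into
    biomass.  A zero return value means the quantity is conserved.
    """

    total = 0.0
    for rid, rxn in model.reactions.items():
        v = fluxes.get(rid, 0.0)
        if abs(v) < 1e-12:
            continue
        if rxn.kind in ("exchange", "sink"):
            for key, coef in rxn.stoichiometry.items():
                # coef is negative (species leaves the network when v > 0)
                total += -float(coef) * v * float(per_species(key))
        elif rxn.kind == "biomass":
            for key, coef in rxn.stoichiometry.items():
                total += -float(coef) * v * float(per_species(key))
    return total


def carbon_balance(model: Model, fluxes: Mapping[str, float]) -> float:
    """Net carbon export (should be ~0 at steady state): secreted + stored
    in biomass minus substrate carbon."""

    net = _boundary_net(model, fluxes, lambda key: _element_count(model, key, "C"))
    # Uptake contributes negative terms, secretion positive: conservation
    # means the two cancel.
    return net


def electron_balance(model: Model, fluxes: Mapping[str, float]) -> float:
    """Net degree-of-reduction export (should be ~0 at steady state)."""

    return _boundary_net(model, fluxes, lambda key: _degree_of_reduction(model, key))
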