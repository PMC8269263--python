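"""Model-validation stage: growth phenotypes, yield comparisons, unit
conversions, and product-ratio calibration.

These operations mirror how a reconstruction is confronted with experimental
data: a growth/no-growth matrix over candidate carbon sources, conversion of
cell counts and protein measurements to dry-weight yields, and calibration
of secreted-product flux ratios to measured concentration ratios before
comparing predicted biomass with batch measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .analysis import ConstrainedModel, LinearCoupling, fba
from .model import MediumSpec, Model

__all__ = [
    "GROWTH_TOLERANCE",
    "CELL_DRY_WEIGHT_MG",
    "PhenotypeRecord",
    "growth_matrix",
    "cells_to_biomass",
    "LinearFit",
    "fit_protein_dryweight",
    "calibrate_product_ratios",
]

#: Biomass flux above which a simulation counts as growth (LP noise floor).
GROWTH_TOLERANCE = 1e-6

#: Estimated dry weight of a single cell, in mg.
CELL_DRY_WEIGHT_MG = 8.2e-10


@dataclass(frozen=True)
class PhenotypeRecord:
    substrate: str
    experimental_growth: bool
    predicted_growth: bool
    exchange_missing: bool = False

    @property
    def consistent(self) -> bool:
        return self.experimental_growth == self.predicted_growth


def growth_matrix(
    model: Model,
    substrates: Sequence[tuple[str, Optional[str], bool]],
    basal_medium: MediumSpec,
    uptake: float = 10.0,
    carbon_exchanges: Optional[Iterable[str]] = None,
) -> list[PhenotypeRecord]:
    """Growth/no-growth prediction per sole carbon source.

    ``substrates`` is a list of (name, exchange id or None, experimental
    growth).  For each, the basal medium is applied with every carbon
    exchange closed to uptake and only the tested substrate opened.  A
    substrate lacking an exchange reaction is recorded as predicted
    no-growth with the ``exchange_missing`` flag set.
    """

    if model.biomass_id is None:
        raise ValueError("model has no biomass reaction")
    carbon = set(carbon_exchanges or [])
    records = []
    for name, exchange, grows in substrates:
        if exchange is None or exchange not in model.reactions:
            records.append(
                PhenotypeRecord(
                    substrate=name,
                    experimental_growth=grows,
                    predicted_growth=False,
                    exchange_missing=True,
                )
            )
            continue
        bounds = dict(basal_medium.bounds)
        for ex in carbon:
            bounds[ex] = (0.0, bounds.get(ex, (0.0, model.default_bound))[1])
        bounds[exchange] = (-float(uptake), bounds.get(exchange, (0.0, model.default_bound))[1])
        sol = fba(model, model.biomass_id, medium=MediumSpec(bounds=bounds))
        predicted = bool(sol.optimal and sol.objective_value > GROWTH_TOLERANCE)
        records.append(
            PhenotypeRecord(
                substrate=name, experimental_growth=grows, predicted_growth=predicted
            )
        )
    return records


def cells_to_biomass(cell_count_per_liter: float) -> float:
    """Convert a cell density (cells/L) to g dry weight per liter."""

    if cell_count_per_liter < 0:
        raise ValueError("cell count must be nonnegative")
    return cell_count_per_liter * CELL_DRY_WEIGHT_MG * 1e-3


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float

    def __call__(self, protein_g_per_l: float) -> float:
        return self.slope * protein_g_per_l + self.intercept


def fit_protein_dryweight(
    pairs: Sequence[tuple[float, float]]
) -> LinearFit:
    """Ordinary least squares line mapping protein yield to dry weight.

    Needs at least two calibration points; returns slope, intercept, and R^2
    of the fit, usable directly as a conversion function.
    """

    if len(pairs) < 2:
        raise ValueError("need at least two calibration points")
    x = np.asarray([p for p, _ in pairs], dtype=float)
    y = np.asarray([d for _, d in pairs], dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    predicted = slope * x + intercept
    ss_res = float(np.sum((y - predicted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return LinearFit(slope=float(slope), intercept=float(intercept), r_squared=r2)


def _default_product_universe(
    model: Model, medium: Optional[MediumSpec] = None
) -> list[str]:
    """Secretion-only exchanges of carbon compounds, excluding CO2.

    These are the overflow metabolites whose relative abundances a batch
    experiment measures; substrate exchanges (anything the medium opens for
    uptake) and CO2 are not part of the measured product pool.
    """

    from .checks import formula_is_generic, parse_formula

    medium_bounds = medium.bounds if medium is not None else {}
    universe = []
    for rid, rxn in model.reactions.items():
        if rxn.kind != "exchange":
            continue
        lower = medium_bounds.get(rid, (rxn.lower_bound, rxn.upper_bound))[0]
        if lower < 0:
            continue
        (key,) = rxn.stoichiometry
        cpd = model.compounds[key]
        if formula_is_generic(cpd.formula):
            continue
        counts = parse_formula(cpd.formula)
        if counts.get("C", 0) > 0 and cpd.id != "co2":
            universe.append(rid)
    return sorted(universe)


def calibrate_product_ratios(
    model: Model,
    measured_ratios: Mapping[str, float],
    products: Optional[Iterable[str]] = None,
    medium: Optional[MediumSpec] = None,
) -> ConstrainedModel:
    """Pin secreted-product flux ratios to measured relative concentrations.

    ``measured_ratios`` maps product exchange ids to molar fractions of the
    total secretion over the product universe (by default, every
    secretion-only carbon exchange except CO2).  For each calibrated product
    p the coupling ``v_p = r_p * sum_q v_q`` (q over the universe) is added.
    Fractions must be positive and sum to at most 1; a single product with
    ratio 1.0 therefore routes the entire secreted pool to that product.
    """

    if not measured_ratios:
        raise ValueError("no product ratios given")
    total = sum(measured_ratios.values())
    if any(r <= 0 for r in measured_ratios.values()) or total > 1.0 + 1e-6:
        raise ValueError(
            "ratios must be positive and sum to at most 1 of the secreted pool"
        )
    universe = (
        sorted(products)
        if products is not None
        else _default_product_universe(model, medium=medium)
    )
    for ex in measured_ratios:
        if ex not in model.reactions:
            raise ValueError(f"unknown product exchange {ex!r}")
        if ex not in universe:
            raise ValueError(f"product {ex!r} is not in the calibration universe")
    couplings = []
    for p in sorted(measured_ratios):
        r = measured_ratios[p]
        coeffs = {q: (1.0 - r) if q == p else -r for q in universe}
        couplings.append(LinearCoupling(coeffs, 0.0, 0.0))
    return ConstrainedModel(model=model, constraints=tuple(couplings))
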