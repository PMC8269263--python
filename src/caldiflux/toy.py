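"""Synthetic core-metabolism model of *Caldicellulosiruptor bescii*.

:func:`build_toy` emits a small, fully element- and charge-balanced
stoichiometric model that reproduces the architecture of the organism's
central carbon and redox metabolism:

* parallel glycolytic branches — NAD-dependent GAPDH/PGK (with PGK accepting
  ADP or GDP) versus the ferredoxin-dependent GOR bypass that skips the
  substrate-level phosphorylation step;
* pyruvate ferredoxin oxidoreductase (POR) as the sole route to acetyl-CoA;
* fermentative sinks: lactate (LDH, whose gene also carries the MDH
  activity), acetate via PTA/AckA substrate-level phosphorylation, an
  NADH-neutral acetoin drain, pyruvate secretion, and — only when the AdhE
  knock-in is present — ethanol;
* the three native ferredoxin sinks: the proton-pumping membrane-bound
  hydrogenase (MBH), the electron-bifurcating hydrogenase (BF-H2ase,
  reversible or H2-producing-only), and the bifurcating NAD(P)
  transhydrogenase (BF-Nfn);
* ATP synthase driven by the pumped-proton pool, plus nucleotide
  housekeeping (NDPK, adenylate kinase, pyrophosphatase) and a lumped
  pyrimidine branch gated by the *pyrE* gene with a uracil-salvage bypass.

Every non-boundary reaction balances exactly (ferredoxin is treated as a
two-electron carrier with a fixed Fe8S8 core, so reduction only changes its
charge).  The redox economics are therefore hand-checkable: with glucose as
substrate the ethanol ceiling is 2 mol/mol (all 24 electron equivalents to
ethanol), reachable only when reduced ferredoxin can be converted to NADH —
via a reversible BF-H2ase recycling MBH-produced H2, via an Rnf, or via the
SH2 hydrogenase.

The module also provides :func:`random_lp_fixture`, a generator of tiny
networks with closed-form optima used as LP test oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

import numpy as np

from .io import parse_equation
from .model import (
    Compound,
    MediumSpec,
    Model,
    ModelValidationError,
    Reaction,
    infer_kind,
    parse_gene_association,
)

__all__ = ["ToyOptions", "build_toy", "default_medium", "random_lp_fixture"]

KNOCKIN_NAMES = ("AdhE", "Rnf_Na", "Rnf_H", "Mrp", "SH1", "SH2")

SUBSTRATE_EXCHANGES = {
    "glucose": "EX_glc",
    "cellobiose": "EX_cellb",
    "cellulose": "EX_cellu",
}

#: Glucose equivalents delivered per unit of substrate uptake.
GLUCOSE_EQUIVALENTS = {"glucose": 1, "cellobiose": 2, "cellulose": 1}


@dataclass(frozen=True)
class ToyOptions:
    """Configuration of the synthetic core model.

    ``substrate`` selects which carbon source the default medium opens;
    ``knockins`` are drawn from AdhE, Rnf_Na, Rnf_H, Mrp, SH1, SH2;
    ``bfh2ase_mode`` is ``reversible`` or ``forward_only`` (H2-producing
    only).  Ion stoichiometries and biomass demands are exposed because the
    published reconstruction does not state them; defaults are small
    integers chosen for hand-checkable balances.
    """

    substrate: str = "glucose"
    knockins: frozenset[str] = frozenset()
    bfh2ase_mode: str = "reversible"
    uptake: float = 10.0
    uracil_in_medium: bool = False
    mbh_protons: int = 1      # H+ pumped out per H2 produced by MBH
    atps_protons: int = 3     # H+ translocated in per ATP by ATP synthase
    rnf_ions: int = 1         # ions translocated per Fd_red oxidized by Rnf
    biomass_atp: float = 30.0
    biomass_nadph: float = 6.0
    biomass_precursor: float = 1.0
    biomass_uracil: float = 1.0
    default_bound: float = 1000.0

    def __post_init__(self) -> None:
        if self.substrate not in SUBSTRATE_EXCHANGES:
            raise ModelValidationError(f"unknown substrate {self.substrate!r}")
        unknown = set(self.knockins) - set(KNOCKIN_NAMES)
        if unknown:
            raise ModelValidationError(f"unknown knock-ins: {sorted(unknown)}")
        object.__setattr__(self, "knockins", frozenset(self.knockins))
        if self.bfh2ase_mode not in ("reversible", "forward_only"):
            raise ModelValidationError(
                f"unknown BF-H2ase mode {self.bfh2ase_mode!r}"
            )
        if "Mrp" in self.knockins and "Rnf_Na" not in self.knockins:
            raise ModelValidationError(
                "Mrp requires the sodium-translocating Rnf_Na (no Na+ species "
                "exist without it)"
            )
        for coeff in (
            self.biomass_atp,
            self.biomass_nadph,
            self.biomass_precursor,
            self.biomass_uracil,
        ):
            if coeff <= 0:
                raise ModelValidationError("biomass coefficients must be positive")
        if min(self.mbh_protons, self.atps_protons, self.rnf_ions) < 1:
            raise ModelValidationError("ion stoichiometries must be >= 1")


# (id, compartment, name, formula, charge)
_COMPOUNDS = [
    ("13dpg", "c", "1,3-bisphosphoglycerate", "C3H4O10P2", -4),
    ("3pg", "c", "3-phosphoglycerate", "C3H4O7P", -3),
    ("ac", "c", "acetate", "C2H3O2", -1),
    ("ac", "e", "acetate", "C2H3O2", -1),
    ("accoa", "c", "acetyl-CoA", "C23H34N7O17P3S", -4),
    ("actn", "c", "acetoin", "C4H8O2", 0),
    ("actn", "e", "acetoin", "C4H8O2", 0),
    ("actp", "c", "acetyl phosphate", "C2H3O5P", -2),
    ("adp", "c", "ADP", "C10H12N5O10P2", -3),
    ("amp", "c", "AMP", "C10H12N5O7P", -2),
    ("atp", "c", "ATP", "C10H12N5O13P3", -4),
    ("cellb", "e", "cellobiose", "C12H22O11", 0),
    ("cellu", "e", "cellulose (anhydroglucose unit)", "C6H10O5", 0),
    ("co2", "c", "CO2", "CO2", 0),
    ("co2", "e", "CO2", "CO2", 0),
    ("coa", "c", "coenzyme A", "C21H32N7O16P3S", -4),
    ("etoh", "c", "ethanol", "C2H6O", 0),
    ("etoh", "e", "ethanol", "C2H6O", 0),
    ("fdox", "c", "oxidized ferredoxin (2e- carrier)", "Fe8S8", 0),
    ("fdred", "c", "reduced ferredoxin (2e- carrier)", "Fe8S8", -2),
    ("g6p", "c", "glucose 6-phosphate", "C6H11O9P", -2),
    ("gap", "c", "glyceraldehyde 3-phosphate", "C3H5O6P", -2),
    ("gdp", "c", "GDP", "C10H12N5O11P2", -3),
    ("glc", "c", "D-glucose", "C6H12O6", 0),
    ("glc", "e", "D-glucose", "C6H12O6", 0),
    ("gtp", "c", "GTP", "C10H12N5O14P3", -4),
    ("h", "c", "proton (cytosolic)", "H", 1),
    ("h", "e", "proton (translocated)", "H", 1),
    ("h2", "c", "H2", "H2", 0),
    ("h2", "e", "H2", "H2", 0),
    ("h2o", "c", "water", "H2O", 0),
    ("h2o", "e", "water", "H2O", 0),
    ("lac", "c", "L-lactate", "C3H5O3", -1),
    ("lac", "e", "L-lactate", "C3H5O3", -1),
    ("mal", "c", "L-malate", "C4H4O5", -2),
    ("nad", "c", "NAD+", "C21H26N7O14P2", -1),
    ("nadh", "c", "NADH", "C21H27N7O14P2", -2),
    ("nadp", "c", "NADP+", "C21H25N7O17P3", -3),
    ("nadph", "c", "NADPH", "C21H26N7O17P3", -4),
    ("nh4", "c", "ammonium", "H4N", 1),
    ("nh4", "e", "ammonium", "H4N", 1),
    ("oaa", "c", "oxaloacetate", "C4H2O5", -2),
    ("pep", "c", "phosphoenolpyruvate", "C3H2O6P", -3),
    ("pi", "c", "orthophosphate", "HO4P", -2),
    ("pi", "e", "orthophosphate", "HO4P", -2),
    ("ppi", "c", "pyrophosphate", "HO7P2", -3),
    ("pyr", "c", "pyruvate", "C3H3O3", -1),
    ("pyr", "e", "pyruvate", "C3H3O3", -1),
    ("ura", "c", "uracil", "C4H4N2O2", 0),
    ("ura", "e", "uracil", "C4H4N2O2", 0),
]

_NA_COMPOUNDS = [
    ("na", "c", "sodium ion", "Na", 1),
    ("na", "e", "sodium ion", "Na", 1),
]


def _core_reactions(opt: ToyOptions) -> list[tuple[str, str, Optional[str], str]]:
    """(id, equation, genes, subsystem) for the native network."""

    p = opt.mbh_protons
    n = opt.atps_protons
    return [
        # Glycolysis (EMP), lumped above GAP
        ("GLK", "glc[c] + atp[c] => g6p[c] + adp[c] + h[c]", "g_glk", "Glycolysis"),
        ("PFKALD", "g6p[c] + atp[c] => (2) gap[c] + adp[c] + h[c]", "g_pfk", "Glycolysis"),
        # NAD branch: GAPDH + PGK (ADP or GDP)
        ("GAPDH", "gap[c] + nad[c] + pi[c] <=> 13dpg[c] + nadh[c] + h[c]", "g_gapdh", "Glycolysis"),
        ("PGK", "13dpg[c] + adp[c] <=> 3pg[c] + atp[c]", "g_pgk", "Glycolysis"),
        ("PGK_GDP", "13dpg[c] + gdp[c] <=> 3pg[c] + gtp[c]", "g_pgk", "Glycolysis"),
        # Ferredoxin branch: GOR bypasses the PGK phosphorylation
        ("GOR", "gap[c] + fdox[c] + h2o[c] => 3pg[c] + fdred[c] + (3) h[c]", "g_gor", "Glycolysis"),
        ("PGMENO", "3pg[c] <=> pep[c] + h2o[c]", "g_eno", "Glycolysis"),
        ("PK", "pep[c] + adp[c] + h[c] => pyr[c] + atp[c]", "g_pyk", "Glycolysis"),
        ("PPDK", "pyr[c] + atp[c] + pi[c] <=> pep[c] + amp[c] + ppi[c] + h[c]", "g_ppdk", "Glycolysis"),
        # Anaplerosis / GTP node
        ("PCK", "oaa[c] + gtp[c] <=> pep[c] + co2[c] + gdp[c]", "g_pck", "Anaplerosis"),
        ("MDH", "oaa[c] + nadh[c] + h[c] <=> mal[c] + nad[c]", "g_ldh", "Anaplerosis"),
        # Pyruvate node
        ("LDH", "pyr[c] + nadh[c] + h[c] => lac[c] + nad[c]", "g_ldh", "Fermentation"),
        ("POR", "pyr[c] + coa[c] + fdox[c] => accoa[c] + co2[c] + fdred[c] + h[c]", "g_por", "Fermentation"),
        ("PTA", "accoa[c] + pi[c] <=> actp[c] + coa[c]", "g_pta", "Fermentation"),
        ("ACK", "actp[c] + adp[c] <=> ac[c] + atp[c]", "g_ack", "Fermentation"),
        ("ALS", "(2) pyr[c] + (2) h[c] => actn[c] + (2) co2[c]", "g_als", "Fermentation"),
        # Redox triad
        (
            "MBH",
            f"fdred[c] + ({2 + p}) h[c] => fdox[c] + h2[c] + ({p}) h[e]"
            if p != 1
            else "fdred[c] + (3) h[c] => fdox[c] + h2[c] + h[e]",
            "g_mbhA and g_mbhB",
            "Redox",
        ),
        ("BFH2", "fdred[c] + nadh[c] + (3) h[c] <=> (2) h2[c] + fdox[c] + nad[c]", "g_bfhA and g_bfhB and g_bfhC", "Redox"),
        ("NFN", "fdred[c] + nadh[c] + (2) nadp[c] + h[c] <=> fdox[c] + nad[c] + (2) nadph[c]", "g_nfn", "Redox"),
        # Energy conservation and nucleotide housekeeping
        (
            "ATPS",
            "adp[c] + pi[c] + h[e] <=> atp[c] + h2o[c]"
            if n == 1
            else f"adp[c] + pi[c] + ({n}) h[e] <=> atp[c] + h2o[c] + ({n - 1}) h[c]",
            "g_atpA and g_atpB",
            "Energy",
        ),
        ("ATPM", "atp[c] + h2o[c] => adp[c] + pi[c] + h[c]", None, "Energy"),
        ("NDPK", "atp[c] + gdp[c] <=> adp[c] + gtp[c]", "g_ndk", "Energy"),
        ("ADK", "amp[c] + atp[c] <=> (2) adp[c]", "g_adk", "Energy"),
        ("PPA", "ppi[c] + h2o[c] => (2) pi[c] + h[c]", "g_ppa", "Energy"),
        # Pyrimidine branch: lumped de novo synthesis (pyrE) + uracil salvage
        ("URASYN", "oaa[c] + (2) nh4[c] => ura[c] + (3) h2o[c]", "g_pyrE", "Pyrimidine"),
        # Transport and extracellular hydrolysis
        ("GLCt", "glc[e] => glc[c]", None, "Transport"),
        ("CELLBHYD", "cellb[e] + h2o[e] => (2) glc[e]", "g_bgl", "Carbohydrate degradation"),
        ("CELLUHYD", "cellu[e] + h2o[e] => glc[e]", "g_celA", "Carbohydrate degradation"),
        ("ETOHt", "etoh[c] <=> etoh[e]", None, "Transport"),
        ("ACt", "ac[c] <=> ac[e]", None, "Transport"),
        ("LACt", "lac[c] <=> lac[e]", None, "Transport"),
        ("PYRt", "pyr[c] <=> pyr[e]", None, "Transport"),
        ("ACTNt", "actn[c] <=> actn[e]", None, "Transport"),
        ("CO2t", "co2[c] <=> co2[e]", None, "Transport"),
        ("H2t", "h2[c] <=> h2[e]", None, "Transport"),
        ("H2Ot", "h2o[c] <=> h2o[e]", None, "Transport"),
        ("URAt", "ura[e] => ura[c]", None, "Transport"),
        ("NH4t", "nh4[e] => nh4[c]", None, "Transport"),
        ("PIt", "pi[e] => pi[c]", None, "Transport"),
    ]


def _knockin_reactions(opt: ToyOptions) -> list[tuple[str, str, Optional[str], str]]:
    k = opt.rnf_ions
    defs = {
        "AdhE": (
            "ADHE",
            "accoa[c] + (2) nadh[c] + (2) h[c] => etoh[c] + coa[c] + (2) nad[c]",
            "g_adhE",
            "Fermentation",
        ),
        "Rnf_Na": (
            "RNF_NA",
            (
                f"fdred[c] + nad[c] + h[c] + ({k}) na[c] => fdox[c] + nadh[c] + ({k}) na[e]"
                if k != 1
                else "fdred[c] + nad[c] + h[c] + na[c] => fdox[c] + nadh[c] + na[e]"
            ),
            "g_rnfNa",
            "Redox",
        ),
        "Rnf_H": (
            "RNF_H",
            (
                f"fdred[c] + nad[c] + ({1 + k}) h[c] => fdox[c] + nadh[c] + ({k}) h[e]"
                if k != 1
                else "fdred[c] + nad[c] + (2) h[c] => fdox[c] + nadh[c] + h[e]"
            ),
            "g_rnfH",
            "Redox",
        ),
        "Mrp": ("MRP", "na[e] + h[c] => na[c] + h[e]", "g_mrp", "Redox"),
        "SH1": ("SH1", "h2[c] + nadp[c] => nadph[c] + h[c]", "g_sh1", "Redox"),
        "SH2": ("SH2", "h2[c] + nad[c] => nadh[c] + h[c]", "g_sh2", "Redox"),
    }
    return [defs[name] for name in sorted(opt.knockins)]


_EXCHANGES = [
    ("EX_ac", "ac[e] <=>"),
    ("EX_actn", "actn[e] <=>"),
    ("EX_cellb", "cellb[e] <=>"),
    ("EX_cellu", "cellu[e] <=>"),
    ("EX_co2", "co2[e] <=>"),
    ("EX_etoh", "etoh[e] <=>"),
    ("EX_glc", "glc[e] <=>"),
    ("EX_h2", "h2[e] <=>"),
    ("EX_h2o", "h2o[e] <=>"),
    ("EX_lac", "lac[e] <=>"),
    ("EX_nh4", "nh4[e] <=>"),
    ("EX_pi", "pi[e] <=>"),
    ("EX_pyr", "pyr[e] <=>"),
    ("EX_ura", "ura[e] <=>"),
]

BIOMASS_ID = "BIOMASS"


def build_toy(options: Optional[ToyOptions] = None) -> Model:
    """Build the synthetic core model for the given options.

    The returned model is deterministic (same options -> identical
    serialization), passes all four quality checks, and has secretion-only
    exchange defaults — pair it with :func:`default_medium` to allow uptake.
    """

    opt = options or ToyOptions()
    model = Model(name="toy-cbescii-core", biomass_id=BIOMASS_ID,
                  default_bound=opt.default_bound)

    compounds = list(_COMPOUNDS)
    if "Rnf_Na" in opt.knockins:
        compounds += _NA_COMPOUNDS
    for cid, comp, name, formula, charge in compounds:
        model.add_compound(
            Compound(id=cid, name=name, formula=formula, charge=charge,
                     compartment=comp)
        )

    for rid, equation, genes, subsystem in _core_reactions(opt) + _knockin_reactions(opt):
        stoich, reversible = parse_equation(equation)
        model.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=-opt.default_bound if reversible else 0.0,
                upper_bound=opt.default_bound,
                genes=parse_gene_association(genes) if genes else None,
                subsystem=subsystem,
                kind=infer_kind(stoich),
            )
        )

    if opt.bfh2ase_mode == "forward_only":
        model.reactions["BFH2"].lower_bound = 0.0

    for rid, equation in _EXCHANGES:
        stoich, _ = parse_equation(equation)
        model.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=0.0,            # secretion-only until a medium opens uptake
                upper_bound=opt.default_bound,
                kind="exchange",
                subsystem="Exchange",
            )
        )
    model.reactions["EX_h2o"].lower_bound = -opt.default_bound  # water is free

    # Cytosolic proton buffer: scalar protons produced/consumed by metabolism
    # are absorbed here; the periplasmic pool h[e] has no such sink, so the
    # proton-motive force is generated only by the pumps (MBH, Rnf, Mrp).
    model.add_reaction(
        Reaction(
            id="SINK_h",
            stoichiometry={("h", "c"): Fraction(-1)},
            lower_bound=-opt.default_bound,
            upper_bound=opt.default_bound,
            kind="sink",
            subsystem="Pseudo",
        )
    )

    a = Fraction(opt.biomass_atp).limit_denominator(10**6)
    r = Fraction(opt.biomass_nadph).limit_denominator(10**6)
    q = Fraction(opt.biomass_precursor).limit_denominator(10**6)
    u = Fraction(opt.biomass_uracil).limit_denominator(10**6)
    biomass_stoich = {
        ("g6p", "c"): -q,
        ("pep", "c"): -q,
        ("pyr", "c"): -q,
        ("accoa", "c"): -q,
        ("oaa", "c"): -q,
        ("ura", "c"): -u,
        ("atp", "c"): -a,
        ("h2o", "c"): -a,
        ("nadph", "c"): -r,
        ("adp", "c"): a,
        ("pi", "c"): a,
        ("nadp", "c"): r,
        ("coa", "c"): q,
        ("h", "c"): a + r,
    }
    model.add_reaction(
        Reaction(
            id=BIOMASS_ID,
            stoichiometry=biomass_stoich,
            lower_bound=0.0,
            upper_bound=opt.default_bound,
            kind="biomass",
            subsystem="Biomass",
        )
    )
    model.validate()
    return model


def default_medium(options: Optional[ToyOptions] = None) -> MediumSpec:
    """Growth medium matching the options: one carbon source, free NH4/water.

    Uptake of the selected substrate is capped at ``options.uptake`` flux
    units (glucose equivalents differ per substrate; see
    :data:`GLUCOSE_EQUIVALENTS`).  Uracil uptake is opened only when
    ``uracil_in_medium`` is set (the salvage condition for ΔpyrE strains).
    """

    opt = options or ToyOptions()
    bounds = {
        SUBSTRATE_EXCHANGES[opt.substrate]: (-float(opt.uptake), 0.0),
        "EX_nh4": (-opt.default_bound, opt.default_bound),
        "EX_pi": (-opt.default_bound, opt.default_bound),
        "EX_h2o": (-opt.default_bound, opt.default_bound),
    }
    if opt.uracil_in_medium:
        bounds["EX_ura"] = (-opt.default_bound, 0.0)
    return MediumSpec(bounds=bounds)


# ---------------------------------------------------------------------------
# Random LP fixtures with known optima
# ---------------------------------------------------------------------------


def random_lp_fixture(
    seed: int, n_reactions: int = 6
) -> tuple[Model, float, str]:
    """Generate a tiny network whose FBA optimum is known in closed form.

    Topologies: a linear conversion chain, or two parallel branches feeding
    one sink.  All bounds are small integers; the optimum is pure bound
    arithmetic (min of chain capacities, or min(uptake, sum of branch
    capacities)).  Returns ``(model, known_optimum, objective_id)`` where the
    objective is the terminal exchange reaction.
    """

    if not 3 <= n_reactions <= 6:
        raise ValueError("n_reactions must be in [3, 6]")
    rng = np.random.default_rng(seed)
    model = Model(name=f"fixture-{seed}", default_bound=1000.0)
    uptake = int(rng.integers(1, 11))

    def cpd(cid: str, comp: str = "c") -> tuple[str, str]:
        key = (cid, comp)
        if key not in model.compounds:
            model.add_compound(Compound(id=cid, compartment=comp))
        return key

    def rxn(rid, stoich, lb, ub, kind):
        model.add_reaction(
            Reaction(
                id=rid,
                stoichiometry={k: Fraction(v) for k, v in stoich.items()},
                lower_bound=float(lb),
                upper_bound=float(ub),
                kind=kind,
            )
        )

    rxn("EX_in", {cpd("m0", "e"): -1}, -uptake, 0, "exchange")

    if rng.random() < 0.5 or n_reactions < 5:
        # Chain: EX_in -> m0 -> m1 -> ... -> EX_out, with random caps.
        n_internal = n_reactions - 2
        caps = [int(rng.integers(1, 11)) for _ in range(n_internal)]
        prev = cpd("m0", "e")
        for i, cap in enumerate(caps):
            nxt = cpd(f"m{i + 1}")
            rxn(f"R{i}", {prev: -1, nxt: 1}, 0, cap, "cytosolic")
            prev = nxt
        rxn("EX_out", {prev: -1}, 0, 1000, "exchange")
        optimum = float(min([uptake] + caps))
    else:
        # Two parallel branches m0 -> sink, capacities c1 and c2.
        c1, c2 = int(rng.integers(1, 8)), int(rng.integers(1, 8))
        src = cpd("m0", "e")
        dst = cpd("m1")
        rxn("RA", {src: -1, dst: 1}, 0, c1, "cytosolic")
        rxn("RB", {src: -1, dst: 1}, 0, c2, "cytosolic")
        rxn("EX_out", {dst: -1}, 0, 1000, "exchange")
        optimum = float(min(uptake, c1 + c2))
    return model, optimum, "EX_out"
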