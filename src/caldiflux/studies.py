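"""Pre-composed study configurations.

The standard design matrix mirrors the engineering comparisons explored for
ethanol optimization: the AdhE+Rnf_Na base strain (E1M), single and combined
deletions of its ATP/GTP and redox functions and genetic-background genes,
and the alternative knock-in strategies (adding Mrp; replacing Rnf_Na with
Rnf_H, SH1 or SH2).  Rows marked with a leading ``-`` delete a function from
E1M; ``+`` inserts one.
"""

from __future__ import annotations

from typing import Mapping, Optional

from .design import DesignMatrixResult, evaluate_designs, knockin_catalog
from .model import MediumSpec, Model, StrainDesign

__all__ = ["standard_designs", "standard_design_matrix"]


def standard_designs(rnf_ions: int = 1) -> dict[str, StrainDesign]:
    """The named design matrix, all rows relative to an unengineered base.

    The base strain E1M is the wild-type network plus AdhE and Rnf_Na.
    Deletion rows remove reactions or genes from E1M; replacement rows swap
    Rnf_Na for an alternative redox knock-in.
    """

    cat = knockin_catalog(rnf_ions=rnf_ions)
    e1m = cat["AdhE"].as_design().merged(cat["Rnf_Na"].as_design())

    def minus(*reactions: str, genes: tuple[str, ...] = ()) -> StrainDesign:
        return e1m.merged(
            StrainDesign(
                deleted_reactions=frozenset(reactions),
                deleted_genes=frozenset(genes),
            )
        )

    adhe_only = cat["AdhE"].as_design()
    designs: dict[str, StrainDesign] = {
        "E1M": e1m,
        "E1M -Rnf_Na": adhe_only,
        "E1M -pyrE": e1m.merged(StrainDesign(deleted_genes=frozenset({"g_pyrE"}))),
        "E1M -ldh": e1m.merged(StrainDesign(deleted_genes=frozenset({"g_ldh"}))),
        "E1M -AckA": minus("ACK"),
        "E1M -PCK": minus("PCK"),
        "E1M -ATPSYN": minus("ATPS"),
        "E1M -MBH": minus("MBH"),
        "E1M -BF-H2ase": minus("BFH2"),
        "E1M -BF-Nfn": minus("NFN"),
        "E1M -MBH -BF-H2ase": minus("MBH", "BFH2"),
        "E1M -MBH -BF-Nfn": minus("MBH", "NFN"),
        "E1M -BF-H2ase -BF-Nfn": minus("BFH2", "NFN"),
        "E1M -MBH -BF-H2ase -BF-Nfn": minus("MBH", "BFH2", "NFN"),
        "E1M +Mrp": e1m.merged(cat["Mrp"].as_design()),
        "E1M Rnf_Na->Rnf_H": adhe_only.merged(cat["Rnf_H"].as_design()),
        "E1M Rnf_Na->SH1": adhe_only.merged(cat["SH1"].as_design()),
        "E1M Rnf_Na->SH2": adhe_only.merged(cat["SH2"].as_design()),
    }
    return designs


def standard_design_matrix(
    base: Model,
    medium: Optional[MediumSpec] = None,
    bfh2ase_mode: str = "forward_only",
    biomass_min: float = 0.0,
    substrate_exchange: str = "EX_glc",
    rnf_ions: int = 1,
) -> DesignMatrixResult:
    """Evaluate the standard matrix against an unengineered base model."""

    return evaluate_designs(
        base,
        standard_designs(rnf_ions=rnf_ions),
        bfh2ase_mode=bfh2ase_mode,
        medium=medium,
        biomass_min=biomass_min,
        substrate_exchange=substrate_exchange,
    )
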