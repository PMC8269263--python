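"""Strain-design studies: knock-in catalog balances, redox yield economics,
design-matrix monotonicity, balance audits, production envelopes."""

import numpy as np
import pytest

from caldiflux.analysis import FluxProblem, fba, fva
from caldiflux.checks import check_charge_balance, check_formula_balance
from caldiflux.design import (
    carbon_balance,
    electron_balance,
    knockin_catalog,
    max_product,
    production_envelope,
)
from caldiflux.model import StrainDesign, apply_design
from caldiflux.studies import standard_design_matrix, standard_designs
from caldiflux.toy import ToyOptions, build_toy, default_medium


def toy_with(knockins=(), mode="reversible"):
    opt = ToyOptions(knockins=frozenset(knockins), bfh2ase_mode=mode)
    return build_toy(opt), default_medium(opt)


class TestKnockinCatalog:
    def test_every_entry_is_element_and_charge_balanced(self):
        """Inserting each knock-in into the core network leaves the balance
        checks clean, translocated ions included."""

        base, _ = toy_with()
        for name, kin in knockin_catalog().items():
            edited = apply_design(base, kin.as_design())
            formulas = check_formula_balance(edited)
            charges = check_charge_balance(edited)
            for rxn in kin.reactions:
                assert rxn.id not in formulas.imbalanced, name
                assert rxn.id not in charges.imbalanced, name
                assert rxn.id not in formulas.excluded, name

    def test_adhe_gates_ethanol(self):
        base, medium = toy_with()
        assert fba(base, "EX_etoh", medium=medium).objective_value == pytest.approx(0.0, abs=1e-9)
        cat = knockin_catalog()
        with_adhe = apply_design(base, cat["AdhE"].as_design())
        assert fba(with_adhe, "EX_etoh", medium=medium).objective_value > 1.0

    def test_rnf_na_without_mrp_carries_no_flux(self):
        """With a closed sodium pool and no antiporter there is no Na+
        return path, so Rnf_Na is flux-locked at steady state."""

        model, medium = toy_with({"AdhE", "Rnf_Na"}, mode="forward_only")
        problem = FluxProblem(model, medium=medium)
        hi = problem.solve({"RNF_NA": 1.0}, maximize=True)
        assert hi.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_mrp_unlocks_rnf_na(self):
        model, medium = toy_with({"AdhE", "Rnf_Na", "Mrp"}, mode="forward_only")
        problem = FluxProblem(model, medium=medium)
        hi = problem.solve({"RNF_NA": 1.0}, maximize=True)
        assert hi.objective_value > 1.0


class TestRedoxEconomics:
    """The hand-checkable mol/mol ethanol ceilings of the core network."""

    @pytest.mark.parametrize(
        "knockins, mode, expected",
        [
            ({"AdhE"}, "reversible", 2.0),
            ({"AdhE"}, "forward_only", 1.0),
            ({"AdhE", "Rnf_H"}, "forward_only", 2.0),
            ({"AdhE", "Rnf_H"}, "reversible", 2.0),
            ({"AdhE", "Rnf_Na"}, "forward_only", 1.0),
            ({"AdhE", "Rnf_Na", "Mrp"}, "forward_only", 2.0),
            ({"AdhE", "SH2"}, "forward_only", 2.0),
        ],
    )
    def test_molar_yields(self, knockins, mode, expected):
        model, medium = toy_with(knockins, mode)
        res = max_product(model, "EX_etoh", medium=medium,
                          substrate_exchange="EX_glc")
        assert res.status == "optimal"
        assert res.yield_mol_per_mol == pytest.approx(expected, abs=1e-6)

    def test_yield_in_millimolar_units(self):
        model, medium = toy_with({"AdhE"}, "reversible")
        res = max_product(model, "EX_etoh", medium=medium,
                          substrate_exchange="EX_glc")
        assert res.millimolar(72.8) == pytest.approx(145.6, abs=1e-3)

    def test_no_ethanol_without_por(self):
        model, medium = toy_with({"AdhE"}, "reversible")
        edited = apply_design(model, StrainDesign(deleted_reactions=frozenset({"POR"})))
        res = max_product(edited, "EX_etoh", medium=medium)
        assert res.product_flux == pytest.approx(0.0, abs=1e-9)

    def test_mbh_bfh2ase_recycle_ratio_two_to_one(self):
        """At maximum ethanol the H2-recycling loop fixes MBH flux at twice
        the reverse BF-H2ase flux (m = 2b with 2 + b = 2b per glucose)."""

        model, medium = toy_with({"AdhE"}, "reversible")
        problem = FluxProblem(model, medium=medium)
        vmax = problem.solve({"EX_etoh": 1.0}, maximize=True).objective_value
        over = {"EX_etoh": (vmax, vmax)}
        mbh_min = problem.solve({"MBH": 1.0}, maximize=False, overrides=over)
        bf_max = problem.solve({"BFH2": 1.0}, maximize=True, overrides=over)
        assert bf_max.objective_value < 0  # forced into the H2-consuming direction
        assert mbh_min.objective_value == pytest.approx(
            2.0 * abs(bf_max.objective_value), rel=1e-6
        )
        # per 10 glucose: 40 MBH turnovers, 20 reverse BF-H2ase turnovers
        assert mbh_min.objective_value == pytest.approx(40.0, abs=1e-5)

    def test_mbh_deletion_shifts_atp_to_substrate_level(self):
        """Deleting MBH removes the pumped-proton supply: at maximum ethanol
        the ATP synthase flux collapses below 2% of its forced minimum in
        the unedited strain, and under a high biomass demand the acetate
        kinase route must carry ATP production instead."""

        model, medium = toy_with({"AdhE"}, "reversible")
        problem = FluxProblem(model, medium=medium)
        vmax = problem.solve({"EX_etoh": 1.0}, maximize=True).objective_value
        atps_min_base = problem.solve(
            {"ATPS": 1.0}, maximize=False, overrides={"EX_etoh": (vmax, vmax)}
        ).objective_value

        deleted = apply_design(model, StrainDesign(deleted_reactions=frozenset({"MBH"})))
        dprob = FluxProblem(deleted, medium=medium)
        dmax = dprob.solve({"EX_etoh": 1.0}, maximize=True).objective_value
        atps_max = dprob.solve(
            {"ATPS": 1.0}, maximize=True, overrides={"EX_etoh": (dmax, dmax)}
        )
        assert atps_min_base > 1.0
        assert atps_max.objective_value < 0.02 * atps_min_base

        # ATP bookkeeping under a biomass demand that exceeds what net
        # glycolytic phosphorylation alone can supply:
        demand = {"BIOMASS": (0.8, 1000.0)}
        ack_min_base = problem.solve({"ACK": 1.0}, maximize=False, overrides=demand)
        ack_min_del = dprob.solve({"ACK": 1.0}, maximize=False, overrides=demand)
        assert ack_min_base.objective_value == pytest.approx(0.0, abs=1e-6)
        assert ack_min_del.objective_value > 1.0


@pytest.fixture(scope="module")
def matrix():
    opt = ToyOptions()
    model = build_toy(opt)
    table = standard_design_matrix(
        model, medium=default_medium(opt), bfh2ase_mode="forward_only",
        substrate_exchange="EX_glc",
    ).table
    return table.set_index("design")


class TestDesignMatrix:
    def test_all_rows_solved(self, matrix):
        assert (matrix["status"] == "optimal").all()

    def test_triple_redox_deletion_is_lethal(self, matrix):
        row = matrix.loc["E1M -MBH -BF-H2ase -BF-Nfn"]
        assert row["max_product_flux"] == pytest.approx(0.0, abs=1e-9)
        opt = ToyOptions()
        model = build_toy(opt)
        triple = standard_designs()["E1M -MBH -BF-H2ase -BF-Nfn"]
        edited = apply_design(model, triple)
        bio = fba(edited, "BIOMASS", medium=default_medium(opt))
        assert bio.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_knockout_rows_never_exceed_parent(self, matrix):
        parent = matrix.loc["E1M", "max_product_flux"]
        knockout_rows = [name for name in matrix.index if " -" in name]
        assert knockout_rows
        for name in knockout_rows:
            assert matrix.loc[name, "max_product_flux"] <= parent + 1e-6

    def test_new_designs_reach_the_redox_ceiling(self, matrix):
        for name in ("E1M +Mrp", "E1M Rnf_Na->Rnf_H", "E1M Rnf_Na->SH1",
                     "E1M Rnf_Na->SH2"):
            assert matrix.loc[name, "yield_mol_per_mol"] == pytest.approx(2.0, abs=1e-6)

    def test_carbon_and_electron_balance_on_every_row(self):
        """Every optimal design solution conserves carbon and electron
        equivalents across the boundary."""

        opt = ToyOptions()
        model = build_toy(opt)
        medium = default_medium(opt)
        for name, design in standard_designs().items():
            merged = design.merged(
                StrainDesign(direction_overrides={"BFH2": "forward_only"})
            )
            edited = apply_design(model, merged)
            problem = FluxProblem(edited, medium=medium)
            sol = problem.solve({"EX_etoh": 1.0}, maximize=True)
            assert sol.optimal, name
            assert abs(carbon_balance(edited, sol.fluxes)) < 1e-6 * 60, name
            assert abs(electron_balance(edited, sol.fluxes)) < 1e-6 * 240, name


class TestProductionEnvelope:
    def test_step_zero_reproduces_unconstrained_fva(self):
        model, medium = toy_with({"AdhE"}, "reversible")
        table = production_envelope(model, "EX_etoh", steps=4, medium=medium,
                                    watch=["GAPDH", "MBH"])
        step0 = table[table.step == 0].set_index("reaction")
        free = fva(model, "EX_etoh", fraction=1.0, medium=medium,
                   reactions=["GAPDH", "MBH"])
        # step 0 pins the product to zero, i.e. variability without any
        # production requirement at all except product = 0
        problem = FluxProblem(model, medium=medium)
        for rid in ("GAPDH", "MBH"):
            lo = problem.solve({rid: 1.0}, maximize=False,
                               overrides={"EX_etoh": (0.0, 0.0)})
            assert step0.loc[rid, "min_flux"] == pytest.approx(
                lo.objective_value, abs=1e-6
            )

    def test_gapdh_essential_only_with_forward_only_bfh2ase(self):
        """At maximum ethanol, GAPDH must carry flux when BF-H2ase cannot
        consume H2, but the GOR route suffices when it can."""

        fwd, medium = toy_with({"AdhE"}, "forward_only")
        table = production_envelope(fwd, "EX_etoh", steps=5, medium=medium,
                                    watch=["GAPDH"])
        final = table[table.step == 5].iloc[0]
        assert final["min_flux"] > 1.0

        rev, medium = toy_with({"AdhE"}, "reversible")
        table = production_envelope(rev, "EX_etoh", steps=5, medium=medium,
                                    watch=["GAPDH"])
        final = table[table.step == 5].iloc[0]
        # zero GAPDH flux is feasible: the GOR route plus the MBH/BF-H2ase
        # recycle can supply all NADH
        assert final["min_flux"] <= 1e-6 <= final["max_flux"]

    def test_rnf_h_makes_mbh_and_h2_dispensable(self):
        """With a proton-pumping Rnf the H2 cycle is optional even at the
        maximum-ethanol point of a H2-producing-only BF-H2ase model."""

        model, medium = toy_with({"AdhE", "Rnf_H"}, "forward_only")
        table = production_envelope(model, "EX_etoh", steps=5, medium=medium,
                                    watch=["MBH", "EX_h2"])
        final = table[table.step == 5].set_index("reaction")
        assert final.loc["MBH", "min_flux"] == pytest.approx(0.0, abs=1e-6)
        assert final.loc["EX_h2", "min_flux"] == pytest.approx(0.0, abs=1e-6)
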