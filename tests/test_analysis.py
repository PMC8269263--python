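"""LP/QP engine: FBA against a brute-force oracle, FVA envelopes, MOMA."""

from fractions import Fraction

import numpy as np
import pytest

from caldiflux.analysis import FluxProblem, fba, fva, moma, moma_linear
from caldiflux.model import Compound, MediumSpec, Model, Reaction, stoichiometric_matrix
from caldiflux.toy import random_lp_fixture

from oracles import vertex_enumerate_optimum


def small_model(reactions, compounds):
    m = Model(name="small")
    for cid, comp in compounds:
        m.add_compound(Compound(id=cid, compartment=comp))
    for rid, st, lb, ub, kind in reactions:
        m.add_reaction(
            Reaction(id=rid, stoichiometry={k: Fraction(v) for k, v in st.items()},
                     lower_bound=lb, upper_bound=ub, kind=kind)
        )
    return m


class TestFba:
    def test_linear_chain_bottlenecked_by_uptake(self, chain_model):
        sol = fba(chain_model, "EX_B")
        assert sol.optimal
        assert sol.objective_value == pytest.approx(10.0)

    def test_medium_overrides_uptake(self, chain_model):
        sol = fba(chain_model, "EX_B", medium=MediumSpec(bounds={"EX_A": (-3, 0)}))
        assert sol.objective_value == pytest.approx(3.0)

    def test_infeasible_is_reported_not_raised(self):
        m = small_model(
            [
                ("EX_A", {("A", "e"): -1}, 0, 0, "exchange"),
                ("T", {("A", "e"): -1, ("B", "c"): 1}, 2, 10, "transmembrane"),
                ("EX_B", {("B", "c"): -1}, 0, 10, "exchange"),
            ],
            [("A", "e"), ("B", "c")],
        )
        sol = fba(m, "EX_B")
        assert sol.status == "infeasible"
        assert sol.objective_value is None

    def test_unbounded_is_reported(self):
        m = small_model(
            [
                ("R1", {("A", "c"): 1}, float("-inf"), float("inf"), "sink"),
                ("R2", {("A", "c"): -1}, float("-inf"), float("inf"), "sink"),
            ],
            [("A", "c")],
        )
        sol = fba(m, "R2")
        assert sol.status == "unbounded"

    def test_unknown_objective_raises(self, chain_model):
        with pytest.raises(KeyError):
            fba(chain_model, "NOPE")

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_vertex_enumeration_oracle(self, seed):
        """FBA equals the brute-force basic-solution optimum on random
        chain/branch fixtures (the full 200-seed sweep runs in the
        acceptance suite)."""

        model, known, objective = random_lp_fixture(seed)
        sol = fba(model, objective)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(known, abs=1e-9)
        S, _, rxns = stoichiometric_matrix(model)
        lb = [model.reactions[r].lower_bound for r in rxns]
        ub = [model.reactions[r].upper_bound for r in rxns]
        c = [1.0 if r == objective else 0.0 for r in rxns]
        oracle = vertex_enumerate_optimum(S.toarray(), lb, ub, c)
        assert sol.objective_value == pytest.approx(oracle, abs=1e-9)


class TestFva:
    def test_unique_optimum_collapses_ranges(self, chain_model):
        ranges = fva(chain_model, "EX_B", fraction=1.0)
        for rid, fr in ranges.items():
            assert fr.min_flux == pytest.approx(fr.max_flux, abs=1e-7)
            assert fr.min_flux == pytest.approx(10.0 if rid != "EX_A" else -10.0, abs=1e-7)

    def test_parallel_branches_span_zero_to_optimum(self):
        m = small_model(
            [
                ("EX_A", {("A", "e"): -1}, -7, 0, "exchange"),
                ("RA", {("A", "e"): -1, ("B", "c"): 1}, 0, 1000, "cytosolic"),
                ("RB", {("A", "e"): -1, ("B", "c"): 1}, 0, 1000, "cytosolic"),
                ("EX_B", {("B", "c"): -1}, 0, 1000, "exchange"),
            ],
            [("A", "e"), ("B", "c")],
        )
        ranges = fva(m, "EX_B", fraction=1.0)
        for rid in ("RA", "RB"):
            assert ranges[rid].min_flux == pytest.approx(0.0, abs=1e-7)
            assert ranges[rid].max_flux == pytest.approx(7.0, abs=1e-7)
        assert ranges["EX_B"].min_flux == pytest.approx(7.0, abs=1e-7)

    def test_fba_flux_lies_inside_every_envelope(self, toy_adhe):
        model, medium = toy_adhe
        sol = fba(model, "EX_etoh", medium=medium)
        ranges = fva(model, "EX_etoh", fraction=0.9999, medium=medium)
        for rid, fr in ranges.items():
            assert fr.min_flux <= fr.max_flux + 1e-9
        assert (
            ranges["EX_etoh"].min_flux - 1e-6
            <= sol.objective_value
            <= ranges["EX_etoh"].max_flux + 1e-6
        )

    def test_infeasible_base_propagates_status(self):
        m = small_model(
            [
                ("EX_A", {("A", "e"): -1}, 0, 0, "exchange"),
                ("T", {("A", "e"): -1, ("B", "c"): 1}, 5, 10, "transmembrane"),
                ("EX_B", {("B", "c"): -1}, 0, 10, "exchange"),
            ],
            [("A", "e"), ("B", "c")],
        )
        result = fva(m, "EX_B", fraction=1.0)
        assert result.status == "infeasible"

    def test_bad_fraction_rejected(self, chain_model):
        with pytest.raises(ValueError):
            fva(chain_model, "EX_B", fraction=0.0)


class TestMoma:
    def test_identity_when_reference_feasible(self, toy_wt):
        model, medium = toy_wt
        ref = fba(model, "BIOMASS", medium=medium)
        sol = moma(model, ref.fluxes, medium=medium)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)
        assert sol.fluxes["BIOMASS"] == pytest.approx(ref.objective_value)

    def test_closed_form_projection_onto_remaining_branch(self):
        """Blocking one of two branches: the QP solution is the analytic
        projection of the reference onto the line R2 = EX_B = -EX_A."""

        m = small_model(
            [
                ("EX_A", {("A", "e"): -1}, -10, 0, "exchange"),
                ("R1", {("A", "e"): -1, ("B", "c"): 1}, 0, 10, "cytosolic"),
                ("R2", {("A", "e"): -1, ("B", "c"): 1}, 0, 10, "cytosolic"),
                ("EX_B", {("B", "c"): -1}, 0, 10, "exchange"),
            ],
            [("A", "e"), ("B", "c")],
        )
        reference = {"EX_A": -8.0, "R1": 5.0, "R2": 3.0, "EX_B": 8.0}
        edited = m.copy()
        edited.reactions["R1"].upper_bound = 0.0
        sol = moma(edited, reference)
        # minimize (0-5)^2 + (t-3)^2 + 2 (t-8)^2  ->  t = 19/3
        t = 19.0 / 3.0
        assert sol.optimal
        assert sol.fluxes["R2"] == pytest.approx(t, abs=1e-6)
        assert sol.fluxes["EX_B"] == pytest.approx(t, abs=1e-6)
        assert sol.objective_value == pytest.approx(25 + (t - 3) ** 2 + 2 * (t - 8) ** 2,
                                                    abs=1e-6)

    def test_distance_zero_iff_reference_feasible(self, toy_wt):
        model, medium = toy_wt
        ref = fba(model, "BIOMASS", medium=medium)
        from caldiflux.model import StrainDesign, apply_design

        edited = apply_design(model, StrainDesign(deleted_reactions=frozenset({"GLK"})))
        sol = moma(edited, ref.fluxes, medium=medium)
        assert sol.optimal
        assert sol.objective_value > 1e-3  # reference is no longer reachable

    def test_infeasible_edited_model_reported(self):
        m = small_model(
            [
                ("EX_A", {("A", "e"): -1}, 0, 0, "exchange"),
                ("T", {("A", "e"): -1, ("B", "c"): 1}, 5, 10, "transmembrane"),
                ("EX_B", {("B", "c"): -1}, 0, 10, "exchange"),
            ],
            [("A", "e"), ("B", "c")],
        )
        assert moma(m, {"EX_B": 1.0}).status == "infeasible"

    def test_linear_variant_agrees_on_sign_of_change(self):
        m = small_model(
            [
                ("EX_A", {("A", "e"): -1}, -10, 0, "exchange"),
                ("R1", {("A", "e"): -1, ("B", "c"): 1}, 0, 10, "cytosolic"),
                ("R2", {("A", "e"): -1, ("B", "c"): 1}, 0, 10, "cytosolic"),
                ("EX_B", {("B", "c"): -1}, 0, 10, "exchange"),
            ],
            [("A", "e"), ("B", "c")],
        )
        reference = {"EX_A": -8.0, "R1": 5.0, "R2": 3.0, "EX_B": 8.0}
        edited = m.copy()
        edited.reactions["R1"].upper_bound = 0.0
        sol = moma_linear(edited, reference)
        assert sol.optimal
        assert sol.fluxes["R1"] == pytest.approx(0.0, abs=1e-9)
        assert sol.fluxes["R2"] >= 3.0 - 1e-9


class TestCobraCrossCheck:
    """Independent cross-check: the same network solved by COBRApy/GLPK
    must give the same optima as this package's HiGHS-based engine."""

    @staticmethod
    def to_cobra(model, medium):
        import cobra

        cm = cobra.Model(model.name)
        applied = medium.apply(model) if medium is not None else model
        mets = {
            key: cobra.Metabolite(f"{cid}_{comp}", compartment=comp)
            for key, (cid, comp) in zip(applied.compounds, applied.compounds)
        }
        reactions = []
        for rid in applied.reaction_ids():
            rxn = applied.reactions[rid]
            cr = cobra.Reaction(rid)
            cr.lower_bound = rxn.lower_bound
            cr.upper_bound = rxn.upper_bound
            reactions.append((cr, {mets[k]: float(v) for k, v in rxn.stoichiometry.items()}))
        cm.add_reactions([cr for cr, _ in reactions])
        for cr, stoich in reactions:
            cr.add_metabolites(stoich)
        return cm

    @pytest.mark.parametrize("objective", ["BIOMASS", "EX_etoh"])
    def test_toy_optima_match(self, toy_adhe, objective):
        model, medium = toy_adhe
        ours = fba(model, objective, medium=medium)
        cm = self.to_cobra(model, medium)
        cm.objective = objective
        theirs = cm.optimize()
        assert theirs.status == "optimal"
        assert ours.objective_value == pytest.approx(theirs.objective_value, abs=1e-6)
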