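"""Shared fixtures: toy model variants and hand-built micro-networks."""

from __future__ import annotations

import sys
from fractions import Fraction
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from caldiflux.model import Compound, Model, Reaction
from caldiflux.toy import ToyOptions, build_toy, default_medium


@pytest.fixture(scope="session")
def toy_wt():
    """Wild-type toy model (no knock-ins, reversible BF-H2ase) + medium."""

    opt = ToyOptions()
    return build_toy(opt), default_medium(opt)


@pytest.fixture(scope="session")
def toy_adhe():
    """Toy with the AdhE knock-in (ethanol-capable), reversible BF-H2ase."""

    opt = ToyOptions(knockins=frozenset({"AdhE"}))
    return build_toy(opt), default_medium(opt)


@pytest.fixture(scope="session")
def toy_e1m_fwd():
    """E1M-like toy (AdhE + Rnf_Na), BF-H2ase H2-producing only."""

    opt = ToyOptions(knockins=frozenset({"AdhE", "Rnf_Na"}), bfh2ase_mode="forward_only")
    return build_toy(opt), default_medium(opt)


def make_chain_model():
    """EX_A(-10,0) -> A -> B -> EX_B: bottleneck is the uptake bound."""

    m = Model(name="chain")
    m.add_compound(Compound(id="A", compartment="e"))
    m.add_compound(Compound(id="A", compartment="c"))
    m.add_compound(Compound(id="B", compartment="c"))
    m.add_reaction(Reaction(id="EX_A", stoichiometry={("A", "e"): Fraction(-1)},
                            lower_bound=-10, upper_bound=0, kind="exchange"))
    m.add_reaction(Reaction(id="T", stoichiometry={("A", "e"): Fraction(-1), ("A", "c"): Fraction(1)},
                            lower_bound=0, upper_bound=1000, kind="transmembrane"))
    m.add_reaction(Reaction(id="R", stoichiometry={("A", "c"): Fraction(-1), ("B", "c"): Fraction(1)},
                            lower_bound=0, upper_bound=1000, kind="cytosolic"))
    m.add_reaction(Reaction(id="EX_B", stoichiometry={("B", "c"): Fraction(-1)},
                            lower_bound=0, upper_bound=1000, kind="exchange"))
    return m


@pytest.fixture()
def chain_model():
    return make_chain_model()


def make_two_pathway_model():
    """The 12-deletable-reaction two-pathway fixture (see tests/oracles.py).

    A -> Z via B (duplicated steps), via C, or via the B->C crosslink;
    a dead-end branch D -> E that no minimal network can use.  The demand
    is expressed through a biomass-like sink on Z.
    """

    m = Model(name="two-pathway", biomass_id="BIO")
    for cid, comp in [("A", "e"), ("A", "c"), ("B", "c"), ("C", "c"),
                      ("Z", "c"), ("D", "c"), ("E", "c")]:
        m.add_compound(Compound(id=cid, compartment=comp))

    def add(rid, st, lb=0.0, ub=1000.0, kind="cytosolic"):
        m.add_reaction(Reaction(
            id=rid, stoichiometry={k: Fraction(v) for k, v in st.items()},
            lower_bound=lb, upper_bound=ub, kind=kind))

    add("EX_A", {("A", "e"): -1}, lb=-10.0, ub=0.0, kind="exchange")
    add("T1", {("A", "e"): -1, ("A", "c"): 1}, kind="transmembrane")
    add("P1a", {("A", "c"): -1, ("B", "c"): 1})
    add("P1b", {("A", "c"): -1, ("B", "c"): 1})
    add("P2a", {("B", "c"): -1, ("Z", "c"): 1})
    add("P2b", {("B", "c"): -1, ("Z", "c"): 1})
    add("Q1", {("A", "c"): -1, ("C", "c"): 1})
    add("Q2a", {("C", "c"): -1, ("Z", "c"): 1})
    add("Q2b", {("C", "c"): -1, ("Z", "c"): 1})
    add("R1", {("B", "c"): -1, ("C", "c"): 1})
    add("D1", {("A", "c"): -1, ("D", "c"): 1})
    add("D2", {("D", "c"): -1, ("E", "c"): 1})
    add("X1", {("A", "c"): -1, ("E", "c"): 1})
    add("BIO", {("Z", "c"): -1}, kind="biomass")
    # E is a true dead end: reactions feeding it can never carry flux.
    return m


@pytest.fixture()
def two_pathway_model():
    return make_two_pathway_model()
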