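# caldiflux

Constraint-based metabolic modeling toolkit for strain design in
*Caldicellulosiruptor bescii*, the extremely thermophilic, cellulolytic
bacterium used as a consolidated-bioprocessing platform for converting
untreated plant biomass into ethanol and other bio-based chemicals.

`caldiflux` is written for metabolic modelers and engineers who want to ask
questions like: *what limits the ethanol yield of an AdhE-expressing
C. bescii strain, which redox functions are essential at maximum production,
and which knock-in would lift the ceiling?*  It provides:

* **Flux analysis** — flux balance analysis (FBA), flux variability analysis
  (FVA), and minimization of metabolic adjustment (MOMA) over stoichiometric
  models with gene–protein–reaction rules;
* **Model quality checks** — stoichiometric (mass) consistency, element and
  charge balance in exact rational arithmetic, and metabolite connectivity;
* **Minimal-network essentiality** — seeded random-order reaction pruning
  under biomass + product constraints, with core-essential / conditionally
  essential / nonessential classification and convergence diagnostics;
* **Strain design** — a knock-in catalog (AdhE, Rnf_Na, Rnf_H, Mrp, SH1,
  SH2), declarative knockout/knock-in designs, design-matrix evaluation, and
  production-envelope sweeps with carbon/electron conservation audits;
* **A synthetic core model** of *C. bescii* central carbon + redox
  metabolism (glycolysis with parallel NAD- and ferredoxin-dependent
  branches, POR, the MBH / BF-H2ase / BF-Nfn redox triad, ATP synthase,
  fermentative sinks) that is fully element- and charge-balanced, so every
  predicted yield can be checked by hand.

## The model

A metabolic network with stoichiometric matrix **S** (metabolites ×
reactions) is simulated at steady state under flux bounds:

```
maximize    c · v
subject to  S v = 0,   lb ≤ v ≤ ub
```

where the objective *c* selects biomass or a product exchange flux.  FVA
reports `[min v_j, max v_j]` for each reaction subject to the objective
staying at ≥ γ of its optimum (γ = 0.9999 for "maximum" constraints, to
absorb LP tolerance).  MOMA predicts mutant behavior as the flux vector of
the edited network closest to the wild-type reference in squared Euclidean
distance — a quadratic program solved here with SLSQP over an
SVD-reduced equality system.

A *minimal network* is a reaction subset from which no single deletable
reaction can be removed without violating the imposed constraints (biomass
flux ≥ threshold; ethanol production fixed at 0, ≥ 50%, or ≥ 99.99% of its
maximum).  Replicates with seeded random pruning orders are classified by
occurrence: reactions in **all** minimal networks are core-essential, in
**some** conditionally essential, in **none** nonessential.

The redox bookkeeping that governs ethanol yield: glucose carries 24
electron equivalents; each ethanol exports 12.  The yield ceiling of 2
mol/mol is reached only if the reduced ferredoxin made by POR (and GOR) can
be converted into NADH for AdhE — either by running the bifurcating
hydrogenase in reverse on MBH-produced H2, by an Rnf (proton-pumping, or
sodium-pumping plus the Mrp antiporter), or by the SH2 hydrogenase.  With a
strictly H2-producing BF-H2ase and no knock-in, NADH comes only from GAPDH
and the yield ceiling drops to 1 mol/mol.

## Worked example

```python
from caldiflux import ToyOptions, build_toy, default_medium, max_product

# AdhE knock-in, bifurcating hydrogenase restricted to H2 production
opt = ToyOptions(knockins=frozenset({"AdhE"}), bfh2ase_mode="forward_only")
model = build_toy(opt)
medium = default_medium(opt)

res = max_product(model, "EX_etoh", medium=medium, substrate_exchange="EX_glc")
print(f"max ethanol flux : {res.product_flux:.2f} mmol/gDW/h")
print(f"molar yield      : {res.yield_mol_per_mol:.2f} mol ethanol / mol glucose")
print(f"at 72.8 mM sugar : {res.millimolar(72.8):.1f} mM ethanol")
```

prints

```
max ethanol flux : 10.00 mmol/gDW/h
molar yield      : 1.00 mol ethanol / mol glucose
at 72.8 mM sugar : 72.8 mM ethanol
```

— with glucose uptake capped at 10 mmol/gDW/h, every glucose yields one
ethanol: the two GAPDH-derived NADH feed AdhE, while the two reduced
ferredoxins must leave as H2.  Swapping in a proton-pumping Rnf
(`knockins={"AdhE", "Rnf_H"}`) recovers those electrons and doubles the
yield:

```
with Rnf_H       : 2.00 mol/mol -> 145.6 mM
```

The same studies are scriptable from the shell:

```sh
caldiflux toy --knockin AdhE --out toy.yaml        # emit the model (YAML)
caldiflux check --toy --knockin AdhE               # quality checks
caldiflux sparse --toy --knockin AdhE --level max --n 200 --seed 7
caldiflux design --toy --bfh2ase-mode forward_only # the design matrix
caldiflux envelope --toy --knockin AdhE --product EX_etoh --steps 100
```

Each command writes TSV artifacts plus a JSON manifest (inputs, seeds,
versions) to the output directory.

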