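# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of `caldiflux`.

## Stoichiometric models

A model is a catalog of compartmentalized compounds (`c` cytosol, `e`
extracellular) and reactions with signed rational stoichiometry, flux
bounds, and boolean gene associations.  Coefficients are stored as exact
`Fraction`s so that the element/charge balance checks and the conservation
audits are exact; they are converted to floats only when an LP is built.
Periplasmic ion pools (translocated H+, Na+) are modeled as
extracellular-compartment species, since the membrane reactions only
distinguish inside from outside.

Bounds default to (−B, +B) for reversible and (0, +B) for irreversible
reactions with B = 1000 mmol·gDW⁻¹·h⁻¹, the common convention for
genome-scale models; explicit `limits` entries override this.  Gene
deletions zero a reaction's bounds rather than removing it, so FVA/MOMA
reports keep a stable reaction index across designs.  The `reversible`
direction override restores the (−B, +B) catalog default, undoing earlier
clamps.

## LP/QP machinery

All linear programs are solved with SciPy's HiGHS backend under fixed
lexicographic row/column ordering; repeated runs give bit-stable objective
values.  Tolerances: steady-state equality at 1e−9, flux comparisons at
1e−6.  Degenerate optima are expected; only objective values are treated as
reproducible, and flux-vector claims are made through FVA envelopes.
"Maximum production" constraints use a fraction of 0.9999 rather than 1.0
to absorb solver tolerance.

MOMA minimizes Σ(v − v_ref)² subject to the edited model's constraints.
The raw mass-balance system contains linearly dependent rows (conserved
moieties), which breaks SLSQP's least-squares subproblem, so the equality
block is first replaced by an orthogonal full-rank equivalent obtained from
its SVD.  The solver is warm-started from an L1-closest feasible point
(itself one LP); if SLSQP fails to converge the slower `trust-constr` path
is used, and the feasible warm start is the last-resort answer.  An L1
(pure-LP) MOMA variant is provided for callers that prefer a solver-free
objective.

## Model quality checks

Four checks mirror standard reconstruction curation:

* **Stoichiometric consistency** — a model is consistent iff every compound
  can be assigned a strictly positive molecular mass m with Sᵀm = 0 over
  the internal (non-exchange, non-biomass, non-sink) reactions.  The
  reported percentage is the maximal consistent compound fraction from one
  LP (maximize Σz with z ≤ m, z ≤ 1, m ≥ ε).
* **Formula / charge balance** — exact rational comparison of substrate and
  product element (and charge) totals per internal reaction.  Reactions
  touching compounds with missing or generic (R/X-group) formulas are
  excluded and reported with the reason, never flagged; the exclusion
  applies to both checks, matching how such reactions are inspected
  manually during curation.
* **Connectivity** — compounds participating in no reaction.

These percentages are the checks' own definitions; they are not claimed to
equal any external scoring tool's aggregate score.

## Minimal-network analysis

`find_minimal_network` visits the deletable reactions in a seeded uniform
random permutation, tentatively zeroing each and keeping the deletion iff
the constraints (biomass ≥ threshold; ethanol fixed at 0, or ≥ level ×
maximum) stay feasible — one feasibility LP per tentative deletion.  The
result is 1-minimal by construction: a retained reaction was infeasible to
remove against a subset of the final blocked set, hence also against the
final set.  The deletable universe excludes exchange, biomass, and sink
pseudo-reactions, so medium design is never conflated with network
essentiality.  Levels: "none" pins production to exactly zero; "half" and
"max" are lower bounds at 50% and 99.99% of the (biomass-constrained)
maximum.

Replicate seeds derive from one base seed by increment and are recorded in
the result for audit.  Classification is plain set algebra over replicate
retention; convergence is declared when all three class sizes are unchanged
over a trailing window (default 100 of 1000 replicates).  The studies in
this repository use n = 150–200 replicates with a window of 50 — a
deliberate sizing for a core model of ~55 reactions, where the convergence
diagnostic confirms the classification stabilizes well before the window —
and the sampler itself is validated exactly against exhaustive enumeration
on a 12-reaction fixture.

The biomass floor used in the studies (0.05 flux units, ≈5% of the toy's
maximum growth) stands in for the published batch-yield constraint
(0.41 g DW/liter); mapping a batch yield into a steady-state flux requires
a substrate-consumption basis that is a configuration input, not a model
constant.

## Strain designs

A `StrainDesign` is a set of gene deletions, reaction deletions, knock-in
insertions (with any new species), and directionality overrides.  The
knock-in catalog fixes explicit stoichiometry with ferredoxin as a
two-electron couple (one Fd_red ≡ 2 e⁻, carried by a fixed Fe8S8 core whose
charge changes on reduction) — published models differ on this convention,
so it is stated prominently.  Ion translocation stoichiometries are not
published for this organism's reconstruction and are configuration values:
MBH pumps 1 H+ per H2, ATP synthase translocates 3 H+ per ATP, Rnf moves 1
ion per Fd_red.  The acceptance-level yield properties are verified robust
across 1–4 H+/ATP and across pump stoichiometries because they are
electron-limited, not ATP-limited.

The sodium pool is closed (no Na+ exchange), so Rnf_Na can carry
steady-state flux only when Mrp provides the Na+ return path — the
"missing sodium gradient" behavior emerges from mass balance rather than
from an ad hoc constraint.

Design-matrix rows are solved under one shared medium with the BF-H2ase
directionality applied uniformly; production envelopes fix the product flux
at s/steps × maximum for s = 0..steps and report min/max flux for a watch
list of reactions.  Carbon and degree-of-reduction audits (γ = 4C + H − 2O
− 3N + 5P + 6S − charge) sum boundary fluxes, counting the biomass
reaction's net elemental consumption as fixed into biomass; both residuals
are ~1e−13 on every optimal design solution.

## The synthetic core model

`build_toy` emits a ~50-compound / ~55-reaction network embodying the
organism's central-carbon + redox architecture: lumped upper glycolysis,
GAPDH/PGK (PGK accepting ADP or GDP, one gene) in parallel with the
ferredoxin-dependent GOR bypass, PK and PPDK, GTP-forming PCK, LDH and MDH
sharing one gene, POR, PTA/AckA, an NADH-neutral acetoin drain, MBH,
BF-H2ase, BF-Nfn (modeled reversible so that SH1's NADPH can re-enter the
NADH/ferredoxin pool), ATP synthase, nucleotide housekeeping, and
exchanges/transports for glucose, cellobiose, cellulose (as anhydroglucose
units with extracellular hydrolysis), the fermentation products, NH4+,
phosphate, water, and uracil.

Choices worth stating:

* **Every non-boundary reaction balances exactly** (elements and charge),
  including proton chemistry.  The cytosolic proton pool has a reversible
  sink representing buffering; the periplasmic pool h[e] has none, so
  proton-motive force arises only from the pumps (MBH, Rnf, Mrp) and is
  consumed only by ATP synthase.
* **Pyrimidine branch**: a lumped de novo uracil synthesis
  (oaa + 2 NH4+ → uracil + 3 H2O, gene `g_pyrE`) plus uracil
  transport/exchange make the ΔpyrE background representable as a true
  uracil auxotroph with salvage — viable exactly when the medium supplies
  uracil.  The lump is stoichiometrically exact but deliberately ignores
  the pathway's ATP and redox costs, which are negligible at the biomass
  coefficient used.
* **Biomass** consumes 1 each of G6P, PEP, pyruvate, acetyl-CoA, OAA and
  uracil, 30 ATP, and 6 NADPH per unit — small integers chosen for
  hand-checkable bookkeeping, configuration-exposed, with growth verified
  robust across a ±50% sweep.
* The toy is **not** a reduction of the published reconstruction; it is an
  independent didactic network whose stoichiometry is printed in the source
  so that all derived yields can be verified by hand (2.0 mol/mol ceilings,
  the 1.0 forward-only ceiling, the MBH:reverse-BF-H2ase 2:1 recycle ratio
  solving m = 2b, 2 + b = 2b).

### What the toy does and does not show

Passing the desk-scale suite shows the algorithms are correct and that the
qualitative redox logic of the organism (which knock-in lifts which
ceiling, which deletions are lethal, which functions become core-essential
under ethanol demand) is reproduced.  It does **not** reproduce the
published mM concentrations or class sizes of the 714-reaction
reconstruction — those depend on the full network (amino acid and
pyrimidine side fluxes, the malate shunt, ion stoichiometries) and on its
supplementary data set.  Two specific known gaps:

* In the full reconstruction, MDH feeds an NADPH→NADH malate shunt (via an
  NADP-linked malic enzyme), which is why an *ldh* deletion — which also
  removes MDH activity — lowers the ethanol ceiling there.  The toy omits
  the shunt deliberately: including it would raise the forward-only
  no-knock-in ceiling from the hand-derivable 1.0 mol/mol to 2.0 and
  destroy the teaching value of the yield table.  Consequently Δldh equals
  its parent strain for maximum ethanol in the toy; the Δldh phenotype is
  instead exercised through MOMA (lactate flux → 0, carbon redirected to
  acetate/pyruvate) after product-ratio calibration.
* Single deletions of BF-Nfn abolish growth in the toy (it is the only
  NADPH source); in the full network other NADPH routes exist.  The triple
  redox deletion (MBH + BF-H2ase + BF-Nfn) is lethal in both.

## Validation stage

Growth/no-growth phenotypes swap the sole carbon source against a basal
medium, closing all other carbon exchanges; growth means biomass flux above
1e−6 (the LP noise floor).  A substrate without an exchange reaction is
recorded as predicted no-growth with a flag.  Unit conversions: cell counts
× 8.2e−10 mg/cell; protein-to-dry-weight by ordinary least squares over
calibration pairs (the fitted slope/intercept are inputs, not constants).
Product-ratio calibration pins each measured product's secretion flux to a
molar fraction of the total over the product universe (all secretion-only
carbon exchanges except CO2, determined under the applied medium);
fractions must be positive and sum to ≤ 1, and the couplings are added as
side constraints rather than edits to the network, so removing the
calibration exactly restores the unconstrained model.  The cellulose-load
comparison is represented by scaling the glucose-equivalent uptake bound by
the observed solubilized fraction, supplied as an input; no solubilization
kinetics are modeled.

## Problem sizes

The test suite and the acceptance script run entirely on generated inputs:
200 random ≤6-reaction LP fixtures against a brute-force vertex enumerator;
500 seeded prunings against exhaustive (2¹²) enumeration on the two-pathway
fixture; 150 minimal-network replicates per ethanol level on the core model
(window 50); an 18-row design matrix; 100-step envelopes where sweeps are
exercised.  The full run takes about a minute on one CPU.
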