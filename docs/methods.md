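# Methods

## Scope and model class

`diazogem` implements the constraint-based (M-model) analysis pipeline
for an aerobic diazotroph: model representation and I/O, flux balance
analysis (FBA), reconstruction quality control, homology-driven GPR
curation and gap-filling, biomass-objective construction, Biolog-style
phenotype screening with confusion statistics, elemental carbon/nitrogen
flux partitioning, and alginate/PHB production analysis.

An M-model is a stoichiometric matrix **S** (metabolites × reactions)
with flux bounds `lb ≤ v ≤ ub` (mmol/gDW/h) and boolean
gene-protein-reaction (GPR) associations. FBA solves

    max c·v   s.t.   S v = 0,  lb ≤ v ≤ ub

where `c` indicates a single objective reaction; when that reaction is a
biomass objective function (BOF) the optimum is the growth rate μ (1/h).
All LPs go through scipy's HiGHS interface. HiGHS is deterministic, so
every result in this package is reproducible run-to-run on the same
platform.

### Numerical choices

* Solver feasibility/optimality tolerance `1e-9`; reporting tolerance
  `1e-6` (steady-state residual, blocked-reaction calls, optimum
  comparisons).
* "Unconstrained" bounds are capped at ±1000 mmol/gDW/h, the usual COBRA
  convention; infinite bounds are clamped to the cap before solving.
* FBA optima are degenerate. Wherever a single flux vector is reported
  (partitioning, flux maps, energy-cycle support) parsimonious FBA
  (pFBA) is used: the objective is pinned at its optimum (relative slack
  `1e-9`) and total absolute flux Σ|v| is minimized via flux splitting.
  This is a deterministic tie-break, not a thermodynamic claim.
* Exchange convention: negative flux = uptake. Experimental uptake
  rates, reported as positive magnitudes, are stored as negative lower
  bounds.

## Model I/O

Two dialects are supported with full semantic round-tripping
(stoichiometry, bounds, formulas, charges, GPR trees, subsystems,
provenance tags, active objective):

* SBML Level 3 Version 1 with the FBC v2 package, through libsbml.
  GPR trees serialize as FBC gene-product associations; provenance and
  subsystem ride in reaction notes. Written files pass libsbml's
  consistency check with zero errors. One caveat: libsbml prints
  doubles with ~15 significant digits, so a first write→read is
  identical only to `1e-12` relative on stoichiometric coefficients
  (subsequent cycles are exact).
* A cobra-style JSON dialect, chosen so fixtures are hand-writable and
  diffable; files load unchanged in cobrapy.

Identifiers follow BiGG conventions with compartment suffixes `_c`
(cytoplasm), `_p` (periplasm), `_e` (extracellular space).

## Quality control

* **Mass/charge balance.** For each internal reaction,
  `imbalance(e) = Σ_i s_i · atoms_e(i)` per element plus the analogous
  net charge; balanced means every term is exactly zero. Boundary
  pseudo-reactions and biomass reactions are inherently unbalanced and
  are skipped (listed separately); a reaction with a formula-less
  participant is flagged `unauditable`, never silently passed.
  Imbalances confined to H (with or without charge) carry a `minor`
  flag, since proton bookkeeping across membranes is a common benign
  cause.
* **Energy-generating cycles.** With every exchange and sink closed
  (bounds (0,0)), a dissipation reaction for the currency couple is
  temporarily added and maximized: `atp + h2o → adp + pi + h` for ATP and
  `nad(p)h → nad(p) + h` (electrons implicit) for the nicotinamide
  couples. These are the community-standard probe forms; a closed model
  must dissipate nothing (≤ 1e-6). The probe is maximized
  parsimoniously so the reported cycle support is minimal and names the
  offending reactions directly.
* **GPR logic.** Deletion screens close every reaction whose GPR
  evaluates inactive for the knockout set and re-run FBA. An empty GPR
  (orphan reaction) is always active.

## Curation and gap-filling

Homology hits (BLAST outfmt-6 style TSV) are accepted when identity ≥
40%, e-value ≤ 1e-4 and query coverage ≥ 85%, all thresholds inclusive;
coverage follows BLAST `qcovs` (query-length) semantics. Best-hit
selection for GPR remapping ranks by lowest e-value, then highest
identity, then lexicographic subject id. Remapping policy for partially
mapped enzyme complexes is `strict` by default — an unmapped AND leaf
invalidates the whole branch, so a complex is never asserted with a
missing subunit — with `permissive` (drop the leaf only) available.
GPRs that empty out are flagged exogenous-only; such reactions are
pruned only when additionally blocked under *every* supplied condition,
and the pruner verifies that no condition optimum moved by more than
1e-6 relative. Native and orphan reactions are never pruned.

Dead ends are classified structurally (produced-only, consumed-only,
disconnected) with reversibility expansion; a metabolite touched by a
single reversible reaction is not a dead end but is flagged
`single-reaction`.

Gap-filling searches for a smallest set of pool reactions lifting the
objective above the growth threshold 0.001 1/h (the same strict
threshold used for growth calls). Pools of ≤ 12 reactions are searched
exhaustively by increasing subset size with a lexicographic tie-break,
so the result is provably minimal and deterministic; larger pools use
add-all-then-greedy-deletion, which still guarantees deletion
minimality. Parsimony (smallest set) was chosen as the objective;
likelihood-weighted gap-filling is out of scope.

## Biomass objective

Amino-acid coefficients come from proteome composition: residues are
pooled across proteins with each protein weighted equally (the
"theoretical abundance in the genome" reading — no expression
weighting), and

    coeff_a = 1000 · P · f_a / Σ_b f_b · m_b     [mmol/gDW]

with `P` the protein mass fraction of dry biomass (default 0.55 g/gDW),
`f_a` molar fractions and `m_b` *residue* (dehydrated) average masses —
free amino acid minus one water (18.02 g/mol) — because polymerized
protein is what the mass fraction refers to. By construction
Σ coeff·m = 1000·P mg/gDW (mass closure, asserted to 1e-6 g/gDW).
Non-protein constituents and the ATP/GTP polymerization cost pass
through unchanged from a template BOF; no nucleotide/lipid estimation is
attempted.

A second, alginate-augmented BOF adds consumption of the periplasmic
alginate monomer at a configurable coefficient, coupling polymer
synthesis to growth. No published value exists for this coefficient;
the toy model uses 0.5 mmol/gDW (≈ 88 mg mannuronate per gDW, ~9% of
dry mass — moderate for an organism whose polymer content spans tens of
percent under producing conditions). Exactly one BOF is active per
simulation.

## Phenotype screens and statistics

Carbon screens open one source at a time at a default uptake bound of
10 mmol/gDW/h (per-plate configurable; the study estimated bounds from
experimental conditions without printing them) on a mineral base medium
(exchanges of metabolites containing neither C nor N stay open).
Nitrogen is supplied as ammonium (non-diazotrophic) or as N2 with
ammonium closed (diazotrophic) — the two regimes are exclusive.
Nitrogen screens fix pyruvate as the sole carbon source and vary the
nitrogen source. Sources without an exchange reaction are excluded with
reason code `not-in-model` and never enter the statistics.

A condition grows when μ > 0.001 1/h, strictly. Against experimental
calls the panel reports accuracy, sensitivity, specificity, PPV, NPV
and the Matthews correlation coefficient from the standard formulas;
any 0/0 ratio is reported as null, never as 0. Summary percentages are
rounded half-away-from-zero to integers. Percent error against paired
experimental growth rates is `|pred − exp| / exp × 100` (pairs with
exp = 0 excluded with a flag).

Note: for the 38-source validation counts (TP=20, FP=0, TN=16, FN=2)
the MCC formula gives ≈ 0.90. A printed value of 0.67 circulating for
this panel is arithmetically inconsistent with its own counts; the
package always reports the formula value.

## Partitioning and production

Element throughput of a reaction at flux v is `|v| · Σ_products s_i ·
atoms_e(i)` — defined on the product side, which equals the substrate
side for balanced reactions (asserted in tests); boundary reactions
with no product side fall back to the substrate side. Per-subsystem
values are arithmetic means over member reactions including zero-flux
members (the literal "average flux per subsystem"); an active-only mean
is available via flag. Transport and exchange subsystems are computed
but flagged excluded from headline summaries. Diazotrophic and
non-diazotrophic condition tables are compared per subsystem with
Pearson r over the paired condition vectors (r > 0.9 flags a conserved
distribution; r is null for constant vectors) plus a global percent
change of summed throughput.

Production analysis: storage polymers (PHB) get an irreversible sink
`SK_<met>` (bounds 0–1000); secreted polymers (alginate) couple to
growth through the augmented BOF. `production_rate` maximizes growth,
fixes it at a chosen fraction of the optimum, then maximizes product
flux (parsimoniously). Flux maps are normalized so an anchor uptake
(glucose) maps to ±100 before per-reaction percent-error comparison
against reference fluxomic maps, with agreement at ≤ 20% error.
Alginate is modeled as its mannuronate monomer (polymer length is not
resolved), so production rates are per-monomer mmol.

## The synthetic toy diazotroph

The generators exist so the whole pipeline runs end-to-end with known
ground truth and no external data. The toy model has 47 reactions, 47
metabolites, 35 genes in three compartments: glucose/fructose/pyruvate
uptake; lumped glycolysis and Entner–Doudoroff routes (with their
correct differential ATP/NADPH yields); lumped TCA cycle, pyruvate
carboxylase and citrate-synthase→isocitrate-dehydrogenase steps; a
lumped respiratory chain at P/O = 2; the canonical Mo-nitrogenase
equation N2 + 8 H⁺ + 8 e⁻ + 16 ATP → 2 NH₃ + H₂ + 16 ADP + 16 Pi with
electrons carried by a lumped one-electron ferredoxin couple reduced
from NADH; net GS/GOGAT ammonium assimilation into a lumped amino-acid
pool (glutamate); a six-reaction alginate branch (isomerase,
phosphomannomutase, GDP-mannose pyrophosphorylase, GDP-mannose
6-dehydrogenase, polymerase/epimerase with periplasmic export,
secretion) and a three-reaction PHB branch (β-ketothiolase,
acetoacetyl-CoA reductase, synthase on a monomer basis); an ATP
maintenance reaction; and two biomass functions (base, and
alginate-augmented at 0.5 mmol/gDW) built through the package's own
biomass constructor with the 55% protein rule applied to the lumped
amino-acid pool.

Every internal reaction is element- and charge-balanced with real
formulas and charges, so the QC suite is green on the defect-free model
by construction, and injected defects are detectable: `unbalanced` (a
water→H₂ typo) trips only the mass-balance audit, `atp_cycle` (costless
ADP + Pi + H⁺ → ATP + H₂O) trips only the ATP energy-cycle check, and
`orphan_metabolite` trips only the dead-end scan.

Plates connect exactly `n_growers` of `n_sources` to the network
(hexose isomers funneled to glucose for carbon; alanine-like substrates
deaminated to pyruvate + ammonium for nitrogen); negatives are declared
metabolites with an exchange but no inward route, emulating
present-but-unusable compounds rather than absent ones. Proteomes are
multinomial samples of a target composition; homology tables stratify
all eight accept/reject combinations of the three curation thresholds
and always include the exact-boundary row (40.0, 1e-4, 85.0). All
generators are pure functions of their arguments and seed (byte-identical
reruns).

### What the toy does and does not show

The toy is a structural stand-in, not a reduced real reconstruction.
Directional findings transfer — diazotrophic growth is strictly cheaper
in ATP terms and therefore slower than ammonium growth for every carbon
source; growth-coupled alginate production is higher on ammonium;
nitrogen-metabolism subsystems decorrelate between the two regimes
while core carbon subsystems correlate near 1 — but absolute magnitudes
(growth rates around 2 1/h at 10 mmol/gDW/h glucose, subsystem
throughputs) are properties of the toy's lumped stoichiometry and do
not reproduce any organism-scale value. Reproducing published absolute
subsystem fluxes or genome-scale growth rates would require the full
published reconstruction and its mineral-medium constraints, which are
deliberately out of scope; the statistics and comparison machinery is
exercised on the published confusion counts and growth-rate pairs
directly, which are pure-arithmetic inputs.

## Problem sizes

Default test and acceptance runs use the 47-reaction toy, 12-well
plates, proteomes of ~50×300 residues, 25-row hit tables, and 20 random
≤ 12-reaction LPs for the solver cross-check against cobrapy (an
independent codebase and solver, used only as an oracle). These sizes
keep the whole suite in seconds while every code path, including the
exhaustive gap-fill search, is exercised.

## Known limitations

* No thermodynamic (loopless) constraints, ΔG feasibility, kinetic
  laws, MILP/quadratic objectives, or FVA beyond the blocked-reaction
  test.
* No transcriptional or enzyme-level regulation — growth predictions
  are purely stoichiometric optima.
* Sequence alignment itself is out of scope; homology hits are consumed
  as precomputed tables.
* The SBML reader targets FBC v2 constraint-based models only (no
  kinetic SBML, no MAT files).
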