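# diazogem

Constraint-based metabolic modeling toolkit for aerobic diazotrophs —
organisms such as *Azotobacter* that fix atmospheric N₂ with the
ATP-hungry nitrogenase complex while secreting alginate and storing
polyhydroxybutyrate (PHB). The package is aimed at systems biologists
building or validating genome-scale metabolic models (M-models) of such
organisms: it covers model I/O, growth simulation, reconstruction
quality control, curation, biomass construction, phenotype-array
validation and carbon/nitrogen flux partitioning, and ships a fully
synthetic toy diazotroph so every analysis runs end-to-end with no
downloads.

## What it computes

At its core is flux balance analysis: for a stoichiometric matrix **S**,
flux bounds and an objective reaction,

```
max c·v    s.t.    S v = 0,    lb ≤ v ≤ ub
```

solved with HiGHS (deterministic), plus parsimonious FBA (fix the
optimum, minimize Σ|v|) to obtain unique flux distributions. Around that
core:

* **core_model / io** — typed model structures (metabolites with
  formulas and charges, reactions with GPR boolean trees and provenance
  tags, media) with round-tripping SBML L3-FBC and cobra-style JSON
  readers/writers.
* **qc** — element/charge balance audit; closed-exchange ATP/NADH/NADPH
  energy-cycle detection via dissipation probes; GPR evaluation and
  gene-deletion screens.
* **reconstruction** — homology-hit filtering at ≥40% identity,
  ≤1e-4 e-value, ≥85% coverage (inclusive); GPR remapping with a strict
  complex policy; exogenous-reaction pruning that provably preserves
  condition optima; dead-end classification; smallest-set gap-filling
  (exhaustive for pools ≤ 12).
* **biomass** — biomass objective construction from proteome amino-acid
  abundance with the 55%-protein mass rule and exact mass closure, plus
  an alginate-augmented second biomass function.
* **screen** — Biolog-style PM1/PM2 (carbon) and PM3 (nitrogen) plate
  simulation under diazotrophic/non-diazotrophic regimes, strict
  μ > 0.001 1/h growth calls, and the full confusion panel (accuracy,
  sensitivity, specificity, PPV, NPV, MCC).
* **partition** — per-subsystem carbon/nitrogen throughput of
  parsimonious flux states, diazotrophic vs non-diazotrophic Pearson
  correlation, sink reactions, growth-coupled production rates, and
  normalized flux-map comparison (anchor uptake = 100, 20% error
  threshold).
* **synth** — deterministic generators: the 47-reaction toy diazotroph
  (every internal reaction element- and charge-balanced; optional
  injected defects for QC negative tests), phenotype plates with ground
  truth, proteomes of known composition, homology tables spanning all
  threshold combinations.

See `docs/methods.md` for the models, conventions and design choices.

## Worked example

```python
import diazogem as dz
from diazogem.synth import make_toy_diazotroph, toy_medium

model, manifest = make_toy_diazotroph()

mu_nh4 = dz.fba(dz.apply_medium(model, toy_medium())).objective_value
mu_n2 = dz.fba(dz.apply_medium(model, toy_medium(diazotrophic=True))).objective_value
print(f"growth on glucose: ammonium {mu_nh4:.4f} 1/h, N2 {mu_n2:.4f} 1/h")

stats = dz.confusion_stats(dz.ConfusionCounts(TP=20, FP=0, TN=16, FN=2))
print(f"accuracy {stats.accuracy:.3f}  PPV {stats.ppv:.3f}  "
      f"NPV {stats.npv:.3f}  MCC {stats.mcc:.4f}")
```

prints

```
growth on glucose: ammonium 2.0662 1/h, N2 1.5003 1/h
accuracy 0.947  PPV 1.000  NPV 0.889  MCC 0.8989
```

Growth is slower on N₂ because nitrogenase spends 16 ATP (plus 8
low-potential electrons) per N₂ reduced; the confusion panel shows a
38-condition carbon screen with 20 true positives, 16 true negatives
and 2 false negatives scoring 95% accuracy, 100% positive and 89%
negative predictive value. The same machinery runs from the shell:

```
diazogem synth toy --out toy.json
diazogem model summarize toy.json
diazogem qc toy.json
diazogem fba toy.json --parsimonious
```

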