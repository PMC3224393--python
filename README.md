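# egfr-erk

Kinetic modeling of EGFR–ERK signal transduction in H1299 non-small-cell
lung cancer cell-line variants, for systems biologists studying how receptor
abnormalities reshape drug response. The package asks a concrete question:
why does the gefitinib-sensitive EGFR L858R mutant suppress ERK activation
under receptor inhibition so much more strongly than cells overexpressing
wild-type EGFR, even though the two lines respond almost identically at the
receptor itself?

## The model

The core is a deterministic ODE model of the canonical EGFR→Ras→Raf→MEK→ERK
pathway: 27 reaction steps over 29 components (27 dynamic states plus the
constant phosphatase pools PP2A and MKP3). Receptor-proximal events — EGF
binding, dimerization, autophosphorylation, and recruitment of Cbl, GAP,
Shc and Grb2/SOS — follow mass-action kinetics; receptor and ShcP
dephosphorylation (steps 4, 11) and the entire Ras/Raf/MEK/ERK cascade
(steps 15–27) follow Michaelis–Menten kinetics. Extracellular EGF acts as
an undepleted ligand bath; Cbl-bound phosphodimers are degraded into an
audited sink. Concentrations are in nM, time in minutes.

Four cell-line variants share one parameter vector:

| variant   | description |
|-----------|-------------|
| `WT`      | parental H1299: low endogenous EGFR |
| `EGFR_WT` | wild-type EGFR overexpression: raised EGFR initial concentration |
| `L858R_A` | L858R + endogenous Mig6: EGFR raised, rate constants k3, k5, k7, k8 slowed (Mig6 blocks the active kinase domain and its couplings) |
| `L858R_B` | L858R + enhanced Cbl: EGFR and Cbl raised, parameters unchanged |

Gefitinib is a multiplicative factor α ∈ (0, 1] on the receptor
autophosphorylation constant k3. Three analyses are built on this:

- **Sensitivity-ratio indices.** With R_X = X(α = 0.0005) / X(α = 1)
  measured at t = 5 min under 10 nM EGF, the ratio R_Shc/R_ERK quantifies
  how much more strongly receptor inhibition registers at ERK than at Shc.
  Grids of this index over pairs of Mig6-affected parameters, and of
  R_complex/R_Y for downstream readouts Y, locate the amplifying steps.
- **Synergy classification.** Given solo k3 and k8 factors that each
  produce X/2 % ERKPP inhibition, the combined perturbation is additive,
  antagonistic or synergistic according to whether it yields exactly, less
  than, or more than X %.
- **Parameter estimation.** A real-coded genetic algorithm (log-space,
  tournament selection, blend crossover, Nelder–Mead elite polish,
  archive-based diversity control) minimizes the summed squared error
  between normalized simulated and measured phospho values at
  t ∈ {1, 5, 10, 30} min, decomposed into an upstream stage (steps 1–17 vs
  pEGFR/pShc) solved before the downstream stage (steps 18–27 vs
  pMEK/pERK). A synthetic pseudo-western-blot generator with known ground
  truth makes the whole pipeline testable end to end.

## Worked example

```python
from egfr_erk import (reference_variants, alpha_scan, r_index,
                      PerturbationSpec, classify_combination)
from egfr_erk.network import DEFAULT_VARIANT_SETTINGS

variants = reference_variants()
for name in ("EGFR_WT", "L858R_A"):
    scan = alpha_scan(variants[name], (1.0, 0.1, 0.01))
    print(name, {p: [float(round(v, 3)) for v in vals]
                 for p, vals in scan.items()})

mult = DEFAULT_VARIANT_SETTINGS["L858R_A"]["multipliers"]
ctx_a = PerturbationSpec(multipliers=mult)
idx_a = r_index("pShc", context=ctx_a) / r_index("pERK", context=ctx_a)
idx_w = r_index("pShc") / r_index("pERK")
print(f"R_Shc/R_ERK  EGFR-WT: {idx_w:.3f}   L858R model A: {idx_a:.3e}")

result = classify_combination(X_grid=(0, 10, 50))
for row in result.rows:
    print(f"X={row.X:>4.0f}%  k3 x{row.k3_factor:.3g}  k8 x{row.k8_factor:.3g}"
          f" -> combined {row.combined_inhibition:.1f}%  ({row.classification})")
```

prints

```
EGFR_WT {'pEGFR': [1.0, 0.254, 0.03], 'pShc': [1.0, 0.224, 0.026], 'pMEK': [1.0, 1.0, 0.883], 'pERK': [1.0, 1.0, 0.983]}
L858R_A {'pEGFR': [1.0, 0.116, 0.012], 'pShc': [1.0, 0.113, 0.011], 'pMEK': [1.0, 0.137, 0.011], 'pERK': [1.0, 0.026, 0.0]}
R_Shc/R_ERK  EGFR-WT: 6.474   L858R model A: 2.381e+07
X=   0%  k3 x1  k8 x1 -> combined 0.0%  (additive)
X=  10%  k3 x0.00801  k8 x0.0179 -> combined 100.0%  (synergistic)
X=  50%  k3 x0.0059  k8 x0.0132 -> combined 100.0%  (synergistic)
```

Reading the numbers: each α-scan row is the t = 5 min response normalized
to the no-drug value at α = 1, 0.1, 0.01. Upstream (pEGFR, pShc) the two
lines respond to gefitinib almost identically, but at ERK the
EGFR-overexpressing model barely notices a 100-fold k3 reduction (0.983)
while the Mig6-carrying L858R model collapses (0.026 already at α = 0.1) —
the Mig6-slowed rate constants strip away the cascade's saturation reserve,
so inhibition that is invisible downstream in EGFR-WT switches ERK off in
L858R. The index ratio makes the same point in one number, and the synergy
table shows that pairing the two k3/k8-reducing perturbations (Mig6 effect
and gefitinib) overshoots the additive expectation at every tested
intensity.

A command-line surface mirrors the library: `egfr-erk simulate|fit|perturb|
synergy|synth|export-sbml`, each writing tidy CSV plus a JSON manifest.
Models round-trip through declarative YAML (`egfr_erk.io.save_model`) and
SBML L3V2 (`export-sbml`).

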