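# Methods

## Model structure

The network tracks EGF-driven signaling from receptor to ERK through 27
numbered reaction steps over 29 components. The 27 dynamic states are: EGF,
EGFR, the EGF/EGFR complex (Ra), the unphosphorylated and phosphorylated
homodimers (E11, E11P), Cbl and E11P/Cbl, the degradation sink, GAP and
E11P/GAP, Shc, E11P/Shc, E11P/ShcP, free ShcP, Grb2/SOS, E11P/ShcP/Grb2/SOS,
ShcP/Grb2/SOS, RasGDP/RasGTP, Raf1/Raf1A, MEK/MEKP/MEKPP and
ERK/ERKP/ERKPP. PP2A and MKP3 are the two constitutively constant
components; they never change and enter only as catalysts of MEK and ERK
dephosphorylation, which is how the component count reaches 29 while the
ODE system stays at 27 equations.

Step assignments: (1) EGF binding, (2) dimerization, (3)
autophosphorylation, (4) receptor dephosphorylation (MM), (5) Cbl binding,
(6) internalization/degradation, (7) GAP binding, (8) Shc binding, (9) Shc
phosphorylation on the receptor, (10) ShcP release, (11) cytosolic ShcP
dephosphorylation (MM), (12) Grb2/SOS recruitment, (13) release of
ShcP/Grb2/SOS, (14) its dissociation, (15) SOS-catalyzed Ras exchange (MM,
E11P/ShcP/Grb2/SOS as catalyst), (16) Ras deactivation catalyzed by
receptor-bound GAP (MM), (17) basal Ras GTPase activity (MM), (18/19) Raf1
activation by RasGTP and deactivation, (20–23) dual MEK
phosphorylation/dephosphorylation by Raf1A/PP2A, (24–27) dual ERK
phosphorylation/dephosphorylation by MEKPP/MKP3. Michaelis–Menten kinetics
applies to exactly steps 4, 11 and 15–27; all other steps are mass action.

Three structural choices were genuinely open and are resolved as follows.
Step 11 is modeled as MM dephosphorylation of free ShcP (not a complex
dissociation). Steps 16/17 are split into a GAP-catalyzed route (16, using
the E11P/GAP complex as catalyst, which ties Ras shutdown to receptor
occupancy) and a basal route (17), so loss of the receptor still lets Ras
relax. PP2A and MKP3 are explicit constant species rather than folded
Vmax constants, which makes the MEK/ERK phosphatase capacity visible and
tunable.

### The EGF bath

Stimulation doses (0.1–10 nM) are far below the per-cell-volume receptor
concentrations (up to 700 nM); if binding consumed EGF stoichiometrically,
the ligand would be depleted within a minute and dose–response structure
would be an artifact of reservoir size. Physically the extracellular medium
holds vastly more EGF molecules than one cell's receptors, so EGF enters
step 1 as a forward-rate multiplier (a modifier) and is not consumed: its
ODE is identically zero. This is the standard ligand-bath approximation.
Consequence: the EGF "pool" is trivially conserved, and the mass-action
contract "kf times the product of reactants" acquires one documented
exception in step 1.

### Degradation bookkeeping

Step 6 transfers the Cbl-bound phosphodimer into a terminal sink species
(and recycles Cbl). Receptor mass is therefore auditable: monomer
equivalents (EGFR and Ra weight 1, every dimer-containing species and the
sink weight 2) are conserved along every trajectory, while the free
receptor pool itself correctly is not. All other moiety pools (Shc,
Grb2/SOS, Ras, Raf1, MEK, ERK, Cbl, GAP) are closed; the test suite checks
each pool's indicator vector against the stoichiometry matrix and its
constancy (≤ 1e-6 relative) along simulated trajectories.

### Observables

Densitometry maps to species sums: pEGFR counts every species containing a
phosphorylated dimer, each dimer once (`DIMER_OBSERVABLE_WEIGHT` switches
to per-receptor-equivalent counting); pShc counts free plus complexed ShcP;
the phospho-MEK antibody (Ser217/221) sees MEKP + MEKPP; the phospho-ERK
antibody sees doubly phosphorylated ERK only. Panels are normalized the way
blot panels are quantified: per protein, each series' t = 0 value is
subtracted, then all series of the panel are divided jointly by the panel
maximum, so exactly one series reaches 1. α-scan panels are instead
normalized per curve to the no-drug (α = 1) value.

## Parameters

No externally fitted constants exist for these cell-line models, so the
reference `ParameterSet` was constructed by the package itself: receptor-
block values descend from the classic short-term EGFR signaling model and
MAPK-block values from the canonical MAPK-cascade model, rescaled to
nM/min, then adjusted once, by hand, until the four-variant family
reproduces the qualitative behaviors the analyses rest on — EGFR-WT
attaining the panel maxima with the pEGFR peak at 10 min, the L858R models
intermediate, gefitinib sensitivity amplified downstream in the Mig6 model
A but not in the Cbl model B, and k3&k8 synergy. Search bounds span ±2
decades around each reference value. Two regimes matter more than any
individual constant:

- **Near-linear receptor dephosphorylation** (Km4 = 1000 nM, above the
  E11P working range): phospho-receptor and phospho-Shc then respond to the
  gefitinib factor α nearly proportionally in every variant, reproducing
  the observation that the cell lines are hard to distinguish upstream.
- **A deeply saturated cascade** (kinase capacity an order of magnitude
  above phosphatase capacity at each of the Raf, MEK and ERK stages): the
  EGFR-WT model then carries a large multiplicative "saturation reserve",
  so ERK output ignores upstream inhibition until α is very small. The
  Mig6 multipliers (k3 ×0.15, k5 ×0.45, k7 ×0.45, k8 ×0.12) spend that
  reserve, moving model A near the cascade threshold where the same α
  collapses ERK. This regime is what makes R_Shc/R_ERK for model A many
  orders of magnitude above EGFR-WT's (the deeply inhibited ERKPP value
  underlying the model-A index is of order 1e-9 nM, so the index's
  magnitude is sensitive to the cascade-bottom kinetics; the robust,
  tested statement is the ≥ 5-fold separation between the variants, not
  the index's absolute size).

Variant settings: EGFR initial concentration 90 nM (WT) vs 700 nM
(overexpressing lines); model B raises Cbl 5-fold. Initial adaptor/kinase
pools (Shc 150, Grb2/SOS 40, Ras 120, Raf1 100, MEK 120, ERK 300, Cbl 85,
GAP 70, PP2A 11, MKP3 2.4 nM) are shared by all lines, matching the
blot-level observation that only EGFR (and, for model B, Cbl) differ.

## Numerics

`solve_ivp` with LSODA (BDF available) integrates the stiff system at
rtol 1e-8, atol 1e-12; the tight atol resolves the deeply inhibited states
(≪ 1 nM) that the R indices divide by. The right-hand side is generated
once per parameter set as unrolled source code and compiled; a naive
per-reaction interpreter of the same rate laws serves as an independent
cross-check in the tests, alongside a finite-difference check of dense
trajectories. Concentrations are clamped at zero inside rate evaluations
so solver undershoot cannot produce spurious negative fluxes; states are
asserted non-negative to solver tolerance. Estimation and synthetic-data
simulations run at rtol 1e-6 for speed.

Inhibition inversion bisects on log10(factor) over [1e-6, 1] to 0.05
percentage points, after verifying the bracket is monotone (a non-monotone
bracket raises an error carrying a diagnostic scan). The additive-class
tolerance ε defaults to 0.5 percentage points; classifications are checked
for stability over ε ∈ [0.25, 1.0].

## Estimation

The objective is the summed squared error over cell lines, proteins and
t ∈ {1, 5, 10, 30} min between normalized data and the candidate's
normalized simulation (the candidate is renormalized per panel, exactly as
the data were). Failed integrations score a large finite penalty (1e6) so
GA ranking survives. The problem decomposes by network topology: nothing
downstream of step 17 feeds back upstream, so receptor-block parameters
(steps 1–17, plus variant settings) are fitted first against pEGFR/pShc,
then cascade parameters (steps 18–27) against pMEK/pERK with the upstream
winners frozen.

The minimizer is a documented genetic algorithm rather than a reimplementation
of any specific historical code: real-coded on log10 parameters, binary
tournament selection, BLX-0.5 blend crossover, per-gene Gaussian mutation
(σ = 0.3 decades), elitism, periodic Nelder–Mead polish of the incumbent,
and diversity maintenance that rejects offspring falling within a fixed
normalized radius of any archived generation-best, regardless of coordinate
scaling. Every knob sits in `GAConfig`; a fixed seed makes results
bit-reproducible, and the reported objective is always re-derivable from
the residual table.

## Synthetic data

The generator emulates the blot tables end to end: simulate each cell line
× dose at the ground-truth parameters on the experimental grid
{0, 1, 5, 10, 30, 120, 360} min, apply multiplicative log-normal noise
(σ = 0.1 by default — densitometry noise scales with band intensity; bands
below a 1e-4 nM floor stay exact so t = 0 remains zero), average the two
replicates, and normalize per protein across cell lines at fixed dose.
Defaults mirror the emulated experimental design: three cell lines (WT,
EGFR-WT, L858R-A), doses {0.1, 1, 10} nM, duplicate replicates.

What it does not emulate: biological variation between passages, antibody
cross-reactivity or blot saturation, and loading-control error — so
passing recovery tests demonstrate that the estimation machinery works on
data of the assumed noise structure, not that the model is identifiable
from real blots.

The recovery harness fits a deliberately small, influential free set
(k3, k8, V4 upstream; kcat20, kcat24 downstream) over all generated doses —
single-dose fits admit dose-specific compensations (e.g. k3 against V4)
that fail to generalize across doses, which is why all doses enter the
objective by default. Desk-scale problem sizes (population 14, 8
generations per stage, ≈ 250 objective evaluations of 9 simulations each)
recover ground-truth normalized trajectories to RMSE ≈ 0.002 per observable
noiselessly and ≈ 0.01–0.03 at 5% noise; individual parameters may still
drift along compensation directions (k3/V4), which is expected
non-identifiability — trajectory recovery is the contract.

## Interfaces

The network round-trips losslessly through a declarative YAML model file,
so an externally supplied reaction table can replace the built-in reference
without code changes; `network_diff` reports structural and parameter
differences between any two networks (e.g. the built-in model vs an
imported SBML document). SBML L3V2 export writes species (boundary
condition for the EGF bath and the phosphatases), global parameters, and
reactions with explicit MathML kinetic laws; the importer recognizes this
model family's two law shapes and reproduces simulations to machine
precision. Measurement tables are plain CSV (UTF-8, header, '.' decimal),
validated with line-number diagnostics.

## Known limitations

- Single well-mixed compartment; no receptor trafficking beyond the one
  degradation step; no stochastic simulation.
- Gefitinib is a constant k3 multiplier for the whole run; the 20-minute
  drug pre-incubation is not modeled separately because the unstimulated
  state is stationary, and no pharmacokinetic mapping from molar drug dose
  to α is attempted.
- The reference parameters are a reconstruction calibrated to qualitative
  behaviors, not a fit to the original densitometry; quantities that
  depend on the cascade's deep-off values (absolute index magnitudes)
  should be read as regime indicators, not measurements.
- Mig6 and Cbl act only through the four rate multipliers and the raised
  Cbl pool, respectively; neither protein is an explicit species.
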