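# Methods

`refloat` analyses specular neutron reflectometry (NR) of *free-floating
bilayers* (FFBs): planar lipid membranes held a few nanometres to tens of
nanometres away from a carboxyl-terminated oligo(ethylene-glycol)
alkanethiol monolayer (COOH-OEG-SAM) on gold, with solution on both
sides.  The headline observable is the **bilayer-to-SAM distance** — the
thickness of the water interlayer between the SAM/water interface and the
proximal bilayer head-group layer — and how it responds to the solution
salt sequence CaCl₂ → EDTA → NaCl → CaCl₂.

## Forward model

The interfacial structure is an ordered stack

    silicon | SiO2 | permalloy | gold | SAM | water interlayer |
    inner head groups | tails | outer head groups | bulk solvent

Specular reflectivity R(Q) is computed exactly for a stack of homogeneous
slabs by the optical-matrix (Abeles/Parratt) method, with the momentum
transfer Q = 4π sin θ / λ.  The permalloy layer is treated as a single
non-magnetic slab (no polarised-beam analysis) and all SLDs are real —
absorption in these materials is negligible at cold-neutron wavelengths.

**Molecular constraints.**  Organic layers are parametrised at the
molecule level rather than as free (thickness, SLD) pairs:

* thickness = V / A, with V the molecular (fragment) volume and A the
  area per molecule;
* SLD ρ = Σb / V, with Σb the summed coherent scattering length.

Head and tail layers of a leaflet share one area per molecule, fixing the
head:tail molar ratio at 1:1 (they belong to the same molecule) and
halving the number of free parameters.  Head-group layers carry an
explicit bound-water count (volume- and Σb-additive); any fraction of a
layer not occupied by molecules is defect-associated solvent, so the
layer SLD is coverage-weighted between molecular and solvent values.
Solvent-exchangeable hydrogens take the solvent's H/D composition with
Δb = 10.41 fm per exchanged hydrogen.  Fragment volumes and scattering
lengths ship as an editable JSON table
(`src/refloat/data/lipid_components.json`) with standard literature
values; they are configuration, not code.  Solvent SLDs are the adopted
constants D₂O = 6.35, H₂O = −0.56 (×10⁻⁶ Å⁻²); gold-matched water (AuMW)
is their 75:25 volume mix, 4.62.

**Roughness by micro-slicing.**  Interfacial roughness is an
error-function profile of width σ attached to each interface.  The
Nevot–Croce damping factor exp(−2 k k′ σ²) is implemented as an oracle,
but it fails when σ approaches the layer thickness — exactly the regime
of an EDTA-released bilayer (σ up to ~125 Å on a water gap of a few
hundred Å).  The fitting path therefore renders the continuous SLD
profile as many thin sharp slabs (midpoint sampling over the interfaces
± 4 σ_max) and feeds those to the matrix kernel.

Two numerical refinements keep this both accurate and affordable:

* *Staircase compensation.*  Midpoint slicing of a smooth profile leaves
  a relative bias of −(Q w)²/12 at slab width w (measured, with the
  expected exact 4× reduction on halving w).  Each micro-interface is
  therefore given a small anti-damping exponent +2 k k′ w²/12 (w capped
  at 4 Å so near-zero-contrast plateau interfaces cannot amplify).  With
  the compensation, halving the default 0.5 Å width changes R by < 10⁻⁵
  relative for every fixture structure — the slicing is converged.
* *Roughness-adaptive widths.*  Slab widths scale as max(floor, σ/12)
  near each interface and plateaus become single slabs, which agrees
  with uniform 0.5 Å slicing to < 2×10⁻³ relative while cutting the
  slab count by ~5× for large-roughness structures.  The data generator
  uses uniform 0.5 Å slicing (the reference path); fits default to the
  adaptive path.

**Resolution.**  Instrument smearing is a Gaussian in Q of constant
fractional width dQ/Q = 3.5% (FWHM convention), evaluated per output
point by fixed 17-point Gauss–Hermite quadrature with the model computed
exactly at the quadrature nodes.  The generator and the fit use the same
rule, so the smearing approximation cancels in recovery studies.

## Co-refinement

All datasets of a sample — three solvent contrasts (D₂O, H₂O, AuMW) per
membrane condition, two per SAM-only control — are fitted against one
parameter vector.  Parameter sharing is by object identity: structures
holding the same `Parameter` instance are constrained together.  The
standard layout shares the substrate + SAM block across every condition
and frees only the membrane position, roughness, area per molecule and
coverage per condition.  Each dataset carries multiplicative scale and
additive background nuisances (defaults 0.8–1.2 and 0–10⁻⁵ when freed).

The likelihood is Gaussian in the reported point uncertainties,
log L = −χ²/2 with χ² = Σ ((scale·R_model + background − R_obs)/dR)².
Point estimation uses bounded differential evolution with an L-BFGS-B
polish (deterministic per seed).  Uncertainties come from a Delayed
Rejection Adaptive Metropolis (DRAM) chain started at the optimum:
Gaussian proposals whose covariance adapts to the running chain
covariance (Haario scaling 2.38²/d, jitter fallback on degeneracy), one
delayed-rejection stage retrying each rejected move with the proposal
shrunk by γ = 0.2, hard parameter bounds.  The default chain length is
5×10⁴ steps with the first 30% discarded as burn-in; the recovery
workflows in this repository use shorter chains (see below).  Marginal
summaries report the distribution maximum (128-bin histogram smoothed by
a 2-bin Gaussian kernel, ties broken toward the median) and the shortest
interval containing 95% of the samples; effective sample sizes come from
the initial-positive-sequence autocorrelation.

## Synthetic data

The generator emulates the measurement design: log-spaced Q grids of 120
points over 0.008–0.3 Å⁻¹ at dQ/Q = 3.5%, a constant incoherent
background of 5×10⁻⁷, and heteroscedastic noise with
dR = max(0.02·R, 5×10⁻⁷) — a fractional floor where the signal dominates
and an absolute floor at the background.  Noise is Gaussian with the
quoted dR, so simulated z-scores are standard normal by construction.
Fixture scenarios pin the water-gap thickness and conformal bilayer
roughness at the resolved values for each lipid composition and salt
condition (distances 10–594 Å, roughnesses 3–125 Å), spanning the regime
where roughness rivals the gap thickness and micro-slicing is essential.
Substrate defaults (SiO₂ 12 Å, permalloy 150 Å, gold 120 Å, SAM ≈ 21 Å)
are plausible configuration values, not measured ones.

What the generator does *not* emulate: true counting statistics of a
time-of-flight instrument, footprint and detector artefacts, per-point
resolution variation, scale drifts between contrasts, and any
imperfection of the molecular model itself (the fit model and the
generator share one parametrisation).  Passing recovery tests therefore
demonstrates the estimator's internal consistency — unbiased recovery
and calibrated credible intervals under the stated noise — not the
absence of model error on real data.

## Problem sizes used by the tests and the acceptance script

Simulate-and-refit exercises are scaled to a desktop run as a deliberate
choice of problem size:

* `scripts/acceptance.py`: the POPC initial-CaCl₂ and EDTA cells at the
  default 120-point grid, distance/roughness/area/coverage free,
  differential evolution (popsize 8, ≤ 15 generations) plus a 1 500-step
  DRAM chain.
* the acceptance test suite: condition-cell recoveries on 60-point log
  grids with distance and roughness free (500-step chains, 7-point
  quadrature on both the generator and the fit so the smearing operator
  cancels); twenty replicate fits of the POPC/EDTA cell for the coverage
  check on a 60-point *linear* grid over 0.01–0.10 Å⁻¹, which samples
  the low-Q Kiessig fringes of the released bilayer at the Nyquist rate
  (coarse log grids alias those fringes and bias the recovered
  distance); and optimiser-only fits on 40-point grids for the
  salt-sequence ordering.

Because the distance likelihood is fringe-multimodal over the broad
(1, 650) Å refinement bounds, the global-search budgets err on the large
side (differential-evolution populations of 20–30); the workflow
defaults do the same.

Shorter chains widen the Monte-Carlo error of the interval endpoints
slightly; the coverage criterion (truth inside the shortest 95% CI in
≥ 85% of replicates) already allows for that slack.

## Auxiliary analyses

* **Boltzmann inversion**: ΔG(z) = −R T ln(n(z)/N₀), R = 8.314462
  J mol⁻¹ K⁻¹, default T = 308 K; N₀ is the mean density beyond 40 Å
  from the surface.  Zero-density bins map to +∞ rather than raising, so
  profiles with excluded regions remain processable; enrichment gives
  negative ΔG and reports also quote the positive well depth |ΔG_min|.
* **Order parameter**: S = (3 cos²θ − 1)/2 for the chain tilt θ from the
  surface normal, with the inverse on the [0°, 90°] branch; S crosses
  zero at the magic angle 54.74°.
* **Sauerbrey mass**: Δm = −C·Δf/n per overtone n; the mass sensitivity
  C (17.7 ng cm⁻² Hz⁻¹ for a 5 MHz crystal) must be configured
  explicitly.

## Known limitations

* The deposited experimental datasets are not bundled; the
  deposited-data check needs them under `data/zenodo-4434613/`.
* The SAM is a single slab (NR resolves it as one ~21 Å layer); no
  head/tail split, no charge regulation or electrostatic prediction of
  the equilibrium distance.
* Both leaflets share one area per molecule by default
  (`decouple_leaflets=True` relaxes this); bound-water counts default to
  fixed values rather than being fitted.
* The 17-point fixed-order quadrature is a smearing approximation shared
  by generator and fit; against a brute-force convolution it differs at
  the few-percent level near the critical edge, which matters only when
  comparing against externally smeared data.
* Reflectivity is specular only: no off-specular scattering, polarised
  beams, energy-dispersive or footprint corrections.
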