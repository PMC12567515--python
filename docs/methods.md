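# Methods

This note records the physical model behind `celldose`, where each parameter
comes from, the numerical choices, what the synthetic-data generators do and
do not emulate, and the known limitations.

## 1. Reactions and constants

### ¹⁰B(n,α)⁷Li thermal capture

Two channels, treated as a capture at rest followed by a two-body breakup:

| branch | probability | charged kinetic release | products |
| --- | --- | --- | --- |
| excited ⁷Li* | 0.94 | 2.31 MeV | α 1.47 MeV, ⁷Li 0.84 MeV, + 0.48 MeV photon |
| ground ⁷Li | 0.06 | 2.79 MeV | α 1.78 MeV, ⁷Li 1.01 MeV |

Product energies follow from non-relativistic momentum balance,
`E_a = Q · m_b / (m_a + m_b)`, with integer mass numbers 4 and 7 — the error
relative to exact atomic masses is far below the two-decimal precision at
which these energies are quoted.  The 0.48 MeV photon energy is derived as
the inter-channel release difference, which the code checks for consistency.

Thermal (2200 m/s) capture cross sections: σ(¹⁰B) = 3837 b,
σ(¹⁴N(n,p)) = 1.83 b with a 0.626 MeV proton.  Natural-boron isotopic
fractions: f(¹⁰B) = 0.199, f(¹¹B) = 0.801.

### p + ¹¹B → 3α fusion

The resonance near 675 keV is represented by a single effective cross section
σ_R = 1 barn.  The fusion yield per incident proton is the thin-target
expression Y = σ_R · n_B, valid because even a solid-boron target a few µm
thick has n_B ≈ 10⁻⁵ atoms/barn, so beam attenuation by the reaction itself
is negligible.  Each fusion releases three alphas; they are modelled as
mono-energetic at 3 MeV (the ~8.7 MeV Q-value splits unevenly and
continuously among the three alphas; 3 MeV is the mean and the shell doses,
dominated by geometric solid angle rather than spectral detail, are
insensitive to the split at the ~µm scoring distances).

### Areal densities

For the solid-inclusion mode, n_B uses the mean chord of a sphere,
`⟨ℓ⟩ = 4r/3` (2 µm for r = 1.5 µm), with boron density 2.37 g/cm³ and the
natural ¹¹B fraction: n_B = 2.115 × 10⁻⁵ atoms/barn.  Combined with the
geometric hit probability π r² / A_field for a 70 × 70 µm² field and 2 × 10⁸
protons (2 × 10⁷ p/s for 10 s), the expected alpha count is ≈18.3.  The
dissolved mode instead uses a mass concentration (ppm of natural boron in
water) times a traversal path, defaulting to the 25 µm cell diameter.

## 2. Cell geometry

Concentric spheres centred at the origin:

- boron inclusion, r = 1.5 µm (water-equivalent density by default; optional
  solid boron at 2.37 g/cm³ for mass bookkeeping),
- ten scoring shells of 10 nm thickness wrapping the inclusion
  (1.5–1.6 µm),
- nucleus, r = 5 µm,
- cell, r = 12.5 µm,

all water otherwise.  This is a classical single-cell dosimetry idealization
(MIRD-style); the experimental situation it abstracts is an adherent
monolayer, which is closer to a slab than a sphere — see Limitations.

Ray tracing computes exact chord segments against every sphere boundary; a
point at exactly radius R is assigned to the inner region, and segment
classification probes an interior point of each segment (not the midpoint,
which for a tangent chord lies exactly on the touching sphere).

## 3. Stopping power, ranges, degrader

Proton electronic stopping uses the Bethe formula with the shell-free
logarithm, I(water) = 75 eV, and the standard K = 0.307075 MeV·cm²/mol.
Below a 0.5 MeV proton-equivalent junction the Bethe expression is replaced
by a power law matched in value and logarithmic slope at the junction, giving
a continuous, monotone S(E) down to the 1 keV tracking cutoff.  Alpha
stopping uses equal-velocity proton scaling multiplied by the Barkas
effective-charge factor z_eff = 2·(1 − exp(−125 β / 2^{2/3}))².  Supported
kinetic energies: 1 keV – 20 MeV.

This S(E) is an analytic model, not a tabulation: it reproduces the shape
and magnitude of reference proton stopping in water to within a few percent
over the MeV range, which is adequate for ratio-type conclusions; absolute
doses inherit that few-percent model error.

CSDA ranges integrate 1/S(E) with adaptive quadrature (relative tolerance
1e-6).  Transport uses a pre-built log–log range table (4000 points) with an
inverse lookup so energy updates are exact range inversions — energy is
conserved per history to better than 1e-9 relative by construction.

Beam degraders are slab stacks (Mylar, air, water); transported energy is
computed by CSDA range subtraction per slab, and `tune_degrader` solves the
free slab thickness by bracketing + Brent root finding to hit a target mean
energy (2.0 MeV through 25 µm Mylar plus ≈2.66 cm air → 675 keV).  Optional
Gaussian energy straggling uses the Bohr variance
σ² = 0.1569 · z² · (Z/A) · ξ (MeV², ξ in g/cm²), appropriate for the thick,
many-collision degraders considered.

## 4. Monte Carlo transport

Condensed-history with straight tracks:

- step length limited by (a) the distance to the next region boundary plus a
  1e-7 µm nudge, and (b) the path over which at most 1% of the current
  energy is lost (via the range table);
- deposits scored to the region containing the step, using `np.add.at` over
  vectorized history batches;
- particles are killed at 1 keV, depositing the residual locally;
- batch statistics: the run is split into independent batches with RNG
  streams `default_rng([seed, batch])`; the reported uncertainty is the
  standard error of the per-batch means.  Results are bitwise reproducible
  for a fixed seed and batch count.

Beam fields: `point` (axis), `square` (uniform raster of side L), `broad`
(uniform over the cell bounding square).  To control the variance of the
nm-shell tallies under a 70 µm field, position sampling is stratified: a
configurable fraction of histories is drawn from the small disk covering the
shell stack, with area-proportional weights keeping all tallies unbiased.

The engine is verified against: the analytic thin-slab dose D = Φ·S/ρ
(within 1%), quadrature CSDA track lengths (0.5%), exact energy balance,
a −1/2 convergence slope of the batch error versus history count, and
distributional tests on the isotropic source.

### Two-step PBFT pipeline

Resonance fusion cross sections cannot be sampled inside a CSDA code, so the
enhancement is computed in two decoupled steps: (1) transport the degraded
proton beam and score shell doses D_p(k); (2) replace the inclusion with an
isotropic 3 MeV alpha emitter, uniform in the sphere volume, with total
statistical weight equal to the expected alpha count, giving D_α(k).  The
enhancement ratio (D_p + D_α)/D_p uses the expectation rather than a sampled
Poisson count — the reported ratio is the mean enhancement, and its standard
error combines the baseline error twice (baseline appears in numerator and
denominator of the comparison) with the alpha-tally error:
SE = sqrt(2·(ratio·r_p)² + ((D_α/D_p)·r_α)²).

At the reference parameters the ratios are 1 + O(10⁻⁴) with percent-level
errors in every shell — statistically indistinguishable from 1.

### Default problem sizes

40 000 proton histories and 20 000 alpha histories in 10 batches are package
defaults chosen so a full two-step run completes in seconds on one core while
keeping every shell's relative error under ~2.5%; they are configuration
values, not physical constants, and scale as 1/√N.

## 5. BNCT kerma model

Charged-particle equilibrium at the cellular scale justifies a kerma
approximation: D_i = (atoms_i/g) · σ_i · Φ · E_i · 1.602 × 10⁻¹³ J/MeV ×
10³ g/kg.  Components: ¹⁰B (release weighted over branches,
0.94·2.31 + 0.06·2.79 MeV), ¹⁴N (3.5 wt% nitrogen, 0.626 MeV), plus
user-supplied hydrogen-recoil and background-photon doses (fast-neutron and
photon fields are facility-specific and not modelled from first principles).
The 0.48 MeV capture photon is treated with a thin-sample escape model
(µ_en/ρ = 0.0325 cm²/g at 478 keV): for sub-mm cultures its locally
deposited dose is below 1% of the boron component and is excluded from the
table.

Uptake conversion: B ng per 10⁶ cells × 10⁸ cells/cm³ packing → µg/g,
times f(¹⁰B) = 0.199 for a natural-abundance compound
(100 ng/10⁶ cells → 1.99 ppm ¹⁰B).

## 6. Bioanalysis conventions

- Fold changes report the raw ratio and a two-significant-figure value with
  half-away-from-zero rounding (matching how such ratios are conventionally
  quoted, e.g. 250/150 → 1.7, 430/200 → 2.2).
- The B:Fe mass ratio for an 18-boron, one-iron anion is
  18 × 10.811 / 55.845 = 3.4845; measured per-compartment ratios are
  compared against it.
- IC50 fitting uses a four-parameter logistic parameterized in log(IC50)
  (curve_fit with bounds); a Spearman pre-check rejects non-decreasing
  viability data before fitting, and the CI is a t-interval on log(IC50).
  Coverage of the 95% interval is verified ≥90% over hundreds of simulated
  plates at both default truth scales.
- Clonogenic survival normalizes colony counts by seeded cells times control
  plating efficiency; values above 1 are flagged, not silently clipped.

## 7. Synthetic-data generators

The generators produce every table the analysis stages consume, with the
ground truth returned alongside, so round-trip tests never need external
data.  Realism choices:

- multiplicative lognormal noise (mean-preserving,
  σ² = ln(1 + cv²)) for concentrations, viabilities and %ID/g — assay noise
  at these scales is ratio-like, not additive;
- Poisson noise for colony counts (genuinely counting statistics);
- Gaussian pixel noise for elemental maps over a disk-in-disk (cytoplasm /
  nucleus) phantom;
- biodistribution as mono-exponential organ clearance; default organ
  parameters contrast a slowly clearing tumour with a fast-clearing liver;
- default truth values (IC50 83.5 and 103 µM for the two cell-line scales,
  compartment iron levels 250/430 vs 150/200 µg/g, 150 ng B per 10⁶ cells
  uptake, 7.5 mg B/kg dosing) sit at the magnitudes typical of published
  metallacarborane uptake and toxicity studies, so analyzer tolerances are
  exercised in a realistic regime.

What they deliberately do not emulate: plate-position effects, detector
drift, inter-batch calibration error, correlated replicate noise, or
multi-compartment pharmacokinetics.

## 8. Numerical choices (summary)

| choice | value | rationale |
| --- | --- | --- |
| tracking cutoff | 1 keV | below any µm-scale range of interest; residual deposited locally |
| max fractional energy loss per step | 1% | keeps S(E) quasi-constant per step; boundaries always honoured exactly |
| boundary nudge | 1e-7 µm | breaks ties after a crossing; far below shell thickness |
| range-table size | 4000 log-spaced points | interpolation error ≪ the 0.5% CSDA acceptance bound |
| quadrature tolerance | 1e-6 relative | range oracle accuracy |
| batches | 10 (default) | stable SEM estimates without fragmenting the sample |
| RNG | PCG64 via `default_rng([seed, batch])` | independent, reproducible streams |

## 9. Limitations

- **Straight-track CSDA transport**: no multiple Coulomb scattering, no
  nuclear elastic/inelastic interactions, no delta-ray transport, no energy
  straggling inside the cell (only optionally at the degrader).  Lateral
  spread of a 675 keV proton over 25 µm is small but not zero; absolute
  nm-shell doses are therefore approximate, while ratios of doses scored in
  the same geometry are much less sensitive.
- **Sphere vs monolayer**: the concentric-sphere cell is an idealization of
  an adherent monolayer.  A 675 keV proton has a ~12 µm residual range in
  water, so in the 25 µm sphere it stops inside the cell and the depth–dose
  gradient makes compartment doses geometry-dependent; compartment-equality
  checks are therefore performed in the shoot-through regime where the model
  is gradient-free, and the degraded-beam configuration is used only for the
  shell-enhancement question it was designed for.
- **Single effective fusion cross section**: the 1 barn resonance value with
  a mono-energetic entrance spectrum replaces an energy-dependent σ(E)
  folded over the slowing-down spectrum; the yield is therefore an
  order-of-magnitude-faithful estimate, which is sufficient given the
  ~10⁻⁴ enhancement it produces.
- **Mono-energetic 3 MeV alphas** replace the continuous 3-body spectrum.
- **BNCT kerma approximation**: no explicit transport of capture products;
  sub-cellular boron microdistribution (whole-cell vs nuclear loading) is
  not resolved in the tissue-level dose table.
- **Analytic stopping power**: a few-percent accuracy envelope versus
  reference tabulations, stated above; no shell, Barkas-correction or
  density-effect terms for protons.
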