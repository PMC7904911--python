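# Methods

## Scope and model overview

The package models a 96-well cancer-cell plate to which ⁹⁰Y resin
microspheres have been added, as used to study beta-radiation effects under
normoxia (~19% O₂), physioxia (5%) and hypoxia (1%).  It has four layers:

1. **Source term** — the ⁹⁰Y beta spectrum and decay kinetics;
2. **Transport** — condensed-history electron transport in water scoring
   absorbed dose on a voxel grid over the microscope field of view (FOV);
3. **Dose bookkeeping** — the per-sphere common dose factor, well-level
   accumulated doses and the 10/70 Gy binning;
4. **Plate emulation and statistics** — a synthetic generator for per-well
   sphere counts and viability readouts, and the non-parametric statistics
   applied to them.

## Beta spectrum

⁹⁰Y → ⁹⁰Zr is a first-forbidden unique transition.  The tabulated density
on a 1 keV grid from 1 keV to the 2.27 MeV endpoint is

n(E) ∝ F₀(Z, W) · p W q² · C(W) · (1 + α/2π · g(W, W₀)),   C(W) = q² + λ₂ p²

with W, p the electron total energy and momentum, q = W₀ − W the neutrino
momentum (mₑ = c = 1), Z = 40 the daughter atomic number.  F₀ is the
relativistic point-Coulomb Fermi function with the (2pR)^(2γ−2) finite-size
factor (R = 1.2 A^(1/3) fm), λ₂ = F₁/F₀ is the generalized-Fermi
Coulomb-amplitude ratio normalized to its Z = 0 limit, and g is Sirlin's
order-α outer radiative correction.

The λ₂ ratio matters: with λ₂ ≡ 1 the quadrature mean comes out ~1.5% hot.
With the full shape the machinery reproduces the evaluated mean of the
sister transition ⁹⁰Sr (model 0.1954 MeV vs 0.1958 evaluated, same
transition type) and gives 0.926 MeV for ⁹⁰Y at the 2.27 MeV endpoint —
0.93 MeV at the two-decimal precision usually quoted.  A plain allowed
shape is also available; it is ~0.02 MeV softer and provided only for
comparison.  Energies below 1 keV are treated as locally deposited
(sub-keV electron ranges are far below the voxel size).

## Stopping power, ranges, transport

Collision stopping power of liquid water uses the Berger–Seltzer (Møller)
formula with I = 75 eV, Z/A = 0.55509 and the Sternheimer density-effect
parameterization; it reproduces reference water tabulations to better than
2% over 10 keV – 2.27 MeV.  The radiative component is approximated by the
S_rad/S_col ≈ E·Z/800 rule (< 2.3% of the total below the endpoint); it is
subtracted from the electron but not deposited — escaping bremsstrahlung is
discarded, which biases the scored dose low by well under a percent in the
thin-layer geometry.  The CSDA range, the integral of the reciprocal total
stopping power, is 11.2 mm at the endpoint (11 mm to the nearest mm).

Transport is condensed-history with a 5% maximum fractional energy loss per
step (2% in oracle comparisons), midpoint-rule energy loss, and Highland
Gaussian multiple scattering per step (on by default).  Step energy is
spread along the step as sub-point deposits at one-third-voxel spacing with
a random per-segment phase; this keeps deposition unbiased on the voxel
scale while conserving energy exactly per history.  Electrons below the
10 keV cutoff (range ~2.5 µm, below voxel size) deposit locally.

Geometry: the scoring grid spans the 1800 × 1300 µm FOV laterally
(10 µm × 10 µm default voxels) and one sphere diameter (32.5 µm) in z —
the water layer of the numerical model.  The surrounding world is unbounded
water: electrons that leave the layer keep being tracked and are scored
again if they re-enter, and are abandoned only when their residual CSDA
range cannot reach the grid.  No plastic or air backscatter is modelled;
relative to a full 3-D well model this biases the absolute dose factor
slightly low.  Spheres are water-equivalent (the resin matrix is ignored),
sources are homogeneous in the sphere volume, and sphere selection per
history is uniform because every sphere carries the same 55 Bq.

## Dose normalization and accumulation

The FOV-average dose deposited by a *single* decay is essentially
independent of how many spheres share the FOV; what scales with occupancy
is the sample dose.  The scoring result therefore reports the sample-level
factor D_calc = n_spheres × (per-decay FOV-average dose) and its per-sphere
normalization D_calc/n_spheres — the quantity that is common across
configurations.  Across random 15/149/216-sphere configurations at ≥10⁵
histories the relative standard deviation of the mean of the per-sphere
factor is ≤ ~1%; the simulated factor (~3.2 × 10⁻⁸ Gy/decay) also agrees
to ~15% with the factor implied by the published mean well doses and
sphere counts at 48 h (~2.8 × 10⁻⁸ Gy/decay), an independent end-to-end
check of the whole chain.

A well with N spheres accumulates D_t = N · f · [A₀/λ (1 − e^(−λt))] with
f the common per-sphere factor, A₀ = 55 Bq and λ = ln 2 / 64.1 h (seconds
internally, hours at the API).  A₀ is referenced to the moment the spheres
enter the well.  The published 48 h and 96 h mean doses are mutually
consistent with this kinetics in all three oxygen arms (the 48 h→96 h
dose ratio is the pure decay number 1.595); the published 72 h rows are
not, so all calibration uses the 48 h anchors only.  Dose bins are
below 10 Gy / 10–70 Gy / above 70 Gy, with boundary ties assigned to the
middle bin (a fixed convention; ties are measure-zero in practice).

## Synthetic plates and the viability model

Per-well sphere counts are drawn from a rounded normal truncated at zero
with the per-arm means/SDs observed in the study (several SDs exceed their
means, which forces the truncation); this is the minimal distribution
honouring the published moments.  Doses follow via the common factor.

Viability uses the linear-quadratic model with an oxygen-enhancement
divisor: S = exp(−α D_e − β D_e²), D_e = D/OER.  Defaults α = 0.05 Gy⁻¹,
β = 5 × 10⁻⁴ Gy⁻², OER = 1.0/1.5/2.5 for N/HP/H — inside the ≤3 band
classically cited for hypoxic radioresistance, and chosen so the ordering
of arm sensitivities is reproduced without overfitting.  The continuous
low-dose-rate exposure motivates an α far below single-fraction values.
BrdU reads 100·S.  A fraction (0.35) of arrested cells becomes senescent;
senescent cells remain metabolically active (gain 1.5 relative to cycling
cells), so the metabolic readout is 100·min(1, S + 1.5·0.35·(1 − S)),
capped at the control level and floored at zero after Gaussian readout
noise (SD 5% points).  This calibration puts the metabolic signal at ~53%
of control just above 70 Gy in normoxia and makes the metabolic assay sit
systematically above the proliferation assay at any positive dose — the
senescence-driven divergence of the two assays.

What the generator does *not* emulate: biological replicate structure,
plate-edge and evaporation effects, cell-cycle dynamics, mechanistic
senescence/SASP biology, and any 3-D or co-culture features.  Passing
tests on synthetic plates therefore validate the pipeline's arithmetic and
qualitative orderings, not the wet-lab effect sizes; published correlation
coefficients and p-values are wet-lab quantities and are deliberately out
of reach.

## Statistics

Percent-of-control metabolic readouts accept either pre-computed reduction
values or raw 570/600 nm absorbance pairs (standard two-wavelength
resazurin reduction formula with fixed extinction coefficients).  Tests:
Wilcoxon signed-rank against the control level (exact null for small n via
scipy), Mann–Whitney U for group splits (exact for small tie-free samples),
Pearson correlation by default with Spearman by flag.  No multiple-testing
correction is applied by default, matching the original reporting; a Holm
adjustment is available.

## Numerical and testing choices

- All randomness flows through numpy Generators seeded explicitly; equal
  seeds give bit-identical grids, datasets and reports.
- Energy conservation per history is exact (float precision) with
  radiative losses disabled, and verified on a padded grid enclosing the
  full CSDA range.
- The stepping engine is validated against two independent oracles: the
  analytic 1-D CSDA depth-dose of a monoenergetic beam (< 2% RMS over the
  first 90% of range, scattering off) and a brute-force straight-line
  kernel integration of an isotropic point source in the thin layer
  (ring-averaged in-plane profile within 5%).
- Acceptance-scale runs use 2 × 10⁵ histories per configuration and
  in-test runs 2–40 × 10³, sizes at which the Monte-Carlo standard error
  is a fraction of the tolerances being tested.
- Sphere packing is uniform rejection sampling with a bounded retry budget;
  infeasible packings raise a capacity error rather than looping.

## Known limitations

- No delta-ray transport, photon transport, or media other than water;
  absolute dose factors are expected a few percent low relative to a full
  coupled-photon 3-D simulation.
- The radiative stopping-power rule and the Highland scattering model are
  approximations; they are adequate for FOV-scale scoring, not for
  track-structure questions.
- The viability model is a deliberately simple LQ + senescence surface;
  its parameters are calibration conventions, not measurements.
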