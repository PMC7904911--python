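# ymicrodose

Micro-scale dosimetry and radiobiology statistics for an **in vitro model of
⁹⁰Y radioembolization**: resin microspheres loaded with yttrium-90 are
scattered over a cancer-cell culture plate, and cell viability is followed
under different oxygen tensions while the spheres irradiate the cells
continuously for days.  The package is written for medical physicists and
radiobiologists who want to compute the absorbed dose that such a plate
actually receives — and to simulate and analyse the whole experiment end to
end when no raw well data are available.

## What it computes

**Source physics.** ⁹⁰Y → ⁹⁰Zr is a first-forbidden unique β⁻ transition
(endpoint 2.27 MeV, half-life 64.1 h).  The spectral density

n(E) dE ∝ F₀(Z,W) p W q² [q² + λ₂ p²] (1 + α/2π · g(W,W₀)) dE

uses the relativistic Fermi function F₀, the generalized-Fermi ratio
λ₂ = F₁/F₀ for the unique shape factor, and Sirlin's outer radiative
correction g.  The quadrature mean is 0.93 MeV.

**Electron transport.** A condensed-history Monte Carlo in liquid water
(Berger–Seltzer collision stopping power with the Sternheimer density
effect; Highland multiple scattering) deposits energy on a voxel grid
spanning the microscope field of view (1800 × 1300 µm) times one sphere
diameter (32.5 µm).  Decays are sampled homogeneously inside the spheres,
directions isotropically, energies from the β spectrum.  The FOV-cuboid
average dose per decay, normalized per sphere, is the *common dose factor*
D_calc; it is stable across sphere configurations to ~1%.

**Dose accumulation.**  A well with N spheres of initial activity
A₀ = 55 Bq each accumulates, after an exposure of t hours,

D_t = N · D_calc · [A₀/λ · (1 − e^(−λt))]

**Plate simulation and statistics.**  A synthetic-data module draws per-well
sphere counts from the observed count distributions, converts them to doses,
and produces Alamar Blue / BrdU readouts from a linear-quadratic survival
model S = exp(−αD_e − βD_e²) with an oxygen-enhancement divisor
(D_e = D/OER) and a senescence term that inflates the metabolic readout.
The analysis module reproduces the study's table structure: descriptives
with Wilcoxon signed-rank tests, Pearson/Spearman dose–viability
correlations, 10/70 Gy dose-bin percentages, and below/above-threshold
Mann–Whitney comparisons.

## Worked example

```python
import numpy as np
from ymicrodose import (
    y90_spectrum, y90_source, mean_energy, csda_range, fraction_delivered,
    generate_config, run_histories, TransportParams, well_dose,
    calibrated_common_factor,
)

spectrum = y90_spectrum()
source = y90_source()
print(f"mean beta energy: {mean_energy(spectrum):.3f} MeV")
print(f"max range in water: {csda_range(2.27):.1f} mm")
print(f"dose delivered in 11 d: {100*fraction_delivered(264, 64.1):.1f}%")

config = generate_config(149, seed=1)
grid, score = run_histories(config, spectrum, TransportParams(n_histories=100_000, seed=1))
print(f"per-sphere dose factor: {score.per_sphere_factor:.2e} Gy/decay "
      f"(study-calibrated: {calibrated_common_factor():.2e})")

wd = well_dose(87, calibrated_common_factor(), source, 96.0)
print(f"87 spheres, 96 h -> {wd.D_t:.1f} Gy ({wd.bin.value})")
```

prints

```
mean beta energy: 0.926 MeV
max range in water: 11.2 mm
dose delivered in 11 d: 94.2%
per-sphere dose factor: 3.23e-08 Gy/decay (study-calibrated: 2.82e-08)
87 spheres, 96 h -> 29.1 Gy (between_10_70)
```

The simulated per-sphere dose factor (3.2 × 10⁻⁸ Gy per decay) agrees with
the factor implied by the published well doses and sphere counts
(2.8 × 10⁻⁸) to ~15%, and a well with 87 spheres accumulates ~29 Gy in
96 h — between the 10 Gy and 70 Gy action thresholds used for the plate
statistics.

There is also a CLI:

```sh
ymicrodose simulate-dose --n-spheres 149 --histories 100000 --seed 1 --out dose
ymicrodose make-plate --seed 1 --out plate.csv
ymicrodose analyze plate.csv --out-dir results/
ymicrodose detect-spheres well.png --pixel-size-um 2.0 --out positions.csv
ymicrodose isodose dose.csv --levels 1,5,10 --time-h 96 --out isodose.json
```

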