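# planksim

Size-structured, diffusion-based modelling of nutrient-limited
phytoplankton growth, and the steady states of a minimal
phytoplankton–zooplankton ecosystem built on it.

The package answers questions like: how far apart are phytoplankton cells
in natural waters (in body lengths), what division rate can molecular
diffusion of nutrient across a cell's boundary layer sustain for a cell of
a given size, and — when those rates drive a size-structured
predator–prey model — whether low nutrient concentrations exclude large
size classes (they do not, absent a constant non-grazing mortality term).

## Modules

- `planksim.size_spectrum` — power-law community size spectra: total
  abundance and volume, moment diameters, carbon biomass, mean inter-cell
  spacing and boundary-layer overlap diagnostics.
- `planksim.physiology` — two-parameter production–resource curves
  (hyperbolic-tangent short-term forms, rectangular-hyperbola acclimated
  forms), the Michaelis–Menten transform, and deterministic multi-start
  least-squares fitting.
- `planksim.diffusion` — diffusion-supported division rates: carbon
  allometry, size envelope of maximum division rates, swimming/sinking
  velocities, Péclet/Sherwood flux enhancement, and the quota-balancing
  iterative growth solver (nitrogen or phosphorus currency).
- `planksim.ecosystem` — 25-class phytoplankton–zooplankton model:
  analytic coexistence fixed points, forward-Euler integration,
  diversity counts, size-distribution slopes, nutrient-grid scans, and
  multispecies / mortality variants.
- `planksim.config`, `planksim.fixtures`, `planksim.io`, `planksim.cli` —
  strict YAML/JSON configuration, synthetic noisy curve fixtures, CSV/JSON
  result serialization, and the command-line interface.

## Command line

```sh
# discreteness diagnostics for a calibrated size spectrum
planksim spectrum --xi 4.5 --prochlorococcus 2e4 --dmin 0.6 --dmax 500

# diffusion-supported division rate for one cell
planksim growth --diameter 12 --group non_diatom --s-inf-nm 5.6 \
    --element P --mu-max 1.19

# division-rate size spectra across nutrient levels
planksim growth-spectrum --s-inf-nm 1,3,17,3000 --dmin 0.6 --dmax 130 --n 60

# ecosystem steady state at one concentration / across the nutrient grid
planksim ecosystem --variant baseline --s-inf-nm 1 --method analytic
planksim grid --group diatom --out results/run1

# fit a production-resource curve form to CSV data (columns resource,rate)
planksim fit --model eq6 --data curve.csv

# synthetic noisy fixture for fit-recovery exercises
planksim fixtures --model eq7 --params '{"v_max": 2, "alpha_v": 0.5}' --seed 1
```

All model paths are deterministic; the `seed` config field affects only
synthetic fixture noise.

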