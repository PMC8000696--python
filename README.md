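# quenchfit

Equilibrium speciation and multiwavelength global fitting of
fluorescence-quenching titrations of ligand–protein binding.

When a drug is titrated into a protein solution, the protein fluorescence
is quenched as drug–protein complexes form. `quenchfit` quantifies the
binding from the recorded spectra with two complementary strategies:

* **Classical single-wavelength analyses** — the Stern–Volmer quench plot
  (with static vs. dynamic classification against the aqueous diffusion
  limit of ~10¹⁰ M⁻¹s⁻¹), the double-logarithm Stern–Volmer (linearized
  Hill) fit, drug-interference percentages, and the ≤10 %-interference
  wavelength-selection rule.
* **Global multiwavelength fitting** — a two-component equilibrium model
  (protein S, quencher Q, complexes SₛQ_q with cumulative formation
  constants), a damped Newton–Raphson mass-balance solver in log
  free-concentration space, per-species molar fluorescences estimated by
  linear least squares, and Gauss–Newton refinement of the log₁₀ binding
  constants against all solutions, wavelengths and acquisition modes
  (emission, synchronous Δλ = 15 nm and Δλ = 60 nm) simultaneously.
  A two-stage fit supports drugs whose synchronous Δλ = 60 nm spectra are
  too intense to join the first refinement stage.
* **Synthetic titrations** — a protocol planner (fixed protein aliquot,
  sixteen stock additions covering a drug:protein ratio of 0.4–14, exact
  dilution bookkeeping) plus Gaussian-band species spectra and seeded
  noise, with four drug-like presets spanning undetectable binding,
  one-site, two-site and strongly interfering behaviour. Every fitting
  stage is validated by recovering the generating constants.

## Command line

```sh
# simulate a two-site titration (spectra.csv + meta.json + ground_truth.json)
quenchfit simulate --preset diflunisal --temp 20 --seed 1 -o run1/

# global multiwavelength fit of that directory
quenchfit fit-global run1/ --preset diflunisal

# classical single-wavelength analyses
quenchfit fit-dlsv run1/ --wavelength 346 --mode emission
quenchfit fit-sv run1/ --wavelength 346 --tau-ns 5

# helpers
quenchfit interference --i-drug 5.3 --i-total 100
quenchfit select-wavelength protein.csv drug.csv --threshold 10
```

Concentrations are µM in files and mol/L in memory. A YAML config file
(`--config`) can supply any protocol or fit option; explicit flags win.

## Layout

```
src/quenchfit/
  equilibrium.py   # models, mass-balance speciation solver
  spectra.py       # grids, spectra, molar fluorescences, smoothing
  classical.py     # SV / DLSV fits, interference, wavelength selection
  globalfit.py     # Gauss-Newton global refinement, staged fit, ranking
  synthetic.py     # titration planner, simulator, drug presets
  recovery.py      # simulate-and-refit recovery studies
  io.py            # titration CSV/JSON dialect, fit reports
  cli.py           # quenchfit command group
tests/             # unit, property (hypothesis) and acceptance suites
scripts/acceptance.py
```
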