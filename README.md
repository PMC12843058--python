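# spionlab

Modelling and analysis toolkit for studying whether one iron-oxide
nanoparticle formulation can serve simultaneously as an MRI contrast agent
and as a magnetic-hyperthermia heat source.

The package covers the full desk-scale workflow:

* **`spionlab.magnetodynamics`** — Néel/Brownian relaxation times, Langevin
  magnetization, Debye complex susceptibility, AC heating power, a numeric
  hysteresis-loop oracle, and a power-versus-diameter sweep.
* **`spionlab.relaxometry`** — outer-sphere proton relaxation theory
  (Ayant/Freed spectral densities, large-crystal and microscopic rate
  formulations), empirical relaxivity extraction from concentration series,
  and r1/r2-versus-diameter sweeps.
* **`spionlab.tem_morphometry`** — STEM image to core-diameter distribution:
  inversion + median filtering, Otsu thresholding, morphological closing,
  distance-transform watershed, minimum-enclosing-circle diameters.
* **`spionlab.calorimetry`** — specific absorption rate (SAR) from
  temperature-time records (windowed-linear or saturating-exponential
  initial-slope estimators) and SAR-versus-diameter summaries.
* **`spionlab.synthetic_data`** — seeded generators for every measured input
  (diameter populations, STEM-like images with ground truth, heating curves,
  relaxation series, correlated property tables).
* **`spionlab.study_analysis`** — Pearson correlation matrix with
  significance/trend labels (p < 0.05 / 0.05 ≤ p < 0.1) and the
  optimum-diameter overlap report.
* **`spionlab.workbench`** — CLI, YAML config validation, CSV/TIFF/JSON
  dialects, and the reproducible end-to-end demo.

All quantities are SI internally; CSV columns and config keys carry their
units in their names (`time_s`, `frequency_khz`, ...), and every CSV table
has a mandatory units row under the header.

## CLI

```bash
spionlab model chi-spectrum --config cfg.yaml --out chi.csv
spionlab model power-sweep  --config cfg.yaml --out power.csv
spionlab relax fit   --csv series.csv --out fit.json
spionlab relax sweep --config cfg.yaml --out r1r2.csv
spionlab tem run --image stem.tif --pixel-size-nm 0.5 --out-dir out/
spionlab sar fit --csv heating.csv --out sar.json
spionlab synth stem --seed 1 --out synth/            # also: heating, relaxation
spionlab study report --table props.csv --out report.json
spionlab demo --seed 0 --out-dir demo_out/           # full synthetic study
```

The demo synthesizes a STEM image, runs the morphometry pipeline, fits
per-diameter relaxivities at 0.55 T and 7 T, estimates SAR from synthetic
heating curves, and emits the correlation matrix plus the
optimum-diameter overlap verdict — bit-identical on re-runs with the same
seed.

## Notes on model conventions

* The equilibrium susceptibility is implemented as the exact small-field
  slope of the Langevin law, `chi0 = mu0*Nm*(MSP*Vm)^2/(3*kB*T)`.
* `power_vs_diameter` defaults to a diameter-independent (unit-`chi0`)
  normalization, which isolates the relaxation-time dependence and yields
  the characteristic unimodal power curve; fixed number-density and fixed
  mass-concentration normalizations are available.
* The outer-sphere prefactors scale as `C/(R*D)`; the JA spectral density
  takes `sqrt(2*omegaI*tauD)` by default (configurable to the literal
  argument).
* A warning is emitted when the excitation amplitude leaves the
  linear-response regime (`xi(H0) > 0.5`, threshold configurable).
* Core density, saturation magnetization and the water diffusion constant
  are not built in; supply them (magnetite literature values: density
  ~5170 kg/m^3, MSP ~300-480 kA/m, D_water ~2.3e-9 m^2/s at 25 °C).
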