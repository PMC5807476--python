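# aunpcount

Quantify a gold-nanoparticle (AuNP) coating on an electrode and the enzymes
immobilized on it, from two electrochemical measurements plus fluorimetry:

1. **Oxide-reduction sweep** — the charge of the gold-oxide reduction peak
   (~+1.1 V vs NHE), divided by a coulometric coefficient (default
   489 µC/cm²), gives the total real AuNP surface area `S`.
2. **Anodic stripping** — the charge `Q` of the gold-dissolution peak
   (~+1.3 V vs NHE) together with `S` gives the mean particle radius
   `r = 3 M_Au / (1.9 e ρ_Au N_A) · Q/S`, the particle count
   `N = S / (x π r²)` (hemispheres, `x = 2`), and the projected coverage of
   the electrode disc.
3. **Fluorimetry** — a linear calibration converts the fluorescence of
   labeled enzymes released by the stripping into an absolute enzyme count,
   hence enzymes per nanoparticle and the per-enzyme footprint (nm²).

A forward simulator generates every raw input from a planted ground truth
(particle-by-particle bookkeeping, Gaussian peaks on a capacitive baseline,
noisy fluorescence), so the whole pipeline is testable by parameter
recovery without any external data.

## Layout

| module | role |
| --- | --- |
| `aunpcount.voltammetry_io` | read/write/validate voltammogram files, cycle segmentation, reference conversion to NHE |
| `aunpcount.peak_analysis` | baseline correction (linear anchors or flat) and trapezoidal charge integration per cycle |
| `aunpcount.nanoparticle_model` | charge → area/radius/count/coverage closed forms, hemisphere geometry, enzyme packing |
| `aunpcount.fluorimetry` | calibration fit, inverse prediction, enzyme counts, footprint, degree of labeling |
| `aunpcount.sem_sizing` | diameter-distribution fit and coverage from particle tables (image segmentation out of scope) |
| `aunpcount.synthetic_data` | forward simulator + file emission + truth manifest |
| `aunpcount.pipeline` / `aunpcount.cli` | per-electrode orchestration, cohort statistics, recovery harness, CLI |

## CLI

```sh
# forward-simulate a cohort of raw files + manifest
aunpcount simulate --config cfg.yaml --outdir raw/ --seed 1

# analyze a manifest: per-electrode results.csv, cohort summary.csv, run.json
aunpcount analyze --manifest raw/manifest.json --outdir out/ --k-ox 489

# cohort statistics from an existing results table
aunpcount summarize --results out/results.csv --group-by group

# simulate -> analyze -> compare to the planted truth
aunpcount recover --config cfg.yaml --outdir rec/ --seed 1 --n-electrodes 25
```

`cfg.yaml` keys mirror the ground truth: `d_mean`, `d_sd`, `n_np`,
`enzyme_density`, `electrode_diameter_mm`, `n_electrodes`, `cal_slope`,
`cal_intercept`, and a `noise:` block (`current_rms_a`, `baseline_a`,
`baseline_slope_a_per_v`, `baseline_curv_a_per_v2`, `fluorescence_cv`).

## Conventions

- Currents are anodic-positive; a per-file `sign` flag flips instruments
  using the opposite convention.
- All potentials are stored in volts and converted to NHE before analysis;
  Ag/AgCl(sat) = +0.197 V and Cu/CuSO₄ = +0.316 V ship as configurable
  defaults, a calibrated wire reference requires an explicit offset.
- Internal model arithmetic is CGS-consistent (cm, g, C); radii cross the
  API in nm, electrode-scale areas in cm², particle-scale areas in nm².
- The coulometric coefficient is selectable among the literature values
  400/450/489/543 µC/cm² (or any custom value, logged with a warning).
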