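# mohnmr

Quantification of mineral oil saturated hydrocarbons (MOSH), mineral oil
aromatic hydrocarbons (MOAH), "other compounds" and the EFSA PAH4 marker
group in pure mineral-hydrocarbon products (petrolatum, white oils,
paraffins) from 1D ¹H NMR spectra, using PULCON/ERETIC external calibration.

The pipeline covers the full chain

    FID → processed spectrum → region integrals → concentrations (g/L)
        → mass fractions (g/100 g) → QC-gated report

plus a seedable synthetic-spectrum generator that provides ground-truth test
inputs for every stage.

## Method summary

* **Calibration**: a quantref sample (5.0 g/L tetrachloronitrobenzene +
  5.0 g/L ethylbenzene in CDCl₃) is measured first in each series. Four
  signals (δ 7.83–7.64 s; δ 7.23–7.11 m, δ 2.75–2.54 q, δ 1.35–1.13 t) give
  per-signal factors `ERETIC = I·MW/(C·N)`; their mean is the series factor.
* **Quantification**: `C = I·MW/(ERETIC·N)` with MOSH as decalin equivalents
  (δ 3.0–0.2, N=18, minus the residual-water window around δ 1.53), MOAH as
  naphthalene equivalents (δ 9.20–7.55, 7.50–7.30, 7.22–7.00, 6.97–6.50,
  N=8; the cut-outs remove CHCl₃ and its ¹³C satellites), "other compounds"
  as glycerol equivalents (δ 6.50–3.00, N=5), and per-analyte windows for
  the PAH4 compounds. Mass fraction = C·V/m·100 from the sample prep
  (~50 mg in 1.5 mL).
* **QC**: a 2500 mg/L cyclohexane control (δ 1.53–1.36, N=12) closes each
  series; its recovery must be within 100 ± 5 % (inclusive) or the series
  is reported INVALID with a nonzero exit status.
* **LOD**: automated 3×noise-SD criterion (noise window δ 10.5–9.5); the
  LOD is the mass fraction of a reference line whose height equals 3× the
  noise SD. PAH4 detection compares the matched-filter peak height above
  the local background to the same threshold.

## CLI

```sh
# write a synthetic series (JCAMP-DX spectra + manifest + ground-truth ledger)
mohnmr simulate --out-dir demo --seed 1 --noise calibrated --n-samples 3

# run the series: quantref → samples → control, reports in demo_out/
mohnmr process --manifest demo/manifest.yaml --out-dir demo_out

# standalone QC check / region scheme inspection
mohnmr qc --quantref demo/quantref.dx --control demo/control.dx
mohnmr regions
```

`process` writes `report.json` (source of truth), `report.csv` and a
Table-style `report.txt`; identical inputs and configuration produce
byte-identical JSON. Inputs are JCAMP-DX files (AFFN or SQZ/DIF/DUP
compressed, `##XYDATA` or `##NTUPLES` real/imaginary pages); sample-prep
metadata comes from the manifest, a YAML/CSV sidecar, or labels embedded in
the files. The integration scheme ships as versioned YAML
(`src/mohnmr/data/regions.yaml`) and can be overridden via the pipeline
config.

## Package layout

| module | role |
| --- | --- |
| `mohnmr.model` | `Spectrum1D`, `FidRecord`, `SamplePrep` data model |
| `mohnmr.spectrum_io` | JCAMP-DX reading/writing, prep sidecars |
| `mohnmr._jcamp` | low-level label parsing + ASDF (SQZ/DIF/DUP) codec |
| `mohnmr.processing` | FT, auto-phasing, baseline (AsLS / modpoly), TMS referencing |
| `mohnmr.pulcon_quant` | regions, ERETIC factor, quantification, PAH4, LOD |
| `mohnmr.qc_validation` | control-recovery gate, CV, spike recovery |
| `mohnmr.synth` | seedable spectrum simulator with ground-truth ledger |
| `mohnmr.cli` | series orchestration, config validation, reports |

The simulator's hump morphology (seeded mixtures of ≥50 overlapping lines
with stated sub-region weights) is a stand-in for real petrolatum
substructure — it reproduces the overlapped-envelope character of mineral
oil spectra without claiming chemical realism.
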