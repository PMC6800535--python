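# adcdar

Drug-to-antibody ratio (DAR) determination for antibody-drug conjugates
(ADCs), built around lysine-linked maytansinoid conjugates of an IgG
scaffold. The package covers the full desk workflow:

- **`adcdar.chem`** — registry of drugs, linkers (SMCC, SM(PEG)2,
  SM(PEG)12) and antibodies, plus the per-drug conjugation mass addition
  (drug + linker − NHS leaving group).
- **`adcdar.extinction`** — standard-curve fitting of serial-dilution
  absorbance tables and conversion of slopes to molar extinction
  coefficients.
- **`adcdar.uv_dar`** — two-wavelength (252/280 nm) UV DAR via the
  closed-form inversion of the absorbance-ratio map.
- **`adcdar.ms_dar`** — intact-mass DAR from linear-mode spectra: baseline
  subtraction, smoothing, main-peak centroid, charge correction, and the
  mass-shift ratio. Also accepts known masses directly (table mode).
- **`adcdar.peptide_map`** — in-silico tryptic digestion with
  conjugation-blocked lysines and digest-map comparison.
- **`adcdar.synthetic_data`** — deterministic generators for dilution
  series, conjugate UV spectra, and low-resolution intact-mass spectra of
  conjugate ensembles (Poisson/binomial/fixed drug load), with ground-truth
  sidecars.
- **`adcdar.report`** — merges per-sample MS and UV results into a
  comparison table (display CSV with 1-decimal rounding; machine CSV at
  full precision).

## CLI

All commands hang off one entry point; `--config` points at a JSON file of
physical constants overriding the shipped defaults
(`src/adcdar/data/constants.json`).

```sh
# simulate a dilution series and fit an extinction coefficient
adcdar simulate-dilution --epsilon-molar 209409 --mw 145423 --out dilution.csv
adcdar fit-extinction --series dilution.csv --wavelength 280 --mw 145423 --out fit.csv

# simulate and analyse a UV spectrum
adcdar simulate-uv --dar 3.5 --out conj_uv.csv
adcdar dar-uv --spectrum conj_uv.csv --out uv.json

# simulate and analyse intact-mass spectra (TSV or --mzml)
adcdar simulate-ms --mean-load 3.5 --out conj.tsv --seed 1
adcdar simulate-ms --load-kind fixed --mean-load 0 --out ref.tsv --seed 2
adcdar dar-ms --conjugate conj.tsv --reference ref.tsv --out ms.json

# table mode: masses known, no spectra needed
adcdar dar-ms --conjugate-mass 150832.2 --reference-mass 147836.9 --per-drug-mass 957.4

# tryptic digest with blocked (conjugated) lysines, 0-based indices
adcdar digest --fasta ab.fasta --blocked 33,76,120 --out peptides.csv

# merge result JSONs into a comparison table
adcdar report --inputs ms.json --inputs uv.json \
    --reference-name Trastuzumab --reference-mass 147836.9 --out table.csv
```

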