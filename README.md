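# tearmrm

Desk-scale, fully testable implementation of an MRM (multiple reaction
monitoring) workflow for quantifying tear proteins — albumin, lactoferrin
and lysozyme — collected on Schirmer strips, with non-human homolog
proteins as internal standards (IS).

Everything the wet lab produced is replaced by a seeded simulator with
known ground truth, so the whole analysis chain is reproducible and
verifiable offline:

| module | what it does |
| --- | --- |
| `tearmrm.masses` | monoisotopic peptide/fragment m/z calculus, tryptic digestion (K/R, not before P) |
| `tearmrm.transitions` | signature-peptide selection, transition-table design, verification of declared m/z values, CSV I/O; ships a six-peptide reference table |
| `tearmrm.synthetic` | seeded simulation of tear samples, strip wetting (1.15 mm/µL), buffer-dependent extraction recovery, analyte/IS co-processing, and a linear MRM instrument response |
| `tearmrm.quantify` | peak integration, IS response-ratio calibration (1/x² weighted), back-calculation, strip length→volume conversion factor |
| `tearmrm.validation` | Rec%, ME%, Bias%, CV%, 3σ/10σ LOD/LOQ, direct-vs-strip method comparison (one-way ANOVA) |
| `tearmrm.workflow` | end-to-end orchestration with YAML config, seed fan-out and a reproducible run manifest |

Notes on conventions: masses are monoisotopic with no modifications
(proton 1.00728 Da, water 18.01056 Da); only b/y fragment series at
charges 1–3 are modelled. The bundled reference table carries the albumin
IS signature peptide as `LVNELTEFAK` — an 11-residue variant of the
sequence circulates in print, but only the 10-residue peptide reproduces
the declared precursor (582.3) and product (708.4 / 837.4) m/z values.

## CLI

```bash
tearmrm transitions verify                  # check the bundled reference table
tearmrm transitions design --panel panel.fasta --manifest panel.csv --out table.csv
tearmrm generate --seed 1 --out bundle/     # synthetic study bundle (CSV + manifest)
tearmrm quantify calibrate --areas bundle/calibration.csv --out curves.csv
tearmrm quantify run --areas areas.csv --curve curves.csv --out quantified.csv
tearmrm validate run --seed 1 --report-dir report/
tearmrm study run --seed 1 --out study/     # the whole pipeline + run manifest
```

`study run` executes: transition verification → bundle generation →
calibration → quantification (QCs, paired direct/strip tears, conversion
factor) → validation, writing every artifact and a `run_manifest.json`
that reproduces the run byte-for-byte under the same seed. A YAML config
(`--config`) can override any design parameter; see `tearmrm.workflow.StudyConfig`
for the schema.

## Synthetic-data caveats

Per-protein tear concentrations (default 10–50 µg/mL), instrument
response factors, and the plain-ammonium-bicarbonate recovery preset are
arbitrary defaults chosen to keep simulated samples inside the validated
calibration range — they are not physiological or measured values. The
extraction recoveries for Buffer A / Buffer B and the strip wetting
factor are the measured means the simulator is parameterised with.
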