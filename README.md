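# sideroforge

In-silico product model for an engineered catechol-siderophore pathway:
combinatorial enumeration of nonribosomal-peptide analogs from supplied amine
precursors, exact-mass and MS/MS fragment-ion prediction, accurate-mass
spectrum annotation with ppm tolerance, and growth-rate analysis of OD610
time courses — plus seeded simulators so every stage is testable offline.

## What it models

An engineered pathway condenses 2,3-dihydroxybenzoic acid (DHB) with fed
polyamine precursors (one amide bond, `M{n}` intermediates) and can further
acylate a second amine site with a DHB-Ser/Thr cap, cyclized (`Sc`/`Tc`) or
open (`So`/`To`), giving full analogs such as `M1Tc`. The same enzymes also
assemble the enterobactin series: DHB-Ser (or DHB-Thr) units joined by ester
bonds, linear or macrocyclized (`Ent`, `Ent trimer/dimer/monomer`,
`Thr-Ent dimer`, ...).

Two m/z conventions are used deliberately: precursor ions are neutral mass +
proton (1.00727646 Da); fragment ions are plain sums of atomic monoisotopic
masses of the charged fragment's formula (this is what reproduces the
reference fragment values such as the DHB acylium at 137.0239).

## Layout

| module | role |
| --- | --- |
| `sideroforge.chemcore` | formula arithmetic, monoisotopic masses, precursor registry |
| `sideroforge.assembly` | candidate product enumeration (intermediates, capped analogs, oligomer series) |
| `sideroforge.fragmenter` | depth-1 fragment-ion prediction and coverage scoring |
| `sideroforge.matcher` | spectrum annotation, isobar handling, incorporation summary |
| `sideroforge.growthfit` | rolling log-linear ("easy linear") growth-rate fits, Welch comparison |
| `sideroforge.synthetic_data` | seeded peak-list and growth-curve simulators with ground truth |
| `sideroforge.io_cli` | MGF/TSV/JSON/YAML plumbing and the `sideroforge` CLI |

Reference tables (precursor registry, published calc/obs masses, frozen
known-unmatched fragments) ship as TSV under `sideroforge/data/`.

## CLI

```bash
sideroforge enumerate --out-dir out/            # candidate table (TSV + JSON)
sideroforge fragments --out out/fragments.tsv   # predicted fragment ions
sideroforge match spectra.mgf --out-dir out/    # annotation + incorporation
sideroforge simulate-spectra --seed 1 --decoys 20 --out sim.mgf --truth-out truth.tsv
sideroforge simulate-growth --seed 1 --rate 0.357 --rate 0.298 --out growth.tsv
sideroforge growth growth.tsv --window 9 --out-dir out/
sideroforge report spectra.tsv --out report.json
```

Spectra are read from MGF (`TITLE` = sample label, `PEPMASS` = precursor
m/z) or TSV (`sample`, `precursor_mz`, semicolon-joined `fragment_mz`).
Numeric sample labels are interpreted as the fed precursor's registry number
and disambiguate isobaric candidates across samples. A YAML config
(`--config`) provides defaults; unknown keys are rejected.

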