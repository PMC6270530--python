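# heliamp

Design and characterization toolkit for perfectly amphipathic helical
antimicrobial peptides built from a hydrophobic residue, a cationic residue
and a single interface tryptophan (Leu/Lys/Trp undecapeptide isomer families
and generalizations).

The package covers the full desk workflow:

- **design** — helical-wheel placement of residues at ((i−1)·100°) mod 360,
  the arc-partition rule that puts the hydrophobic face counterclockwise and
  the cationic face clockwise of the interface tryptophan, family
  enumeration (one isomer per interface position), and a perfect-amphipathy
  validator.
- **physchem** — mean residue hydrophobicity and helical hydrophobic moment
  against pluggable scales (Eisenberg consensus ships as a resource), polar
  angle of the cationic face, average/monoisotopic mass with C-terminal
  amidation, integer net charge, and A280 → molarity via the Trp
  absorptivity (5500 M⁻¹cm⁻¹).
- **activity** — geometric-mean MIC (log2 domain, exact on two-fold series),
  hemolysis % normalization, minimal hemolytic concentration (first strict
  exceedance of a 5 % threshold), and the pseudo-therapeutic index
  TI′ = MHC / unrounded GM. Out-of-range cells (`>128`) are explicit bound
  markers, never numbers.
- **cd** — mdeg → mean residue molar ellipticity, wavelength readouts by
  linear interpolation, a single-wavelength two-state helicity estimator at
  222 nm, the [θ]₂₂₂ × [θ]₂₀₈ product, and an isodichroic-point locator for
  spectral families.
- **fluor_nmr** — smoothed emission λmax, Δλmax against a reference
  (negative = blue shift), and ¹Hα secondary chemical shifts with a helical
  flag at ≤ −0.1 ppm from the 4.7 ppm random-coil reference.
- **sar** — OLS regression of activity against structural parameters with
  R², and refits under peptide-id exclusion lists.
- **synth** — seeded generators for every input kind (two-state CD
  mixtures, emission peaks, Hill hemolysis curves, two-fold-quantized MIC
  tables, planted linear SAR tables) so every stage is testable offline.

A transcribed MIC/MHC reference panel for the 11-member L5K5W family ships
as packaged CSV fixtures (`heliamp/data/`).

## CLI

```sh
heliamp design --formula L5K5W --trp-pos all --out family.fasta
heliamp physchem --in family.fasta --scale eisenberg-consensus --out profiles.csv
heliamp activity --out summary.csv                      # packaged panels
heliamp activity --mic mic.csv --hemolysis hemo.csv --out summary.csv
heliamp cd --in spectra/cd_0.txt --in spectra/cd_1.txt --in spectra/cd_2.txt --out cd.csv
heliamp fluor --in em/emission_NATA.txt --in em/emission_W2.txt --reference NATA --out fluor.csv
heliamp nmr --in shifts.csv --out shifts_out.csv
heliamp sar --table sar.csv --y hemolysis_128 --x theta_product --exclude W1,W11 --out fit.json
heliamp simulate --what all --seed 1 --out simdata/
```

FASTA headers carry `|amide=yes|trp=<p>|formula=L5K5W` tags; spectra are
two-column text with `# key: value` metadata headers; tables are plain CSV
(see `heliamp.fileio` docstrings for the exact schemas).

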