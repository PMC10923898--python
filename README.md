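# phasesep

Structure-aware prediction of phase-separating proteins (PSPs) from
AlphaFold-style PDB models.  From a single-chain model with per-residue
pLDDT in the B-factor column, the pipeline derives:

1. **IDRs** — residues with pLDDT < 50, minus residues assigned helix or
   sheet secondary structure, refined by iterative smoothing (stretches
   ≤ 3), gap bridging (ordered gaps ≤ 10 between IDRs ≥ 20), and pruning
   of IDRs shorter than 20 residues;
2. **SSUP** — the structured superficial region: residues outside every
   IDR whose relative solvent accessibility (Shrake–Rupley SASA over a
   max-ASA table) exceeds 25%;
3. **charged stickers** — SSUP residues whose net charge index
   (positive minus negative SSUP residues within 14 Å, K/R vs D/E)
   exceeds 3 in magnitude, grouped by centroid-linkage hierarchical
   clustering on Cα coordinates cut at 14 Å;
4. **an ~83-entry feature vector** per protein (amino-acid and
   physicochemical-group composition, hydropathy, polarity, isoelectric
   point, molecular weight — computed separately on IDRs and SSUP — plus
   IDR extent, sticker frequencies, and optionally phosphosite
   frequency), with IDR features *missing* (not zero) for proteins
   without IDRs;
5. **a PS score** from an ensemble of ten gradient-boosted tree
   classifiers, each trained on all positives plus a fresh negative
   subsample of twice their number, with inverse-class-frequency sample
   weights and native missing-value routing; the score is the member
   mean.

Secondary structure uses an external DSSP binary when one is on PATH and
an internal Kabsch–Sander assigner otherwise.

## CLI

```
phasesep features --pdb-dir pdbs/ --out features.csv             # feature matrix
phasesep train    --features features.csv --labels labels.csv --out-dir model/
phasesep tune     --features features.csv --labels labels.csv --out best.json --n-trials 50
phasesep predict  --pdb-dir pdbs/ --model-dir model/ --out scores.csv
phasesep eval     --scores scores.csv --labels labels.csv --out metrics.json
phasesep fixtures --out-dir fx/ --seed 5                         # synthetic test article
phasesep threshold-scan --pdb-dir pdbs/ --out scan.tsv           # 10–20 Å sticker scan
```

Labels CSVs use columns `protein_id,label[,split]` with labels in
`{ID-PSP, noID-PSP, non-PSP}`.  Every command writes a JSON config
snapshot next to its output; reruns are byte-identical under a fixed
seed.  Per-protein parse/analysis failures are logged and skipped.

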