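# terminome

Peptide terminome analysis: infer which proteases shaped a peptidome.

Given a quantified peptidome (label-free DIA peak areas) and the parent
protein sequences, the package

1. applies the standard quantification filters (shared peptides out,
   confidence ≥ 80%), normalizes every acquisition run to unit total area,
   sums peptide areas into cleaved-protein areas, and calls fold changes
   against a reference group (significant above 2.0-fold);
2. maps each peptide back to its parent protein and reads off the cleavage
   context (P2, P1 | P1′, P2′ in Schechter–Berger numbering) at both peptide
   termini, accumulating an abundance-weighted 20 × 4 amino-acid frequency
   matrix per sample group (the observed *terminome matrix*);
3. decomposes that matrix into a convex combination of per-protease
   cleavage-site specificity matrices by simplex-constrained least squares
   (sum of contributions = 1, contributions ≥ 0), solved exactly with an
   active-set quadratic program and cross-checked by a brute-force simplex
   lattice oracle; and
4. normalizes the fitted contributions across groups on a log10 scale for
   heatmap display.

A synthetic-data module generates ground-truth proteomes, Dirichlet-sampled
protease specificity panels, and simulated digests with known mixture
weights f\*, so the whole pipeline is testable end to end without any
external download. A packaged fixture ships the published fold-change
matrix of 135 cleaved fish-muscle proteins (groups Decap, AirEx1, AirEx5,
AirEx10) and a synthetic 45-protease example specificity panel.

## CLI

```sh
# make a synthetic dataset (proteome FASTA, specificity TSV, peptide quant TSV)
terminome simulate --seed 3 --out-dir demo/

# full pipeline: filters -> fold changes -> terminome -> deconvolution -> heatmap
terminome run-all \
    --peptides demo/peptides.tsv \
    --proteins demo/proteome.fasta \
    --specificity demo/specificity.tsv \
    --reference-group Decap \
    --out-dir demo/run1/
```

Individual stages are available as `filter`, `foldchange`, `terminome`,
`fit`, and `heatmap` subcommands; `run-all` writes a `manifest.json` with a
config hash so reruns are verifiably identical.

### File dialects

- **Quant table** (TSV): `peptide_seq, protein_id, group, replicate, area,
  confidence, shared` — one row per peptide per acquisition run.
- **Specificity panel** (long TSV): `protease_id, ec_number, position,
  residue, value` with positions `P2, P1, P1p, P2p`; counts or frequencies,
  column-normalized at load.
- **Terminome matrices** (long TSV): `group, position, residue, frequency`.
- **Contributions** (TSV): `group, protease_id, f, Z`; normalized
  contributions as a proteases × groups TSV with `NA` marking zero
  contributions (log10 undefined).

## Layout

```
src/terminome/
  alphabet.py        residue alphabet and position labels
  specificity.py     per-protease 20x4 specificity matrices (load/validate/build)
  peptidome.py       quant-table filters, run normalization, fold changes, coverage maps
  terminome.py       peptide mapping, cleavage contexts, observed matrices
  deconvolution.py   simplex-constrained fit, lattice oracle, log10 normalization
  synthetic.py       ground-truth generators and the recovery experiment
  cli.py             click-based pipeline CLI
  data/              packaged fixtures (fold-change matrix, example panel)
```
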