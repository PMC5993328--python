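# dmsenv

Environment-resolved analysis of deep mutational scanning (DMS) experiments
for a single gene: from per-sample mutant read counts (or raw amplicon
FASTQ) to per-mutant fitness scores, environment-level selection statistics,
biophysical-constraint analysis and folding x binding fitness landscapes.
A fully specified synthetic-data generator makes every stage testable
without any external downloads.

## What it computes

- **Variant calling** (`dmsenv.calling`): exact-anchor placement of
  full-length amplicon reads (or SAM ingestion of externally aligned reads),
  codon-by-codon comparison with mean-read/mean-codon Phred > 30 filters, a
  >= 3 reads-per-variant cutoff, and collapse of codon counts to amino-acid
  substitutions.
- **Fitness scoring** (`dmsenv.scoring`): depth-normalised log2 preferential
  enrichment of selected over unselected pools, averaged over replicates;
  mutants absent from every selected replicate are *eliminated* (null
  fitness, no number); neutrality thresholds = mean +/- 2 SD of
  unselected-vs-unselected enrichments.
- **Selection statistics** (`dmsenv.selection`): mean viability selection
  coefficient `s = 1 - v_non/v_syn` with a conjugate Beta(1,1) posterior
  (1000 paired draws, pMCMC contrasts between environments), delta-F,
  mutational robustness rho (Spearman), and the n_pos/n_neg ratio with
  replicate-noise thresholds `(mu_t+mu_r)/2 +/- 2*sqrt((s_t^2+s_r^2)/2)`.
- **Structural features** (`dmsenv.structure`): PDB parsing, distance of
  each residue's C-alpha to the active-site residue's atoms (minimum over
  atoms), C-alpha-to-partner-chain dimer-interface distances, logP/pI
  substitution deltas from a bundled property table, and validated ingestion
  of per-substitution feature TSVs (ddG, depth, conservation, ...).
- **Constraint analysis** (`dmsenv.constraints`): fitness-feature Spearman
  correlation matrices with hierarchical clustering; folding x binding
  subsets (FB / cFB / FcB / cFcB) cut at the feature medians with a
  10-percentile exclusion band; subset-wise `s` posteriors; exact one-sided
  Mann-Whitney subset tests; bootstrap cross-environment correlations with
  subset contrasts.
- **Landscapes** (`dmsenv.landscape`): nearest-neighbour interpolation of
  fitness over the (ddG, distance-to-active-site) plane on min-max
  normalised axes, with batch rendering under a shared colour scale.
- **Synthetic data** (`dmsenv.simulate`): NNK single-site libraries,
  ground-truth fitness from a folding-cliff x binding-cliff double sigmoid
  (defaults: cliff at 2 kcal/mol and 15 A), multinomial sampling of
  selected/unselected pools at configurable depth, and FASTQ emission with
  two-point base qualities — byte-identical outputs for a fixed seed.

## CLI

```sh
dmsenv simulate --config sim.yaml --out dataset/   # synthetic experiment
dmsenv call --fastq reads.fastq --reference ref.fasta --out called
dmsenv run --config run.yaml                       # full pipeline
dmsenv reproduce --fitness-table scores.tsv --reference reference
```

A minimal simulation config:

```yaml
gene_length_codons: 70
depth_per_sample: 100000
n_replicates: 2
seed: 1
environments:
  - {name: reference}
  - {name: heat, folding_shift: 1.5}
```

A run config lists the samples and analysis inputs:

```yaml
reference_environment: reference
reference_fasta: dataset/reference.fasta
features: features.tsv        # optional: per-substitution biophysics
outdir: out
seed: 1
samples:
  - {environment: reference, pool: selected,   replicate: 1, fastq: dataset/reads/reference_selected_1.fastq}
  - {environment: reference, pool: unselected, replicate: 1, fastq: dataset/reads/reference_unselected_1.fastq}
  # ... one selected + one unselected pool per environment per replicate
```

Exit codes: 0 success, 2 config/validation error, 3 stage failure.
`out/report.json` contains every computed statistic plus seeds and manifest.

## Reproduction mode

`dmsenv reproduce` (and the acceptance report) recompute the per-environment
selection coefficient, delta-F and rho directly from a deposited per-mutant
fitness table.  The published table is a spreadsheet that is not
redistributable here; export it (TSV, CSV or XLSX) to

```
data/supplementary/fitness_scores.tsv
```

with one row per mutant — a `mutant` column (`L5P` style ids; synonymous
mutants have wt == mut) and one fitness column per environment, blank cells
meaning the mutant was eliminated in that environment.  Environment columns
are recognised by name (e.g. `reference`/`37C 12.5`, `Gm 25`, `30C`, `42C`,
`TMAO`, `glycerol`, `42C TMAO`, `42C glycerol`).

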