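# isoscreen

Analysis pipeline for pooled CRISPR/Cas9 drop-out screens run in isogenic
cell-line pairs (knockout vs wild-type), plus a seeded screen simulator so
every stage is verifiable without raw sequencing data.

Stages:

1. **quantify** — exact-match sgRNA counting from adapter-trimmed FASTQ
   (scan or anchored policy, zero mismatches, collision-free library).
2. **essentiality** — per-guide log2 fold change vs the plasmid library
   (`log2((c+α)·S/depth)` difference, defaults α=5, S=1e7), then gene-level
   Bayes-factor lethality scores: kernel density estimates fitted on
   reference essential / non-essential genes and a summed log2 likelihood
   ratio over each gene's guide × replicate fold changes.  Replicate lines
   are scored separately and aggregated per genotype (mean by default).
3. **differential** — OLS of knockout gene scores on wild-type scores,
   standardized residuals `Z = (r − mean(r)) / sd(r)` (population sd by
   default), dependency calls at strict `Z > 3.5`, ranks, and one-sided
   hypergeometric term enrichment (unadjusted p, BH as an extra column).
4. **synthetic_data** — seeded generative screen: log-normal plasmid skew,
   infection bottleneck at configurable coverage, exponential growth over
   *d* doublings with per-guide knockout efficiency
   (`e·2^(d·f) + (1−e)` mixture), multinomial sequencing, FASTQ export,
   and planted ground truth for precision/recall scoring.
5. **validation_assays** — competitive-depletion normalization, ΔΔCt,
   ChIP percent-input, and luciferase fold-activity calculators.

## CLI

```sh
isoscreen simulate --out sim/ --seed 1 [--config sim.yaml] [--fastq]
isoscreen count    --library lib.tsv --sheet sheet.tsv --fastq-dir fq/ --out counts.tsv
isoscreen bf       --counts counts.tsv --sheet sheet.tsv --library lib.tsv \
                   --ess ess.txt --noness noness.txt --out bf.tsv
isoscreen diff     --bf bf.tsv --out diff.tsv [--threshold 3.5 --sd population]
isoscreen report   --diff diff.tsv --annotation terms.tsv --out enrichment.tsv
isoscreen run      --config run.yaml          # full pipeline with provenance
isoscreen demo     --seed 1                   # synthetic end-to-end + recovery
isoscreen assay    depletion|ddct|pctinput|luc ...
```

All tabular I/O is TSV: the library is `guide_id, gene, sequence[,
guide_class]`; the sample sheet is `sample_id, genotype
(knockout|wildtype|plasmid), replicate, timepoint_days`; reference gene
sets are one symbol per line.

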