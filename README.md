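# rnaseq-snp-eval

Evaluate SNP calling from bulk RNA-seq alignments against a truth genotype
set. The package implements the full analysis pipeline as composable,
tested stages:

- **synthetic_data** — seeded generator for a small reference genome, gene
  models, planted diploid SNVs, expression-weighted 40 bp single-end RNA-seq
  alignments (with sequencing errors and PCR duplicates), uniform-depth DNA
  evidence alignments, and an accessibility mask. All fixtures are written
  in standard formats (FASTA, SAM, VCF, BED, refFlat/BED12), so no external
  data are needed.
- **dedup** — both duplicate-removal semantics: pre-alignment
  (exact-sequence identity) and post-alignment (same contig/start/end/strand,
  SAM flag 0x400).
- **caller** — a minimal, exactly documented threshold pileup genotype
  caller (min depth 3, het band 0.2–0.8, hom above 0.8); external VCF call
  sets can be substituted at any pipeline boundary.
- **filters** — SNP-cluster removal (two or more variants within a 3 bp
  window; all members removed) and accessibility-mask filtering.
- **evaluate** — expected-call definition (truth sites at ≥3× coverage),
  TP/FP/FN classification with allele-catalog matching, specificity
  (TP/(TP+FP)) and sensitivity (TP/(TP+FN)) stratified by depth bin and
  zygosity, and call-set overlap.
- **rescue** — re-examination of putative false positives against DNA
  evidence (het rescued at 20–80% alt fraction inclusive; hom at >90%).
- **pipeline** / **cli** — strategy-grid orchestration (pre/post dedup ×
  genome/transcriptome scope) and a `rnaseq-snp-eval` command-line tool.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: brute-force
oracle equivalence for every core operation, the noiseless perfect-metrics
limit, depth/zygosity phenomenology on a 200 kb simulation, the
post-vs-pre duplicate-strategy ordering, exact-binomial rescue calibration,
and file-format round-trips.

## CLI

```sh
# generate a synthetic dataset
rnaseq-snp-eval simulate --config sim.yaml --outdir data/ --seed 1

# individual stages
rnaseq-snp-eval dedup --mode post --in data/rna.sam --out dedup.sam --ref data/reference.fa
rnaseq-snp-eval call --bam dedup.sam --ref data/reference.fa --min-depth 3 --out calls.vcf
rnaseq-snp-eval filter --vcf calls.vcf --mask data/mask.bed --ref data/reference.fa --out filtered.vcf
rnaseq-snp-eval evaluate --calls filtered.vcf --truth data/truth.vcf \
    --catalog data/catalog.vcf --bam dedup.sam --out report/
rnaseq-snp-eval rescue --fp filtered.vcf --evidence data/evidence.sam \
    --ref data/reference.fa --out rescued.vcf

# the whole strategy grid in one go
rnaseq-snp-eval run-all --sim-config sim.yaml --outdir run/ --seed 1
```

`sim.yaml` maps any `SimConfig` field, e.g.:

```yaml
n_reads: 50000
error_rate: 0.005
pcr_duplicate_rate: 0.2
duplicate_error_mode: with_errors
mask_fraction: 0.05
evidence_depth: 20
```

A strategies YAML for `run-all --strategies` lists `StrategyConfig`
entries (`name`, `dedup_mode`, `reference_scope`, nested `caller_params`).

## Conventions

FASTA/SAM/VCF coordinates are 1-based; BED and refFlat are 0-based
half-open. Duplicate reads are flagged, never silently deleted, in SAM
output. Undefined metric ratios are reported as missing, never 0 or 1.
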