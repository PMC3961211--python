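# isletpop

Population-genetic analysis toolkit for genotype-array cohorts from isolated
populations: quality control, structure statistics, runs-of-homozygosity
(RoH) calling, and a haplotype-based positive-selection scan — plus a
synthetic-data generator so the whole pipeline is testable end to end without
any external data.

## What it does

- **core_io** — domain types (genotype matrix, phased ancestral-coded
  haplotype matrix, RoH segments) and readers/writers for VCF (via cyvcf2),
  PLINK `.ped`/`.map` text, BED and TSV. Coordinates are 1-based inclusive
  internally; BED output is 0-based half-open.
- **qc** — call-rate (default ≥98%), minor-allele-frequency (default ≥0.01)
  and Hardy–Weinberg (default exact test, p ≥ 1×10⁻³) filters with a removal
  report. Fixed order: autosomes → samples → MAF → HWE.
- **structure** — PCA on standardized genotypes; multinomial-logistic group
  prediction accuracy from leading PCs; pairwise genomic-control inflation
  factor λ_GC (allelic 1-df chi-square, median / 0.4549); Hudson Fst
  (genome-wide ratio of averages, block-jackknife CI, permutation p) and an
  inbreeding-robust Fst (haploidize each individual, then a count-based
  unbiased estimator); per-sample genomic inbreeding coefficients; Welch
  group comparisons.
- **roh** — sliding-window RoH caller (50-SNP windows capped at 5000 kb,
  ≤1 heterozygote and ≤5 missing calls per window, hit proportion > 0.05,
  segments ≥500 kb and ≥50 SNPs), six half-open length classes
  (0.5–1 … >16 Mb), and F_RoH% summaries against a 2.84 Gb accessible-genome
  denominator.
- **selection** — EHH for ancestral and derived alleles, integrated EHH
  (trapezoid with 0.05 cutoff and 200 kb gap cap), iHS standardized within
  derived-frequency bins, and a windowed scan for regions enriched in
  |iHS| > 4 with binomial nominal p-values and permutation-based
  family-wise empirical p-values.
- **synthetic_data** — Balding–Nichols genotypes with tunable differentiation
  and per-sample inbreeding, planted autozygous tracts, planted-sweep phased
  haplotypes with known truth, and null sample splits.
- **pipeline** — YAML-configured orchestration with a content-hash manifest
  and a one-command synthetic demo.

## CLI

```sh
isletpop demo --seed 1                 # synthetic end-to-end run + report
isletpop run config.yaml               # full pipeline from a config
isletpop qc input.vcf --min-maf 0.01 --hwe-alpha 1e-3
isletpop structure fst input.vcf labels.tsv --pair g1,g2 --estimator hudson
isletpop structure lambda-gc input.vcf labels.tsv --pair g1,g2
isletpop roh call input.vcf --window-snps 50 --window-kb 5000 --min-kb 500
isletpop selection scan phased.vcf --threshold 4 --n-perm 1000 --seed 1
```

`labels.tsv` needs columns `sample_id` and `group`. The selection scan takes
a phased VCF; the ancestral allele comes from INFO/AA or a side TSV with
columns `chrom`, `pos`, `ancestral`.

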