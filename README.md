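# pedqtl

Pedigree-aware association mapping for quantitative traits and gene
expression, with rule-based QTL/eQTL colocalization and a gene-drop
simulator for multi-breed pedigreed populations.

The core is a generalised least-squares (GLS) single-marker scan whose
error covariance

```
W = sigma2_P * (h2 * A + (1 - h2) * I)
```

partitions the phenotypic variance into an additive genetic component
structured by the pedigree numerator relationship matrix `A` and an
iid environmental component. On top of that engine the package provides:

- **`pedqtl.core_io`** — readers/writers for pedigree, genotype (VCF or
  TSV dosage), phenotype, expression-count and annotation tables; variant
  QC (call rate, MAF); association-table round-tripping.
- **`pedqtl.relationship`** — dense tabular-method `A` matrix, inbreeding,
  founder-breed ancestry fractions with a 15/16 purebred threshold, and
  opposite-homozygote Mendelian concordance checks.
- **`pedqtl.association`** — the GLS scan (one symmetric factorization per
  trait, closed-form per-variant regressions), minor allele frequencies,
  genomic inflation factor (median chi-square / 0.45494), Bonferroni /
  inflation-adjusted / prioritisation thresholds, greedy 1 Mbp locus
  definition, and per-variant phenotypic variance explained.
- **`pedqtl.eqtl`** — expression filtering (mean reads/animal), a
  closed-form negative-binomial variance-stabilising transform (arcsinh
  family with median-of-ratios size factors), single-pass PCA outlier
  exclusion, and cis-eQTL scanning with the same GLS engine.
- **`pedqtl.coloc`** — per-window Pearson/Spearman correlation of QTL and
  eQTL chi-square vectors, composite LD between top variants, and the
  candidate-gene triage rules (coding variant in LD, correlated eQTL,
  shared top variant).
- **`pedqtl.synthetic_data`** — discrete-generation two-breed pedigrees,
  Balding–Nichols founder allele frequencies, Markov-correlated founder
  haplotypes (tunable LD), Poisson-recombination gene drop, phenotypes
  with planted QTL plus polygenic and environmental components, and
  negative-binomial expression counts with planted cis effects. Fully
  reproducible from `(config, seed)`.

## Command line

```sh
# generate a synthetic cohort
pedqtl simulate --config sim.yaml --seed 7 --out-dir sim/

# GLS association scan (writes TSV + significance JSON)
pedqtl assoc --genotypes sim/genotypes.tsv --phenotypes sim/phenotypes.tsv \
             --pedigree sim/pedigree.tsv --trait trait --h2 0.5 --out assoc.tsv

# expression preprocessing + per-gene cis-eQTL scans
pedqtl eqtl --counts sim/counts.tsv --genotypes sim/genotypes.tsv \
            --pedigree sim/pedigree.tsv --genes genes.tsv --h2 0.3 --out-dir eqtl/

# chi-square correlation colocalization and candidate triage
pedqtl coloc --qtl-assoc assoc.tsv --eqtl-dir eqtl/ \
             --genotypes sim/genotypes.tsv --threshold-p 1e-6 --out-dir coloc/
```

Every run logs the package version, seed and SHA-256 digests of its
inputs. Missing dosages are mean-imputed per variant inside the
association engine only and never persisted.

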