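# stabilityqtl

Simultaneous mapping of expression QTLs (eQTLs) and mRNA-stability QTLs
(stQTLs) from RNA-seq exon/intron read counts and genotype dosages.

Relative mRNA stability per gene and sample is inferred from the difference
between exonic and intronic log2 abundance deviations (exon-intron split
analysis with a per-sample linear bias correction). Both expression
(`log10(100*TPM + 1)`) and stability traits are then scanned against cis
variants (100 kb upstream of the TSS to 100 kb downstream of the TTS) with
ordinary least squares dosage models and Benjamini-Hochberg FDR control.
Downstream tooling covers:

- cross-classification of eQTLs vs stQTLs with effect-direction concordance,
- greedy LD-block construction (dosage r² > 0.9) and representative-QTL
  filtering,
- genic-region (upstream / 5'UTR / CDS / intron / 3'UTR / downstream) and
  positional enrichment with Fisher exact tests,
- binding-site (RBP / miRNA BED intervals) overlap and per-factor enrichment
  on mature-mRNA variants,
- sex-specific stQTL classification by sex-stratified scans and a
  genotype-by-sex interaction model.

A self-contained simulator (`stabilityqtl.simdata`) generates LD-structured
genotypes (founder-haplotype copying: Hardy-Weinberg proportions plus block
LD), gene models, covariates, and negative-binomial exon/intron counts from
a steady-state transcription/decay kinetic model with planted allelic
effects on log2 transcription rate or log2 decay rate, together with a truth
table for parameter-recovery testing. No real genotype or expression data is
required or bundled.

## CLI

```sh
stabilityqtl run --out runs/demo --seed 1            # full simulated workflow
stabilityqtl simulate --out sim/ --seed 1            # just the synthetic data
stabilityqtl stability --counts-exon sim/counts_exon.tsv \
    --counts-intron sim/counts_intron.tsv --out stability.tsv
stabilityqtl assoc --trait stability --vcf sim/genotypes.vcf \
    --counts-exon sim/counts_exon.tsv --counts-intron sim/counts_intron.tsv \
    --gtf sim/annotation.gtf --covariates sim/covariates.tsv --out stqtl.tsv
stabilityqtl compare --eqtl eqtl.tsv --stqtl stqtl.tsv --out cross.tsv
stabilityqtl ld-filter --vcf sim/genotypes.vcf --qtl stqtl.tsv --out reps.tsv
stabilityqtl enrich --vcf sim/genotypes.vcf --gtf sim/annotation.gtf \
    --qtl stqtl.tsv --out regions.tsv
stabilityqtl rbp-overlap --vcf sim/genotypes.vcf --gtf sim/annotation.gtf \
    --qtl stqtl.tsv --sites sites.bed --out rbp.tsv
```

Formats: genotypes as VCF 4.2 (GT only), gene models as GTF (1-based,
inclusive) with a companion segment BED (0-based, half-open), counts /
covariates / results as headered TSV, binding sites as BED with a factor
name in column 4.

## Notes

- Stability values are relative to the cohort mean per gene (rows are
  centered), never absolute decay rates; the sign convention is
  stability = -log2(decay rate).
- The stringency filter maps a fraction sigma in (0, 1] to the sigma-quantile
  of per-gene minimum read counts; each gene's largest passing grid value
  (11-point grid, 0.01-0.99) is reported as `max_stringency`.
- LD blocks use a position-ordered greedy approximation of clique
  partitioning; the input variant order is part of the contract.
- PEER-style latent factors are accepted as pre-computed covariate columns,
  never estimated here.
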