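# varprio

Case-control rare-variant prioritization for small cohorts: allelic
association with PLINK-style QC, consequence-severity ranking,
case-exclusive variant filtering, gene-level co-occurrence
aggregation, and STRING-style protein-interaction subnetwork
extraction.

## The problem

In a small case-control cohort (the motivating design is 12 cases and
11 controls of persistent vs. nonpersistent opioid users, all exposed
to opioid painkillers), no single variant reaches significance after
multiple-testing correction. Signal is instead sought in three
complementary ways:

1. **Candidate-gene panel scan.** Variants inside a curated panel of
   addiction-associated genes (±5 kb flanks) are tested with the
   allelic χ² and reported at a raw-p threshold.
2. **Case-exclusive filtering.** Genome-wide, keep variants where
   every non-missing control is homozygous reference and at least one
   case carries the alternate allele; rank by consequence severity and
   significance.
3. **Co-occurrence aggregation.** A gene hit by several distinct
   case-exclusive variants may be impaired additively: per gene, the
   case alternate-allele counts C_A of its variants are summed, and
   genes with ≥ 2 variants and a sum ≥ 10 join the significant single
   variants' genes to form the **genes of interest (GOI)**. The GOI
   seed a STRING-style protein-interaction subnetwork whose connected
   components feed downstream enrichment tools.

## The statistics

For a variant with `a`/`b` alternate/reference alleles in cases and
`c`/`d` in controls (missing genotypes contribute no alleles):

- allelic test: `χ² = N(ad − bc)² / [(a+b)(c+d)(a+c)(b+d)]`, 1 df,
  no continuity correction; `p` from the upper χ² tail,
- frequencies `F_A = a/(a+b)`, `F_U = c/(c+d)` for the alternate
  allele (keep-allele-order; no minor-allele flipping),
- odds ratio `OR = ad/bc`, printed `NA` when `bc = 0`,
- QC per variant: missing-call rate ≤ 0.1, pooled minor-allele
  frequency ≥ 0.05, exact two-sided Hardy–Weinberg p ≥ 1e-7,
- Bonferroni and Benjamini–Hochberg adjusted p-values side by side.

Interaction confidences (integer `combined_score`, 0–1000) are
normalized per gene — `norm_score = s(u,v) / min(M(u), M(v))` with
`M(x)` the best score at node `x` — so every gene keeps its strongest
interaction at any threshold ≤ 1. The seed subnetwork is seeds +
neighbors, plus (applied once) any node with ≥ 2 selected neighbors.

## Worked example

Simulate the default study-like cohort (planted case-exclusive
variants with known genes and consequences, plus null background
variants and a STRING-like network), then run the case-exclusive
stage:

```sh
varprio simulate cohort --out sim --seed 7
varprio case-exclusive --vcf sim/cohort.vcf --pheno sim/phenotypes.tsv \
    --vep sim/annotations.tsv
```

which prints:

```
chrom	id	pos	gene	C_A	consequence	chi2	p
chr1	rsP0001	1000000	FAM186A	11	frameshift_variant	13.25	0.0002722
chr1	rsP0002	1100000	SCUBE2	10	missense_variant	11.71	0.0006207
chr1	rsP0003	1200000	CCDC185	9	missense_variant	10.26	0.001362
chr1	rsP0004	1300000	MTUS2	8	missense_variant	8.877	0.002888
```

Each row is a variant whose alternate allele was seen only in cases:
`C_A` of the 24 case alleles carry it, none of the 22 control alleles
do, and the allelic χ² with its raw p quantifies the imbalance (a
C_A = 11 case-exclusive variant gives χ² = 13.25, p = 2.7e-4). The
full pipeline — panel scan, co-occurrence table, GOI list, and PPI
subnetwork with components — runs from one YAML config:

```sh
varprio run-all --config config.yaml
```

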