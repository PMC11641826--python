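# Methods

## Cohort model

The package models a small, unrelated, diploid autosomal case-control
cohort. Genotypes are alternate-allele dosages in {0, 1, 2, missing};
half-calls (`./1`) are conservatively treated as missing, and
multi-allelic VCF records are split into one biallelic variant per
alternate allele with genotypes recoded against that allele. Variants
are keyed by (chrom, pos, ref, alt); identifiers fall back to the
`"REF > ALT"` label when no rsID is present. Phenotypes use the
PLINK-style 1 = control / 2 = case coding. Coordinates are 1-based
inclusive throughout.

## Allelic association

The unit of inference is the 2×2 table of alternate/reference allele
counts in cases (a, b) versus controls (c, d); missing genotypes
contribute zero alleles, so a+b+c+d equals twice the number of called
samples at the variant. The statistic is the uncorrected Pearson
allelic χ² with 1 df,

    χ² = N (ad − bc)² / [(a+b)(c+d)(a+c)(b+d)],

with the upper-tail p computed from the χ² survival function
(regularized incomplete gamma via `scipy`). No Yates correction is
applied: the continuity-corrected statistic does not reproduce the
reference worked-example values (13.25, 10.48, 8.324, ...), which the
test suite locks at printed precision. A zero table margin leaves the
statistic undefined; such variants are flagged, not errors.

Two allele-frequency conventions coexist deliberately:

- **association output** reports unflipped alternate-allele
  frequencies F_A = a/(a+b), F_U = c/(c+d) (keep-allele-order), so
  direction of effect is readable and the odds ratio OR = ad/bc has
  the asymmetric rendering the convention forces: `NA` exactly when
  bc = 0, `0` exactly when ad = 0 with bc > 0;
- **QC** uses the pooled minor-allele frequency min(f, 1−f).

### Hardy–Weinberg exact test

QC uses the exact conditional test: given the observed allele totals,
the heterozygote count follows a discrete distribution with known
rational probabilities; the two-sided p sums the probabilities of all
heterozygote counts no more likely than the observed one. The
implementation uses the numerically stable mode-seeded recurrence and
is verified, for every genotype table with up to 50 alleles, against
an exact-rational full-enumeration oracle. HWE is computed on all
samples pooled — the cohort is unrelated, so no founder restriction
applies; note that some association tools would instead restrict the
HWE filter to controls in case/control data.

### QC defaults

Per variant, checked in order (first failing rule logged):
missing-call fraction > 0.1; pooled MAF < 0.05; HWE exact p < 1e-7.
These are the conventional thresholds for small-cohort association
scans.

### Multiple testing

Bonferroni (min(1, m·p)) and Benjamini–Hochberg (step-up with
enforced monotonicity, via `statsmodels`) are computed side by side;
BH is the default `p_adj`. The BH route is verified against a
hand-worked step-up calculation frozen in the tests. Reported
statistics are formatted at 4 significant figures, matching the
precision at which such tables are customarily printed; tests compare
at printed precision, not machine epsilon.

## Consequence severity

Sequence-ontology consequence terms are ranked by a packaged severity
table mirroring the canonical VEP ordering. The ten top-ranked terms
(transcript_ablation, splice_acceptor_variant, splice_donor_variant,
stop_gained, frameshift_variant, stop_lost, start_lost,
transcript_amplification, feature_elongation, feature_truncation)
form the "most severe" block used in prioritization, and a unit test
asserts the block against the table. Per-variant severity is the
minimum rank over all of its (transcript/gene) annotations, with
lexicographic tie-break for determinism. Unknown terms are retained,
flagged, and ranked after every known term so new ontology releases
degrade gracefully. Annotations join to variants on the uploaded
variant identifier; real VEP output using default
`chrom_pos_ref/alt`-style identifiers must be keyed consistently by
the caller.

## Case-exclusive filter and prioritization

A variant passes when (a) every **non-missing** control call is
homozygous reference and (b) at least one case carries the alternate
allele. A missing control genotype is not evidence of carriage: the
decision uses observed calls only, and the number of missing controls
is logged per variant so a reader can judge the strength of the
exclusivity claim. Prioritization keeps variants with raw p below a
threshold (default 0.05) and sorts by (severity rank, p); a stricter
listing threshold (default 0.005) produces the headline table with
one row per variant (its most severe gene annotation).

## Co-occurrence and genes of interest

Per gene, the C_A values of its distinct case-exclusive significant
variants are summed (a variant annotated to several genes counts
toward each; within a gene each site counts once). The multi-variant
route keeps genes with ≥ 2 variants and allele sum ≥ 10 — the
threshold printed with the reference gene table; a stricter preset
(≥ 3 variants, sum ≥ 14) reflects an alternative cut quoted in prose
and is exposed but not default. The GOI set is the union of the
single-variant route (genes of listing variants) and the multi-variant
route; the construction treats overlap between the routes as an error
because disjointness is an invariant of the two definitions as used
here (a listing variant needs p < 0.005, i.e. C_A ≥ 8 under full
genotyping, while multi-route genes consist of weaker variants).

## PPI network

Edges carry integer `combined_score` ∈ [0, 1000]; self-loops are
dropped and duplicate unordered pairs merged keeping the maximum
score. Absolute-score filtering can delete every edge of a gene whose
best partner scores below the cutoff, so scores are normalized per
gene: with M(x) the maximum score incident to x, each edge gets
norm_score = s/min(M(u), M(v)). Every non-isolated node then retains
a norm-1 edge (asserted as a property test). The alternative
convention — normalizing each edge twice, once per endpoint — is not
used.

Threshold selection inspects the score histogram (default bin width
25 raw / 0.025 normalized) expressed as percent of all interactions:
the reported minimum is the interior argmin over the occupied support
of the histogram, accepted only when strictly larger mass exists on
both sides; flat or monotone histograms report no minimum plus a
warning, with 800 (raw) and 0.8 (normalized) as the conventional
fallbacks. Kernel-density views of the same distribution are
visualization, not part of the decision rule.

Subnetwork extraction from seed genes: S1 = seeds present in the
graph plus all their neighbors; S2 = S1 plus any node with at least
two neighbors in S1; the result is the subgraph induced by S2. The
expansion is applied exactly once (iterating to fixpoint would grow
the set unboundedly and is deliberately not the default). "Distance
one" is measured from S1, the only reading under which the rule adds
nodes beyond immediate neighbors. Components are ordered by size
descending, ties by smallest label, so "component 1" is always the
largest.

## Synthetic data

The generator emits the exact formats the readers consume (plain-text
VCF 4.2, phenotype TSV, VEP-style TSV, STRING-style links) plus truth
manifests. The default cohort is 12 cases / 11 controls. Null
variants draw per-chromosome alleles binomially at a frequency
uniform in [0.05, 0.5], identically in both groups. Planted
case-exclusive variants place exactly C_A alternate alleles on case
chromosomes (heterozygotes first) and none in controls; the default
study-like structure plants four single-variant genes at C_A = 11,
10, 9, 8 and eight multi-variant genes with per-variant counts
summing to ≥ 10 (31, 30, 16, 14, 12, 12, 12, 10). C_A = 8 is the
weakest single surviving the 0.005 listing cut under full genotyping
(χ² = 8.88, p = 0.0029); weaker published rows (χ² = 8.324 at
C_A = 7) arise only with a missing case genotype and are reproduced
by the acceptance script with explicit missing calls, not planted by
default. Missingness is applied per call after planting and, by
default, never erases a planted carrier, so the observable C_A equals
the specification; a flag disables the protection for robustness
testing.

The generator deliberately omits linkage disequilibrium, population
structure, genotyping error, and sequencing artifacts: the analysis
under test treats variants independently, so passing tests certify
the statistical machinery, not robustness to those real-data
features.

Synthetic PPI graphs combine Erdős–Rényi background edges with
truncated-normal scores (mode ≈ 400) and a planted high-confidence
module (mode ≈ 950, pairwise edge probability 0.9), yielding the
bimodal score histogram with an interior minimum between the modes
that the threshold-detection rule expects.

## Calibration and problem sizes

- Null calibration uses 10,000 simulated null variants (runs in
  ≈ 1 s): the 0.05-level rejection rate must fall within 3 binomial
  standard errors of 0.05, and the Kolmogorov–Smirnov discrepancy
  against uniform must stay below 0.1 — a tolerance set by the
  discreteness of 2×2 tables at ≈ 46 alleles, where the p-value
  distribution is a step function.
- HWE equivalence is checked exhaustively for all 3,275 genotype
  tables with ≤ 25 samples; subnetwork extraction against brute force
  over 300 seeded random graphs of ≤ 12 nodes; components against a
  transitive-closure oracle at 50 nodes.
- The end-to-end determinism check runs the full pipeline twice on a
  100-null-variant fixture and requires byte-identical outputs; the
  run manifest therefore records the configuration without the output
  directory, and timings go only to the log.

## Known limitations

- No logistic regression, covariates, population-structure
  correction, or confidence intervals on OR; the allelic χ² is
  approximate at these allele counts (hence the calibration test, not
  an exactness claim).
- No compound-heterozygote phasing and no dominance/recessive models
  in the case-exclusive filter.
- No gene-symbol ↔ STRING-identifier mapping; the caller must supply
  consistent identifiers across the annotation table and the links
  file.
- The co-occurrence aggregation is a plain sum — not a weighted
  burden statistic — by design.
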