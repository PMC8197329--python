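# Methods

## Scientific setting

`pairconcord` analyses targeted-panel somatic variant calls from patients
with colorectal cancer who have both a primary-site and a metastatic-site
tumor sample. The central question is genomic concordance: what fraction of
clinically significant mutations is shared between the two tumors of a
patient, and how does sharing vary by gene, variant type, and the timing of
metastasis? High concordance in actionable driver genes supports using
archived primary-tumor tissue for treatment decisions in the metastatic
setting.

## Clinical-significance filter

A variant is retained when all three criteria hold:

1. **Protein-altering class** — missense SNV, nonsense SNV, indel, or
   splice-site. Synonymous and other classes (including multi-nucleotide
   substitutions, which the cBioPortal reader maps to `other` and logs) are
   discarded.
2. **Population rarity** — gnomAD total **and** East-Asian allele frequency
   ≤ 0.1% (`maf_threshold = 0.001`, boundary inclusive). A variant absent
   from gnomAD passes: absence from a population database is evidence of
   rarity, and the alternative — discarding unannotated somatic variants —
   would empty the call set.
3. **Probable pathogenicity** — ClinVar significance in {Pathogenic, Likely
   pathogenic, Drug response} **or** OncoKB oncogenicity in {Oncogenic,
   Likely Oncogenic, Predicted Oncogenic}. Matching is case-insensitive on
   exact tokens after normalizing underscores; multi-valued ClinVar cells
   pass if any token is accepted.

The filter is total, order-preserving, idempotent on its kept set, and
monotone in the rarity threshold; all three are property-tested.

## Pair matching and concordance accounting

Variants are matched within a patient on the exact nucleotide key
(gene, chrom, pos, ref, alt). Protein-level matching would merge distinct
nucleotide events at the same residue and understate discordance, so it is
not used. Buckets are pure set algebra: shared, primary-only,
metastatic-only.

Counting conventions, fixed by mutual consistency of the cohort-level
summaries:

- **Event-level**: a shared variant is one *event*; overall concordance is
  `n_shared / (n_shared + n_primary_only + n_metastatic_only)`. Per-gene and
  per-class concordances use the same event denominators (a patient-level
  per-gene variant is available via `gene_frequencies`).
- **Per-sample averages**: a shared variant appears once in each sample, so
  the mean number of concordant variants per sample is `2·n_shared /
  n_pairs`, and discordant `n_discordant / n_pairs`.
- **Pair-level**: per-pair concordance is `shared / (shared + discordant)`;
  pairs with zero filtered variants are excluded from the mean and logged.

## Statistical tests

- **Stratum and cohort proportion contrasts** (concordance by metastasis
  timing, gene frequency between cohorts, variant-class composition): the
  two-sided pooled-variance two-proportion z-test. Equal sample proportions
  return p = 1 exactly, which also covers the degenerate 0%/100% pooled
  corner.
- **Paired VAF comparison**: two-sided paired t-test on (primary VAF,
  metastatic VAF) couples of *shared* variants — discordant variants have no
  partner VAF. A zero-variance nonzero difference reports machine-epsilon
  with a warning; zero difference reports p = 1.
- **Clinical associations**: mutation status × covariate contingency tables.
  Fisher's exact test when any expected cell is < 5 and the table is 2×2,
  otherwise the chi-square test *without* continuity correction — the
  uncorrected statistic is calibrated at nominal level for the table sizes
  this package meets, whereas the Yates correction is conservative; sparse
  R×C tables fall back to chi-square with a warning. Zero-margin tables are
  uninformative and return p = 1.
- **Survival**: Kaplan–Meier product-limit estimator with right censoring
  (lifelines) by mutation status, log-rank test for two groups. Recurrence
  times are compared by a two-sided Wilcoxon rank-sum test on observed
  recurrence days; a log-rank treating recurrence as the event is possible
  upstream but the rank-sum on recorded times is the documented default.
- No multiple-testing correction is applied by default, matching the raw
  per-test reporting style of the analyses this package reproduces;
  Benjamini–Hochberg can be layered on the returned p-values.

## MSI classification

Bethesda five-marker panel (BAT25, BAT26, D5S346, D2S123, D17S250): ≥ 2
unstable markers → MSI-H; exactly 1 → MSI-L; 0 unstable with ≥ 4 evaluable
markers → MSS; otherwise unknown. The evaluable-marker guard is a
conservative treatment of partially failed panels: a mostly-failed panel
with no observed instability is not declared stable. The rule is monotone
(flipping a marker to unstable never moves the call toward MSS) and
order-invariant, both property-tested.

## Synthetic cohort generator

The generator emulates a 95-pair metastatic CRC study arm with 4
primary-only and 47 metastatic-only singletons (146 patients). For each
patient and gene: mutation with gene-specific per-patient frequency; a
mutated pair draws `1 + Poisson(mean_variants − 1)` distinct variants; each
variant is truncal with probability `c_g ± δ/2` (synchronous `+`,
metachronous `−`, clipped to [0, 1], `δ = 0.06`, 55% synchronous), emitted in
both samples under the same nucleotide key; private variants go to the
primary with probability ρ = 0.62. VAFs: truncal ~ Beta(4, 12) (mean 0.25)
per role, subclonal ~ Beta(2, 18) (mean 0.10); TP53 truncal metastatic VAFs
carry a +0.09 additive shift. MSI-H prevalence 5%, with SMAD4 frequency
multiplied by an enrichment odds of 5 in MSI-H patients
(`expected_gene_frequency` gives the resulting marginal). Decoy variants —
30% of the kept count per filter criterion, each violating exactly one
criterion and placed in a reserved coordinate block so they never collide
with a kept key — exercise the filter with unambiguous ground truth.
Survival is exponential (mean 900 days) with uniform censoring on
[100, 2000] days; recurrence times are exponential with median 294 days
(137 days for FBXW7-mutant patients), recorded for half the patients.

Gene defaults: frequencies follow the study marginals
(APC 0.71, TP53 0.54, KRAS 0.45, PIK3CA 0.16, SMAD4 0.15, FBXW7 0.11, plus
a tail of rare panel genes at 2–5%); per-gene truncal concordances keep the
published per-gene pattern (KRAS 0.98, NRAS/FBXW7/PTEN/BRCA2 1.0, APC 0.90,
TP53 0.91, PIK3CA 0.70, SMAD4 0.61, ERBB2/PIK3R1/TSC1/VHL 0.40). The
reported per-gene concordances of the top genes and the ~81% overall
event-level concordance over the whole panel are mutually consistent only
if the rare panel genes share far less than the drivers, so the rare-gene
tail defaults to 0.40–0.60; the resulting cohort expectation is ≈ 0.82.
This is a calibration of the simulation to published marginals, not ground
truth about any real cohort.

What the generator deliberately does **not** model: shared subclonal
phylogeny between samples (private variants are independent across the two
samples), copy-number events, sequencing error, read-level data,
hypermutated outliers, and panel footprint effects. Passing
parameter-recovery and calibration tests therefore demonstrates the
statistics are implemented correctly under the stated sampling model — not
that the model captures every feature of real paired cohorts.

Determinism: all randomness flows from one `numpy` `default_rng(seed)`;
identical parameters and seed give byte-identical output files.

## Numerical choices and degenerate inputs

- Rarity boundary: `af ≤ threshold` keeps the variant (inclusive).
- Equal proportions short-circuit to z = 0, p = 1 before the pooled-variance
  division.
- Per-pair concordance is undefined (excluded, logged) for zero-variant
  pairs; `concordance_report` refuses empty pair lists.
- Shared-event class disagreements between the matched records warn and use
  the primary record's class.
- Ranked frequency tables break count ties alphabetically for deterministic
  output.
- Duplicate variant rows are dropped at read time with a warning; duplicate
  keys *within* one sample at classification time are an error.

## Problem sizes used in the test suite

Chosen as the package's own verification budget: Fisher vs hypergeometric
enumeration exhaustively over all 2×2 tables with n ≤ 40; type-I
calibration with 1000 replicate null cohorts (60 pairs for the stratified
z-test; 142 singleton patients for associations); log-rank calibration with
500 replicates of 60 patients; parameter recovery over 50 seeds of the full
95-pair default cohort, scored with exact central binomial / t intervals.

## Known limitations

- The two-proportion z-test is asymptotic; with very few variant events per
  stratum its calibration degrades (the generator's defaults provide ~150
  events per stratum).
- `frequency_table_from_records` infers the denominator from distinct
  patient ids when no manifest accompanies a reference MAF; patients with
  zero kept variants must be supplied via the explicit `n_patients`
  argument to avoid denominator bias.
- MSI marker calls are consumed as boolean stability calls; fragment-size
  signal processing is upstream of this package.
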