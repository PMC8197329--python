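# pairconcord

Genomic concordance analysis for paired primary–metastatic tumor cohorts.

When a colorectal cancer patient has both the primary tumor and a distant
metastasis sequenced on a targeted cancer-gene panel, the two samples can be
compared mutation by mutation. `pairconcord` implements that comparison as a
reusable, tested pipeline for molecular pathologists and translational
researchers: it filters annotated variant calls down to the clinically
significant set, matches variants within each patient pair, quantifies
concordance at the cohort, gene, variant-class, and pair level, classifies
microsatellite instability from Bethesda-panel marker calls, and tests
clinical associations and survival differences by mutation status. A fully
parameterized synthetic paired-cohort generator with ground-truth
bookkeeping makes every stage testable without any patient data.

## The statistics at its core

For each patient with samples from both sites, filtered variants are matched
on the exact nucleotide key *(gene, chrom, pos, ref, alt)* and partitioned
into shared (*S*), primary-only (*P*), and metastatic-only (*M*) events.

- overall concordance = |S| / (|S| + |P| + |M|), with per-gene and
  per-variant-class analogues;
- per-sample averages count a shared variant once per pair member:
  concordant per sample = 2|S| / n_pairs;
- stratum contrasts (synchronous vs. metachronous metastasis) use the
  two-sided pooled two-proportion z-test on pooled event counts;
- VAF shifts between sites use a paired t-test on shared-variant
  (VAF_primary, VAF_metastatic) couples;
- gene frequencies are patient-level (a patient counts once per gene) and
  cohorts are compared gene-wise with the same z-test, also for external
  reference MAFs in cBioPortal dialect;
- mutation × covariate associations use Fisher's exact test for sparse 2×2
  tables and the chi-square test otherwise; overall survival uses
  Kaplan–Meier curves with a log-rank test.

The clinical-significance filter keeps protein-altering variants that are
rare in gnomAD (total and East-Asian AF ≤ 0.1%) and carry ClinVar
(Pathogenic / Likely pathogenic / Drug response) or OncoKB (Oncogenic /
Likely Oncogenic / Predicted Oncogenic) support. MSI status follows the
five-marker Bethesda rule (≥2 unstable markers → MSI-H, 1 → MSI-L, 0 →
MSS). Details, conventions, and edge-case policy are in
[docs/methods.md](docs/methods.md).

## Worked example

Generate the default synthetic cohort (95 pairs plus singletons, 146
patients), filter, match, and summarize:

```python
from pairconcord.concordance import concordance_report
from pairconcord.filtering import apply_filter, kept_variants
from pairconcord.model import Cohort
from pairconcord.pipeline import classify_cohort_pairs
from pairconcord.simulate import SimulationParams, generate
from pairconcord import stats as cstats

result = generate(SimulationParams(seed=1))
decisions = apply_filter(result.cohort.variants)
cohort = Cohort(variants=kept_variants(decisions), patients=result.cohort.patients)
classifications = classify_cohort_pairs(cohort)
report = concordance_report(classifications)

print(f"kept {len(cohort.variants)} of {len(result.cohort.variants)} variants")
print(f"overall concordance: {report.overall_concordance:.1%} "
      f"({report.n_shared}/{report.n_variants})")
for gene in ("APC", "KRAS", "SMAD4"):
    gc = report.per_gene[gene]
    print(f"{gene}: {gc.concordance:.0%} concordant ({gc.n_shared}/{gc.n_total})")
vaf = cstats.paired_vaf_test(classifications, "TP53")
print(f"TP53 VAF primary {vaf.mean_primary:.2f} vs metastatic {vaf.mean_metastatic:.2f} "
      f"(paired t, p = {vaf.p_value:.4f})")
```

prints

```
kept 676 of 1285 variants
overall concordance: 83.2% (238/286)
APC: 90% concordant (77/86)
KRAS: 98% concordant (44/45)
SMAD4: 76% concordant (13/17)
TP53 VAF primary 0.28 vs metastatic 0.33 (paired t, p = 0.0400)
```

Half the generated rows are decoys that violate exactly one filter
criterion; the filter removes them all (the generator's ground-truth
bookkeeping confirms kept/discarded labels match exactly). Of 286 matched
variant events across the 95 pairs, 83.2% are present in both tumors; the
early driver KRAS is almost fully shared while the later driver SMAD4 is
not; and TP53 variant allele frequencies are significantly higher in the
metastasis, consistent with clonal expansion of TP53-mutant cells during
metastatic outgrowth.

The same analyses are available from the shell:

```sh
concord simulate --seed 1 --out sim/
concord run --config run.yaml          # full pipeline with provenance manifest
concord freq --variants sim/variants.tsv --manifest sim/manifest.tsv --scope primary
concord msi --marker-calls sim/msi_markers.tsv
```

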