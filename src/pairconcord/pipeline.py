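"""End-to-end pipeline: load -> panel restriction -> significance filter ->
pair classification -> concordance report -> cohort statistics, with a
provenance manifest so a run is reproducible and auditable.

Every output directory contains a ``run_manifest.json`` recording the config
hash, seed, package version and row counts of each emitted table; re-running
with identical inputs and config is byte-identical.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

import pairconcord
from pairconcord import io as pio
from pairconcord.concordance import (
    PairClassification,
    classify_pair,
    concordance_report,
    stratified_concordance_test,
)
from pairconcord.filtering import FilterConfig, apply_filter, kept_variants
from pairconcord.model import Cohort, MsiStatus, SampleRole, Timing, VariantClass
from pairconcord.msi import classify_cohort
from pairconcord import stats as cstats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    variants: Path
    manifest: Path
    out_dir: Path
    marker_calls: Optional[Path] = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    panel: Optional[list[str]] = None  # None = accept every observed gene
    seed: int = 0
    stratify_by_timing: bool = True
    vaf_genes: Optional[list[str]] = None  # None = all genes with enough pairs
    association_genes: list[str] = field(default_factory=list)
    association_covariates: list[str] = field(default_factory=list)
    survival_gene: Optional[str] = None

    def __post_init__(self) -> None:
        self.variants = Path(self.variants)
        self.manifest = Path(self.manifest)
        self.out_dir = Path(self.out_dir)
        for p in (self.variants, self.manifest):
            if not p.exists():
                raise FileNotFoundError(p)
        if self.panel is not None and not self.panel:
            raise ValueError("panel must be non-empty when given")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        kwargs = dict(raw)
        for key in ("variants", "manifest", "out_dir", "marker_calls"):
            if kwargs.get(key) is not None:
                p = Path(kwargs[key])
                kwargs[key] = p if p.is_absolute() else base / p
        if "filter" in kwargs and isinstance(kwargs["filter"], dict):
            kwargs["filter"] = FilterConfig.from_dict(kwargs["filter"])
        return cls(**kwargs)

    def digest(self) -> str:
        payload = {
            "variants": str(self.variants),
            "manifest": str(self.manifest),
            "marker_calls": str(self.marker_calls) if self.marker_calls else None,
            "filter": {
                "maf_threshold": self.filter.maf_threshold,
                "clinvar_accept": sorted(self.filter.clinvar_accept),
                "oncokb_accept": sorted(self.filter.oncokb_accept),
                "protein_altering_classes": sorted(
                    c.value for c in self.filter.protein_altering_classes
                ),
            },
            "panel": sorted(self.panel) if self.panel else None,
            "seed": self.seed,
            "stratify_by_timing": self.stratify_by_timing,
            "vaf_genes": self.vaf_genes,
            "association_genes": self.association_genes,
            "association_covariates": self.association_covariates,
            "survival_gene": self.survival_gene,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> int:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)
    return len(rows)


def classify_cohort_pairs(cohort: Cohort, variants=None) -> list[PairClassification]:
    """Classify every complete pair of the cohort (kept variants only)."""
    variants = cohort.variants if variants is None else variants
    by_sample: dict[str, list] = {}
    for v in variants:
        by_sample.setdefault(v.sample_id, []).append(v)
    out = []
    for p in cohort.pairs:
        out.append(
            classify_pair(
                by_sample.get(p.primary_sample_id, []),
                by_sample.get(p.metastatic_sample_id, []),
                patient_id=p.patient_id,
            )
        )
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    row_counts: dict[str, int] = {}
    try:
        cohort = pio.load_cohort(config.variants, config.manifest)
    except Exception as exc:
        raise RuntimeError(f"stage load: {exc}") from exc

    if config.marker_calls is not None:
        calls = pio.read_marker_calls(config.marker_calls)
        statuses = classify_cohort(calls)
        for p in cohort.patients:
            if p.patient_id in statuses:
                p.msi_status = statuses[p.patient_id]

    variants = cohort.variants
    if config.panel is not None:
        panel = set(config.panel)
        n_before = len(variants)
        variants = [v for v in variants if v.gene in panel]
        logger.info("panel restriction dropped %d variants", n_before - len(variants))

    try:
        decisions = apply_filter(variants, config.filter)
    except Exception as exc:
        raise RuntimeError(f"stage filter: {exc}") from exc
    kept = kept_variants(decisions)
    pio.write_variant_table(kept, out / "filtered_variants.tsv")
    row_counts["filtered_variants.tsv"] = len(kept)

    summary: dict = {"n_input_variants": len(cohort.variants), "n_kept_variants": len(kept)}
    filtered_cohort = Cohort(variants=kept, patients=cohort.patients, name=cohort.name)

    classifications = classify_cohort_pairs(filtered_cohort)
    if classifications:
        try:
            report = concordance_report(classifications)
        except Exception as exc:
            raise RuntimeError(f"stage concordance: {exc}") from exc
        row_counts["per_gene.tsv"] = _write_tsv(
            out / "per_gene.tsv",
            ["gene", "n_total", "n_shared", "concordance"],
            [
                [g, gc.n_total, gc.n_shared, f"{gc.concordance:.6f}"]
                for g, gc in sorted(report.per_gene.items())
            ],
        )
        row_counts["per_class.tsv"] = _write_tsv(
            out / "per_class.tsv",
            ["variant_class", "n_total", "n_shared", "concordance"],
            [
                [c.value, gc.n_total, gc.n_shared, f"{gc.concordance:.6f}"]
                for c, gc in sorted(report.per_class.items(), key=lambda kv: kv[0].value)
            ],
        )
        row_counts["per_pair.tsv"] = _write_tsv(
            out / "per_pair.tsv",
            ["patient_id", "n_shared", "n_discordant", "concordance"],
            [
                [pid, s.n_shared, s.n_discordant,
                 "" if s.concordance is None else f"{s.concordance:.6f}"]
                for pid, s in sorted(report.per_pair.items())
            ],
        )
        summary["concordance"] = {
            "n_pairs": report.n_pairs,
            "n_variants": report.n_variants,
            "n_shared": report.n_shared,
            "n_primary_only": report.n_primary_only,
            "n_metastatic_only": report.n_metastatic_only,
            "overall_concordance": report.overall_concordance,
            "mean_pair_concordance": report.mean_pair_concordance,
            "mean_concordant_per_pair": report.mean_concordant_per_pair,
            "mean_discordant_per_pair": report.mean_discordant_per_pair,
        }

        if config.stratify_by_timing:
            strata: dict[str, list[PairClassification]] = {}
            timing_by_pid = {p.patient_id: p.metastasis_timing for p in cohort.patients}
            for cls in classifications:
                t = timing_by_pid.get(cls.patient_id, Timing.UNKNOWN)
                if t is not Timing.UNKNOWN:
                    strata.setdefault(t.value, []).append(cls)
            if len(strata) == 2 and all(strata.values()):
                reports = {k: concordance_report(v) for k, v in strata.items()}
                if all(r.n_variants > 0 for r in reports.values()):
                    props, p_conc = stratified_concordance_test(reports, "concordance")
                    props_po, p_po = stratified_concordance_test(reports, "primary_only_fraction")
                    summary["timing_strata"] = {
                        "concordance": {"proportions": props, "p_value": p_conc},
                        "primary_only_fraction": {"proportions": props_po, "p_value": p_po},
                    }

        vaf_genes = config.vaf_genes
        if vaf_genes is None:
            counts: dict[str, int] = {}
            for cls in classifications:
                for prim, met in cls.shared:
                    if prim.vaf is not None and met.vaf is not None:
                        counts[prim.gene] = counts.get(prim.gene, 0) + 1
            vaf_genes = sorted(g for g, n in counts.items() if n >= 2)
        vaf_rows = []
        for gene in vaf_genes:
            try:
                cmp = cstats.paired_vaf_test(classifications, gene)
            except ValueError as exc:
                logger.warning("vaf test skipped: %s", exc)
                continue
            vaf_rows.append(
                [gene, cmp.n_variant_pairs, f"{cmp.mean_primary:.4f}", f"{cmp.sd_primary:.4f}",
                 f"{cmp.mean_metastatic:.4f}", f"{cmp.sd_metastatic:.4f}", f"{cmp.p_value:.6g}"]
            )
        row_counts["vaf_comparison.tsv"] = _write_tsv(
            out / "vaf_comparison.tsv",
            ["gene", "n_variant_pairs", "mean_primary", "sd_primary",
             "mean_metastatic", "sd_metastatic", "p_value"],
            vaf_rows,
        )

    for scope in (SampleRole.PRIMARY, SampleRole.METASTATIC):
        try:
            table = cstats.gene_frequencies(filtered_cohort, scope)
        except ValueError:
            continue
        row_counts[f"freq_{scope.value}.tsv"] = _write_tsv(
            out / f"freq_{scope.value}.tsv",
            ["gene", "n_mutated_patients", "frequency"],
            [[g, n, f"{f:.6f}"] for g, n, f in table.ranked()],
        )
        summary.setdefault("gene_frequencies", {})[scope.value] = {
            "n_patients": table.n_patients
        }

    if config.association_genes and config.association_covariates:
        results = cstats.association_tests(
            filtered_cohort, config.association_genes, config.association_covariates
        )
        row_counts["associations.tsv"] = _write_tsv(
            out / "associations.tsv",
            ["gene", "covariate", "test", "p_value", "levels", "wild_type_counts", "mutated_counts"],
            [
                [r.gene, r.covariate, r.test, f"{r.p_value:.6g}", ",".join(r.levels),
                 ",".join(map(str, r.table[0])), ",".join(map(str, r.table[1]))]
                for r in results
            ],
        )

    if config.survival_gene is not None:
        try:
            surv = cstats.survival_summary(filtered_cohort, config.survival_gene)
            summary["survival"] = {
                "gene": surv.gene,
                "logrank_p": surv.logrank_p,
                "median_recurrence_by_status": surv.median_recurrence_by_status,
                "recurrence_p": surv.recurrence_p,
            }
        except ValueError as exc:
            logger.warning("survival summary skipped: %s", exc)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(
            {
                "config_hash": config.digest(),
                "seed": config.seed,
                "version": pairconcord.__version__,
                "row_counts": dict(sorted(row_counts.items())),
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return out
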