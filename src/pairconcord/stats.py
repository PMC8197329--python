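"""Cohort-level statistics: gene mutation frequencies, cross-cohort
comparisons, paired VAF tests, variant-type composition, hotspot tables,
clinical association tests, and survival summaries.

Frequencies are patient-level: a patient is "mutated" in a gene when at
least one filtered variant of that gene is present in the scoped sample,
and denominators count patients with a scoped sample.  VAF comparisons are
variant-level and restricted to shared variants, which are the only events
with a VAF on both sides of a pair.
"""

from __future__ import annotations

import logging
import math
import re
import sys
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps

from pairconcord.concordance import PairClassification
from pairconcord.model import (
    PROTEIN_ALTERING,
    Cohort,
    SampleRole,
    VariantClass,
    VariantRecord,
)
from pairconcord.stattests import two_proportion_ztest

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# gene frequencies


@dataclass
class GeneFrequencyTable:
    cohort_name: str
    n_patients: int
    rows: dict[str, tuple[int, float]]  # gene -> (n_mutated_patients, frequency)

    def frequency(self, gene: str) -> float:
        return self.rows.get(gene, (0, 0.0))[1]

    def ranked(self) -> list[tuple[str, int, float]]:
        """Rows sorted by descending count, ties broken alphabetically."""
        return sorted(
            ((g, n, f) for g, (n, f) in self.rows.items()),
            key=lambda r: (-r[1], r[0]),
        )


def _scoped_sample_ids(cohort: Cohort, scope: SampleRole) -> dict[str, str]:
    """patient_id -> scoped sample id, for patients having that sample."""
    out = {}
    for p in cohort.patients:
        sid = p.primary_sample_id if scope is SampleRole.PRIMARY else p.metastatic_sample_id
        if sid is not None:
            out[p.patient_id] = sid
    return out


def gene_frequencies(cohort: Cohort, scope: SampleRole) -> GeneFrequencyTable:
    """Patient-level mutation frequency per gene within one sample scope."""
    scoped = _scoped_sample_ids(cohort, scope)
    if not scoped:
        raise ValueError(f"no {scope.value} samples in cohort {cohort.name!r}")
    mutated: dict[str, set[str]] = {}
    for v in cohort.variants:
        if v.sample_role is scope and scoped.get(v.patient_id) == v.sample_id:
            mutated.setdefault(v.gene, set()).add(v.patient_id)
    n = len(scoped)
    rows = {g: (len(pids), len(pids) / n) for g, pids in mutated.items()}
    return GeneFrequencyTable(f"{cohort.name}:{scope.value}", n, rows)


def frequency_table_from_records(
    records: Sequence[VariantRecord], name: str, n_patients: Optional[int] = None
) -> GeneFrequencyTable:
    """Build a frequency table straight from a (reference-cohort) variant list.

    For cBioPortal-style files with no manifest the denominator defaults to
    the number of distinct patients observed in the file.
    """
    patients = {v.patient_id for v in records}
    n = n_patients if n_patients is not None else len(patients)
    if n <= 0:
        raise ValueError("cohort has zero patients")
    mutated: dict[str, set[str]] = {}
    for v in records:
        mutated.setdefault(v.gene, set()).add(v.patient_id)
    rows = {g: (len(p), len(p) / n) for g, p in mutated.items()}
    return GeneFrequencyTable(name, n, rows)


def compare_frequencies(
    table_a: GeneFrequencyTable,
    table_b: GeneFrequencyTable,
    assume_zero: bool = True,
) -> dict[str, tuple[float, float, float]]:
    """Per-gene two-sample proportion z-test between two cohorts.

    Returns gene -> (freq_a, freq_b, p).  With ``assume_zero`` (default) a
    gene absent from one table is treated as 0 mutated patients out of that
    table's n; otherwise only genes present in both tables are compared —
    the right choice when the two cohorts were sequenced on different gene
    panels.
    """
    if table_a.n_patients == 0 or table_b.n_patients == 0:
        raise ValueError("both cohorts must be non-empty")
    genes = (
        set(table_a.rows) | set(table_b.rows)
        if assume_zero
        else set(table_a.rows) & set(table_b.rows)
    )
    out = {}
    for g in sorted(genes):
        na, fa = table_a.rows.get(g, (0, 0.0))
        nb, fb = table_b.rows.get(g, (0, 0.0))
        _, p = two_proportion_ztest([na, nb], [table_a.n_patients, table_b.n_patients])
        out[g] = (fa, fb, p)
    return out


# ---------------------------------------------------------------------------
# paired VAF comparison


@dataclass
class VafComparison:
    gene: str
    n_variant_pairs: int
    mean_primary: float
    sd_primary: float
    mean_metastatic: float
    sd_metastatic: float
    p_value: float

    @property
    def mean_shift(self) -> float:
        return self.mean_metastatic - self.mean_primary


def paired_vaf_test(
    classifications: Sequence[PairClassification], gene: str
) -> VafComparison:
    """Two-sided paired t-test on (primary VAF, metastatic VAF) couples of
    shared variants in one gene.

    Raises ``ValueError`` when fewer than two shared variant pairs carry a
    VAF on both sides.
    """
    pairs = [
        (p.vaf, m.vaf)
        for cls in classifications
        for p, m in cls.shared
        if p.gene == gene and p.vaf is not None and m.vaf is not None
    ]
    if len(pairs) < 2:
        raise ValueError(f"gene {gene}: only {len(pairs)} usable VAF pairs (need >= 2)")
    prim = np.array([a for a, _ in pairs])
    met = np.array([b for _, b in pairs])
    diffs = met - prim
    sd_diff = float(np.std(diffs, ddof=1))
    if sd_diff == 0.0:
        if float(np.mean(diffs)) == 0.0:
            p = 1.0
        else:
            logger.warning("gene %s: zero-variance nonzero paired difference", gene)
            p = sys.float_info.epsilon
    else:
        p = float(sps.ttest_rel(met, prim).pvalue)
    return VafComparison(
        gene=gene,
        n_variant_pairs=len(pairs),
        mean_primary=float(prim.mean()),
        sd_primary=float(np.std(prim, ddof=1)),
        mean_metastatic=float(met.mean()),
        sd_metastatic=float(np.std(met, ddof=1)),
        p_value=p,
    )


# ---------------------------------------------------------------------------
# variant-type composition


def variant_type_composition(
    variants: Sequence[VariantRecord], by_gene: bool = False
) -> dict[str, dict[VariantClass, float]]:
    """Fractions of protein-altering classes, overall or per gene.

    Input is expected to be post-filter, so only the four protein-altering
    classes appear; fractions sum to one within each scope.
    """
    scopes: dict[str, list[VariantRecord]] = {}
    if by_gene:
        for v in variants:
            scopes.setdefault(v.gene, []).append(v)
    else:
        scopes["all"] = list(variants)
    out: dict[str, dict[VariantClass, float]] = {}
    for scope, vs in scopes.items():
        if not vs:
            raise ValueError(f"zero variants in scope {scope!r}")
        counts: dict[VariantClass, int] = {}
        for v in vs:
            counts[v.variant_class] = counts.get(v.variant_class, 0) + 1
        out[scope] = {c: n / len(vs) for c, n in counts.items()}
    if not out:
        raise ValueError("zero variants in scope")
    return out


def compare_composition(
    variants_a: Sequence[VariantRecord],
    variants_b: Sequence[VariantRecord],
    vclass: VariantClass,
) -> tuple[float, float, float]:
    """Compare the share of one variant class between two variant sets
    (two-sample proportion z-test); returns (frac_a, frac_b, p)."""
    if not variants_a or not variants_b:
        raise ValueError("both variant sets must be non-empty")
    xa = sum(1 for v in variants_a if v.variant_class is vclass)
    xb = sum(1 for v in variants_b if v.variant_class is vclass)
    _, p = two_proportion_ztest([xa, xb], [len(variants_a), len(variants_b)])
    return xa / len(variants_a), xb / len(variants_b), p


# ---------------------------------------------------------------------------
# hotspots

_HGVS_P_POSITION = re.compile(r"^p\.\(?(?:[A-Z][a-z]{2}|[A-Z*])(\d+)")


def protein_position(protein_change: str) -> Optional[int]:
    """First residue number of an HGVS.p string, or None if unparseable."""
    m = _HGVS_P_POSITION.match(protein_change.strip())
    return int(m.group(1)) if m else None


def hotspot_table(
    variants: Sequence[VariantRecord], gene: str
) -> dict[object, tuple[int, float]]:
    """Recurrence of protein positions in one gene.

    Returns position -> (count, fraction); fractions are over parseable
    variants.  Unparseable protein strings are tallied under the key
    ``"unknown"`` with fraction NaN and logged.
    """
    counts: dict[int, int] = {}
    n_unknown = 0
    for v in variants:
        if v.gene != gene:
            continue
        pos = protein_position(v.protein_change)
        if pos is None:
            n_unknown += 1
            logger.info("gene %s: unparseable protein change %r", gene, v.protein_change)
        else:
            counts[pos] = counts.get(pos, 0) + 1
    total = sum(counts.values())
    out: dict[object, tuple[int, float]] = {
        pos: (n, n / total) for pos, n in sorted(counts.items())
    }
    if n_unknown:
        out["unknown"] = (n_unknown, math.nan)
    return out


# ---------------------------------------------------------------------------
# clinical associations


@dataclass
class AssociationResult:
    gene: str
    covariate: str
    table: np.ndarray  # 2 x k: rows wild-type / mutated, columns covariate levels
    levels: list[str]
    test: str  # "fisher" or "chi2"
    p_value: float


def _mutation_indicator(cohort: Cohort, gene: str, scope: str) -> dict[str, bool]:
    """patient_id -> mutated flag, over patients with a sample in scope."""
    roles = {
        "primary": (SampleRole.PRIMARY,),
        "metastatic": (SampleRole.METASTATIC,),
        "any": (SampleRole.PRIMARY, SampleRole.METASTATIC),
    }[scope]
    eligible = {
        p.patient_id
        for p in cohort.patients
        if (SampleRole.PRIMARY in roles and p.primary_sample_id is not None)
        or (SampleRole.METASTATIC in roles and p.metastatic_sample_id is not None)
    }
    mutated = {
        v.patient_id
        for v in cohort.variants
        if v.gene == gene and v.sample_role in roles and v.patient_id in eligible
    }
    return {pid: pid in mutated for pid in eligible}


def fisher_p(table: np.ndarray) -> float:
    """Two-sided Fisher's exact p for a 2x2 table."""
    return float(sps.fisher_exact(np.asarray(table), alternative="two-sided")[1])


def contingency_test(table: np.ndarray) -> tuple[str, float]:
    """Fisher's exact test when any expected cell < 5 (2x2 only), else the
    chi-square test without continuity correction.

    A table with a zero margin carries no information; p = 1.
    """
    table = np.asarray(table)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    if n == 0 or (row == 0).any() or (col == 0).any():
        return "degenerate", 1.0
    expected = np.outer(row, col) / n
    if (expected < 5).any():
        if table.shape == (2, 2):
            return "fisher", fisher_p(table)
        logger.warning("sparse %sx%s table: chi-square may be unreliable", *table.shape)
    _, p, _, _ = sps.chi2_contingency(table, correction=False)
    return "chi2", float(p)


def association_tests(
    cohort: Cohort,
    genes: Iterable[str],
    covariates: Iterable[str],
    scope: str = "any",
) -> list[AssociationResult]:
    """Mutation status x clinical covariate contingency tests.

    For every (gene, covariate) a 2 x k table of wild-type / mutated patient
    counts across covariate levels is tested.  Covariates resolve against
    ``PatientPair.clinical`` first, then the named manifest fields
    (``msi_status``, ``metastasis_timing``, ``metastasis_site``).  Patients
    missing the covariate are excluded; single-level covariates are skipped
    with a warning.
    """
    results = []
    by_id = {p.patient_id: p for p in cohort.patients}
    for covariate in covariates:
        values: dict[str, str] = {}
        for pid, p in by_id.items():
            v = p.clinical.get(covariate)
            if v is None and covariate in ("msi_status", "metastasis_timing", "metastasis_site"):
                raw = getattr(p, covariate)
                v = getattr(raw, "value", raw) or None
                if v == "unknown":
                    v = None
            if v:
                values[pid] = v
        levels = sorted(set(values.values()))
        if len(levels) < 2:
            logger.warning("covariate %r has < 2 levels; skipped", covariate)
            continue
        for gene in genes:
            indicator = _mutation_indicator(cohort, gene, scope)
            table = np.zeros((2, len(levels)), dtype=int)
            for pid, level in values.items():
                if pid in indicator:
                    table[int(indicator[pid]), levels.index(level)] += 1
            test, p = contingency_test(table)
            results.append(
                AssociationResult(
                    gene=gene, covariate=covariate, table=table, levels=levels, test=test, p_value=p
                )
            )
    return results


# ---------------------------------------------------------------------------
# survival


@dataclass
class SurvivalSummary:
    gene: str
    km_by_status: dict[str, tuple[np.ndarray, np.ndarray]]  # status -> (times, S(t))
    logrank_p: Optional[float]
    n_events: int
    median_recurrence_by_status: dict[str, float]
    recurrence_p: Optional[float]


def survival_summary(cohort: Cohort, gene: str, scope: str = "any") -> SurvivalSummary:
    """Kaplan-Meier overall-survival curves by mutation status with a
    log-rank test, plus a recurrence-time comparison.

    OS uses the product-limit estimator with right censoring.  Recurrence
    times (when recorded) are compared between mutant and wild-type with a
    two-sided Wilcoxon rank-sum test; a log-rank on recurrence is available
    upstream by treating recurrence as the event of interest, but the plain
    rank-sum on observed recurrence times is the default.
    """
    indicator = _mutation_indicator(cohort, gene, scope)
    rows = [
        (("mutant" if indicator[p.patient_id] else "wild_type"), p)
        for p in cohort.patients
        if p.patient_id in indicator
    ]
    os_rows = [(s, p.os_days, bool(p.os_event)) for s, p in rows if p.os_days is not None and p.os_event is not None]
    n_events = sum(1 for _, _, e in os_rows if e)
    if n_events < 2:
        raise ValueError(f"gene {gene}: fewer than 2 overall-survival events")
    km_by_status: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    groups: dict[str, tuple[list[float], list[bool]]] = {}
    for status, t, e in os_rows:
        groups.setdefault(status, ([], []))[0].append(t)
        groups[status][1].append(e)
    for status, (times, events) in groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(times, event_observed=events)
        sf = kmf.survival_function_
        km_by_status[status] = (sf.index.to_numpy(float), sf.iloc[:, 0].to_numpy(float))
    logrank_p = None
    if len(groups) == 2:
        (ta, ea), (tb, eb) = (groups[s] for s in sorted(groups))
        logrank_p = float(logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb).p_value)

    rec: dict[str, list[float]] = {}
    for status, p in rows:
        if p.recurrence_days is not None:
            rec.setdefault(status, []).append(p.recurrence_days)
    median_rec = {s: float(np.median(v)) for s, v in rec.items()}
    recurrence_p = None
    if len(rec) == 2 and all(len(v) >= 1 for v in rec.values()):
        a, b = (rec[s] for s in sorted(rec))
        recurrence_p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return SurvivalSummary(
        gene=gene,
        km_by_status=km_by_status,
        logrank_p=logrank_p,
        n_events=n_events,
        median_recurrence_by_status=median_rec,
        recurrence_p=recurrence_p,
    )
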