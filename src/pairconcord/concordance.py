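"""Pair-level variant matching and concordance statistics.

Variants from the two samples of one patient are matched on the exact
nucleotide-level key (gene, chrom, pos, ref, alt) and partitioned into
shared / primary-only / metastatic-only buckets.  Protein-level matching
would merge distinct nucleotide events and deflate discordance, so it is
deliberately not used.

Counting conventions
--------------------
A shared variant is one *event* in the event-level tallies
(``overall_concordance = n_shared / n_variants``) but counts once per pair
member in the per-sample averages, so the mean number of concordant
variants per sample is ``2 * n_shared / n_pairs`` and the mean number of
discordant variants per sample is ``n_discordant / n_pairs``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from pairconcord.model import VariantClass, VariantRecord
from pairconcord.stattests import two_proportion_ztest

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariantKey:
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str

    @classmethod
    def of(cls, v: VariantRecord) -> "VariantKey":
        return cls(v.gene, v.chrom, v.pos, v.ref, v.alt)


@dataclass
class PairClassification:
    """The shared / primary-only / metastatic-only partition of one pair."""

    patient_id: str
    shared: list[tuple[VariantRecord, VariantRecord]] = field(default_factory=list)
    primary_only: list[VariantRecord] = field(default_factory=list)
    metastatic_only: list[VariantRecord] = field(default_factory=list)

    @property
    def n_shared(self) -> int:
        return len(self.shared)

    @property
    def n_discordant(self) -> int:
        return len(self.primary_only) + len(self.metastatic_only)

    @property
    def n_events(self) -> int:
        return self.n_shared + self.n_discordant

    @property
    def concordance(self) -> Optional[float]:
        if self.n_events == 0:
            return None
        return self.n_shared / self.n_events


def classify_pair(
    primary_variants: Sequence[VariantRecord],
    metastatic_variants: Sequence[VariantRecord],
    patient_id: Optional[str] = None,
) -> PairClassification:
    """Partition one patient's filtered variants by set algebra on VariantKey.

    Raises ``ValueError`` on a duplicated key within one sample (upstream
    deduplication should prevent this).
    """
    if patient_id is None:
        for v in list(primary_variants) + list(metastatic_variants):
            patient_id = v.patient_id
            break
        else:
            patient_id = ""

    def index(variants: Sequence[VariantRecord], label: str) -> dict[VariantKey, VariantRecord]:
        out: dict[VariantKey, VariantRecord] = {}
        for v in variants:
            key = VariantKey.of(v)
            if key in out:
                raise ValueError(f"duplicate key {key} in {label} sample of {patient_id}")
            out[key] = v
        return out

    prim = index(primary_variants, "primary")
    met = index(metastatic_variants, "metastatic")
    shared_keys = prim.keys() & met.keys()
    return PairClassification(
        patient_id=patient_id,
        shared=[(prim[k], met[k]) for k in prim if k in shared_keys],
        primary_only=[prim[k] for k in prim if k not in shared_keys],
        metastatic_only=[met[k] for k in met if k not in shared_keys],
    )


@dataclass
class GeneConcordance:
    n_total: int
    n_shared: int

    @property
    def concordance(self) -> float:
        return self.n_shared / self.n_total


@dataclass
class PairSummary:
    n_shared: int
    n_discordant: int

    @property
    def concordance(self) -> Optional[float]:
        n = self.n_shared + self.n_discordant
        return None if n == 0 else self.n_shared / n


@dataclass
class ConcordanceReport:
    """All pair-concordance statistics for one cohort of pairs."""

    n_pairs: int
    n_shared: int
    n_primary_only: int
    n_metastatic_only: int
    per_gene: dict[str, GeneConcordance]
    per_class: dict[VariantClass, GeneConcordance]
    per_pair: dict[str, PairSummary]

    @property
    def n_discordant(self) -> int:
        return self.n_primary_only + self.n_metastatic_only

    @property
    def n_variants(self) -> int:
        """Distinct matched variant events (a shared variant counts once)."""
        return self.n_shared + self.n_discordant

    @property
    def overall_concordance(self) -> float:
        return self.n_shared / self.n_variants

    @property
    def primary_only_fraction(self) -> float:
        return self.n_primary_only / self.n_variants

    @property
    def metastatic_only_fraction(self) -> float:
        return self.n_metastatic_only / self.n_variants

    @property
    def primary_share_of_discordant(self) -> Optional[float]:
        return None if self.n_discordant == 0 else self.n_primary_only / self.n_discordant

    @property
    def mean_pair_concordance(self) -> float:
        """Average per-pair concordance over pairs with >= 1 event."""
        vals = [s.concordance for s in self.per_pair.values() if s.concordance is not None]
        if not vals:
            raise ValueError("no pair has any filtered variant")
        return sum(vals) / len(vals)

    @property
    def mean_concordant_per_pair(self) -> float:
        """Shared events counted once per pair member."""
        return 2 * self.n_shared / self.n_pairs

    @property
    def mean_discordant_per_pair(self) -> float:
        return self.n_discordant / self.n_pairs

    def gene_mean_concordance(self, genes: Iterable[str]) -> float:
        """Unweighted mean of per-gene concordances over the named genes."""
        vals = [self.per_gene[g].concordance for g in genes]
        return sum(vals) / len(vals)


def concordance_report(classifications: Sequence[PairClassification]) -> ConcordanceReport:
    """Aggregate per-pair classifications into the full report.

    For a shared event the variant class and gene are taken from the primary
    record; a class disagreement between the matched records triggers a
    warning (the key guarantees gene agreement).
    """
    if not classifications:
        raise ValueError("concordance_report requires at least one pair")
    per_gene: dict[str, GeneConcordance] = {}
    per_class: dict[VariantClass, GeneConcordance] = {}
    per_pair: dict[str, PairSummary] = {}
    n_shared = n_primary_only = n_metastatic_only = 0

    def tally(gene: str, vclass: VariantClass, shared: bool) -> None:
        g = per_gene.setdefault(gene, GeneConcordance(0, 0))
        c = per_class.setdefault(vclass, GeneConcordance(0, 0))
        g.n_total += 1
        c.n_total += 1
        if shared:
            g.n_shared += 1
            c.n_shared += 1

    for cls in classifications:
        for prim, met in cls.shared:
            if prim.variant_class is not met.variant_class:
                logger.warning(
                    "pair %s: shared variant class disagreement (%s vs %s); using primary",
                    cls.patient_id,
                    prim.variant_class.value,
                    met.variant_class.value,
                )
            tally(prim.gene, prim.variant_class, shared=True)
        for v in cls.primary_only:
            tally(v.gene, v.variant_class, shared=False)
        for v in cls.metastatic_only:
            tally(v.gene, v.variant_class, shared=False)
        n_shared += cls.n_shared
        n_primary_only += len(cls.primary_only)
        n_metastatic_only += len(cls.metastatic_only)
        if cls.n_events == 0:
            logger.info("pair %s has no filtered variants; excluded from pair means", cls.patient_id)
        per_pair[cls.patient_id] = PairSummary(cls.n_shared, cls.n_discordant)

    return ConcordanceReport(
        n_pairs=len(classifications),
        n_shared=n_shared,
        n_primary_only=n_primary_only,
        n_metastatic_only=n_metastatic_only,
        per_gene=per_gene,
        per_class=per_class,
        per_pair=per_pair,
    )


def stratified_concordance_test(
    report_by_stratum: Mapping[str, ConcordanceReport],
    statistic: str = "concordance",
) -> tuple[dict[str, float], float]:
    """Compare a pooled proportion between exactly two strata.

    ``statistic`` selects the numerator over pooled variant events:
    ``"concordance"`` uses shared events, ``"primary_only_fraction"`` uses
    primary-only events.  Returns per-stratum proportions and the two-sided
    pooled two-proportion z-test p-value.
    """
    if len(report_by_stratum) != 2:
        raise ValueError("exactly two strata required")
    if statistic not in ("concordance", "primary_only_fraction"):
        raise ValueError(f"unknown statistic {statistic!r}")
    counts, nobs, props = [], [], {}
    for name, rep in report_by_stratum.items():
        if rep.n_variants == 0:
            raise ValueError(f"stratum {name!r} has zero variant events")
        x = rep.n_shared if statistic == "concordance" else rep.n_primary_only
        counts.append(x)
        nobs.append(rep.n_variants)
        props[name] = x / rep.n_variants
    _, p = two_proportion_ztest(counts, nobs)
    return props, p
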