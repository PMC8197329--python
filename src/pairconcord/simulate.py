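"""Synthetic paired primary-metastatic cohort generator.

The generator emulates a targeted-panel paired colorectal cancer cohort: for
every patient and gene, mutation occurs with a gene-specific patient
frequency; a mutated pair's variant is truncal (present in the founding
clone, hence emitted in both samples under the same nucleotide key) with the
gene's concordance probability, otherwise private to one sample — the
primary with probability ``private_primary_share``.  Truncal VAFs follow a
Beta distribution per sample role with an optional per-gene additive shift
in the metastasis; private (subclonal) variants draw from a lower-mean Beta.
Synchronous and metachronous pairs differ in concordance by a configurable
delta, centred on the gene concordance.  Decoy variants violating each
filter criterion, Bethesda marker calls, timing, survival and recurrence
times are all emitted with complete ground-truth bookkeeping, so every
downstream stage can be checked label-by-label.

Private variants are generated independently across the two samples of a
pair (no shared subclonal phylogeny); that is sufficient for the statistics
under test and is a deliberate simplification of neutral-evolution
intratumor heterogeneity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from pairconcord.filtering import FilterCriterion
from pairconcord.model import (
    Cohort,
    MsiStatus,
    PatientPair,
    SampleRole,
    Timing,
    VariantClass,
    VariantRecord,
)
from pairconcord.msi import MsiMarker, MsiMarkerCall

_LN2 = math.log(2.0)

_BASES = "ACGT"
_AA = "ARNDCQEGHILKMFPSTWYV"


@dataclass
class GeneModel:
    """Per-gene parameters of the generator.

    frequency
        Probability that a patient carries >= 1 clinically significant
        variant of the gene (per-patient, applied once per patient).
    concordance
        Probability that a mutated pair's variant is truncal, i.e. shared
        by both samples (before the timing-stratum delta).
    class_mixture
        Mixture over protein-altering variant classes.
    hotspots
        Optional protein position -> weight map; weights need not sum to 1,
        the remainder is spread over random positions.
    mean_variants
        Mean number of distinct variants per mutated patient (>= 1); the
        excess over one is Poisson.
    vaf_shift
        Additive shift of the metastatic truncal VAF relative to primary.
    """

    frequency: float
    concordance: float
    class_mixture: dict[VariantClass, float] = field(
        default_factory=lambda: {
            VariantClass.MISSENSE_SNV: 0.6,
            VariantClass.NONSENSE_SNV: 0.2,
            VariantClass.INDEL: 0.15,
            VariantClass.SPLICE_SITE: 0.05,
        }
    )
    hotspots: Optional[dict[int, float]] = None
    mean_variants: float = 1.0
    vaf_shift: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.frequency <= 1.0):
            raise ValueError(f"frequency {self.frequency} outside [0, 1]")
        if not (0.0 <= self.concordance <= 1.0):
            raise ValueError(f"concordance {self.concordance} outside [0, 1]")
        if self.mean_variants < 1.0:
            raise ValueError("mean_variants must be >= 1")
        total = sum(self.class_mixture.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"class_mixture sums to {total}, expected 1")


def default_gene_models() -> dict[str, GeneModel]:
    """Gene panel defaults for a paired metastatic colorectal cohort.

    Frequencies and per-gene concordances follow the marginals of a 95-pair
    targeted-panel CRC cohort: APC/TP53/KRAS/PIK3CA/SMAD4/FBXW7 as the top
    six driver genes, early drivers (KRAS, NRAS, APC) nearly fully truncal,
    later events (PIK3CA, SMAD4) less so, and a tail of rare panel genes
    with lower clonal sharing.  TP53 carries a +0.09 metastatic VAF shift.
    """
    m = VariantClass.MISSENSE_SNV
    n = VariantClass.NONSENSE_SNV
    i = VariantClass.INDEL
    s = VariantClass.SPLICE_SITE
    models = {
        "APC": GeneModel(0.71, 0.90, {n: 0.72, i: 0.26, s: 0.02}, mean_variants=1.3),
        "TP53": GeneModel(
            0.54,
            0.91,
            {m: 0.66, n: 0.22, i: 0.08, s: 0.04},
            hotspots={175: 0.24, 248: 0.12, 273: 0.08},
            mean_variants=1.1,
            vaf_shift=0.09,
        ),
        "KRAS": GeneModel(
            0.45, 0.98, {m: 1.0}, hotspots={12: 0.70, 13: 0.15, 61: 0.10, 146: 0.05}
        ),
        "PIK3CA": GeneModel(
            0.16, 0.70, {m: 1.0}, hotspots={1047: 0.36, 545: 0.32, 542: 0.15, 546: 0.12}
        ),
        "SMAD4": GeneModel(0.15, 0.61, {m: 0.5, n: 0.3, i: 0.2}),
        "FBXW7": GeneModel(0.11, 1.00, {m: 0.6, n: 0.3, i: 0.1}),
        "TET2": GeneModel(0.05, 0.60),
        "NRAS": GeneModel(0.04, 1.00, {m: 1.0}, hotspots={61: 0.8, 12: 0.2}),
        "VHL": GeneModel(0.04, 0.40),
        "ATR": GeneModel(0.03, 0.50),
        "PIK3R1": GeneModel(0.03, 0.40),
        "PTEN": GeneModel(0.03, 1.00),
        "RB1": GeneModel(0.03, 0.50),
        "BRAF": GeneModel(0.02, 0.90, {m: 1.0}, hotspots={600: 0.9}),
        "BRCA2": GeneModel(0.02, 1.00),
        "CTNNB1": GeneModel(0.02, 0.50),
        "ERBB2": GeneModel(0.02, 0.40),
        "MED12": GeneModel(0.02, 0.50),
        "NOTCH1": GeneModel(0.02, 0.50),
        "RNF43": GeneModel(0.02, 0.50),
        "TSC1": GeneModel(0.02, 0.40),
    }
    for g in ("ATM", "ERBB3", "PTCH1", "SMARCA4", "AKT1", "CDH1", "BAP1", "DNMT3A", "FOXL2", "MSH6"):
        models[g] = GeneModel(0.02, 0.45)
    return models


@dataclass
class SimulationParams:
    """Full parameterization of the synthetic paired-cohort generator.

    Defaults describe a 95-pair metastatic CRC study arm with 4 primary-only
    and 47 metastatic-only singletons, 55% synchronous metastases, 62% of
    discordant events primary-specific, ~5% MSI-H prevalence with SMAD4
    enrichment, truncal VAFs ~ Beta(4, 12) (mean 0.25) and subclonal VAFs
    ~ Beta(2, 18) (mean 0.10).
    """

    n_pairs: int = 95
    n_primary_only: int = 4
    n_metastatic_only: int = 47
    seed: int = 0
    gene_models: dict[str, GeneModel] = field(default_factory=default_gene_models)
    private_primary_share: float = 0.62
    p_synchronous: float = 0.55
    concordance_delta: float = 0.06
    vaf_truncal: tuple[float, float] = (4.0, 12.0)
    vaf_subclonal: tuple[float, float] = (2.0, 18.0)
    p_msi_h: float = 0.05
    msi_enrichment_odds: dict[str, float] = field(default_factory=lambda: {"SMAD4": 5.0})
    decoy_fractions: dict[FilterCriterion, float] = field(
        default_factory=lambda: {
            FilterCriterion.NOT_PROTEIN_ALTERING: 0.3,
            FilterCriterion.COMMON_IN_GNOMAD: 0.3,
            FilterCriterion.NOT_PATHOGENIC_OR_ONCOGENIC: 0.3,
        }
    )
    os_mean_days: float = 900.0
    censor_range_days: tuple[float, float] = (100.0, 2000.0)
    recurrence_gene: str = "FBXW7"
    recurrence_median_mutant: float = 137.0
    recurrence_median_wild: float = 294.0
    p_recurrence_recorded: float = 0.5
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.gene_models:
            raise ValueError("gene_models must be non-empty")
        if self.n_pairs < 0 or self.n_primary_only < 0 or self.n_metastatic_only < 0:
            raise ValueError("cohort sizes must be nonnegative")
        for nm, frac in (
            ("private_primary_share", self.private_primary_share),
            ("p_synchronous", self.p_synchronous),
            ("p_msi_h", self.p_msi_h),
            ("p_recurrence_recorded", self.p_recurrence_recorded),
        ):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"{nm}={frac} outside [0, 1]")
        for a, b in (self.vaf_truncal, self.vaf_subclonal):
            if a <= 0 or b <= 0:
                raise ValueError("Beta parameters must be positive")
        for frac in self.decoy_fractions.values():
            if frac < 0:
                raise ValueError("decoy fractions must be nonnegative")


def expected_gene_concordance(params: SimulationParams, gene: str) -> float:
    """Marginal truncal probability of a pair variant in ``gene``, averaging
    the timing strata (the per-stratum delta is centred on the gene value
    and clipped to [0, 1])."""
    c = params.gene_models[gene].concordance
    d = params.concordance_delta / 2.0
    ps = params.p_synchronous
    return ps * min(1.0, c + d) + (1.0 - ps) * max(0.0, c - d)


def expected_gene_frequency(params: SimulationParams, gene: str) -> float:
    """Marginal per-patient mutation probability, including MSI enrichment."""
    f = params.gene_models[gene].frequency
    odds = params.msi_enrichment_odds.get(gene, 1.0)
    return params.p_msi_h * min(1.0, f * odds) + (1.0 - params.p_msi_h) * f


@dataclass
class GroundTruth:
    """Label-by-label bookkeeping of everything the generator decided."""

    # (sample_id, chrom, pos, ref, alt) -> "kept" or the violated criterion
    variant_fate: dict[tuple, str] = field(default_factory=dict)
    # (patient_id, gene, chrom, pos, ref, alt) -> shared / primary_only / metastatic_only
    bucket: dict[tuple, str] = field(default_factory=dict)
    truncal: dict[tuple, bool] = field(default_factory=dict)
    patient_timing: dict[str, Timing] = field(default_factory=dict)
    patient_msi: dict[str, MsiStatus] = field(default_factory=dict)
    # (patient_id, role value) -> genes with >= 1 kept variant in that sample
    gene_mutations: dict[tuple, set] = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return sum(1 for f in self.variant_fate.values() if f == "kept")

    def decoy_count(self, criterion: FilterCriterion) -> int:
        return sum(1 for f in self.variant_fate.values() if f == criterion.value)


@dataclass
class SimulationResult:
    cohort: Cohort
    marker_calls: list[MsiMarkerCall]
    truth: GroundTruth
    params: SimulationParams


@dataclass
class _VariantSpec:
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: VariantClass
    protein: str


class _Generator:
    def __init__(self, params: SimulationParams):
        self.p = params
        self.rng = np.random.default_rng(params.seed)
        self.genes = sorted(params.gene_models)
        # stable per-gene coordinate blocks so keys never collide across genes
        self.gene_chrom = {g: f"chr{(i % 22) + 1}" for i, g in enumerate(self.genes)}
        self.gene_base = {g: 1_000_000 + i * 5_000_000 for i, g in enumerate(self.genes)}
        self.truth = GroundTruth()

    # -- variant construction -------------------------------------------------

    def _protein_pos(self, model: GeneModel) -> int:
        if model.hotspots:
            positions = sorted(model.hotspots)
            weights = np.array([model.hotspots[q] for q in positions], dtype=float)
            rest = max(0.0, 1.0 - weights.sum())
            if self.rng.random() < rest:
                return int(self.rng.integers(1, 1500))
            return int(self.rng.choice(positions, p=weights / weights.sum()))
        return int(self.rng.integers(1, 1500))

    def _make_spec(self, gene: str, used: set[int], decoy: bool = False) -> _VariantSpec:
        model = self.p.gene_models[gene]
        classes = list(model.class_mixture)
        probs = np.array([model.class_mixture[c] for c in classes], dtype=float)
        vclass = classes[int(self.rng.choice(len(classes), p=probs / probs.sum()))]
        for _ in range(200):
            aa = self._protein_pos(model)
            pos = self.gene_base[gene] + aa * 3 + int(self.rng.integers(3))
            if decoy:
                pos += 3_000_000  # decoys never share a key with kept variants
            if pos not in used:
                break
        else:  # pragma: no cover - would need a pathological hotspot config
            raise RuntimeError(f"could not find a free position in {gene}")
        used.add(pos)
        ref = _BASES[pos % 4]
        if vclass is VariantClass.INDEL:
            if self.rng.random() < 0.5:
                alt, protein = "-", f"p.{_AA[aa % 20]}{aa}fs"
            else:
                ref, alt, protein = "-", ref + _BASES[(pos + 1) % 4], f"p.{_AA[aa % 20]}{aa}dup"
        else:
            alt = _BASES[(pos % 4 + 1 + int(self.rng.integers(3))) % 4]
            if alt == ref:  # pragma: no cover - arithmetic guarantees alt != ref
                alt = _BASES[(pos + 1) % 4]
            if vclass is VariantClass.MISSENSE_SNV:
                protein = f"p.{_AA[aa % 20]}{aa}{_AA[(aa + 1) % 20]}"
            elif vclass is VariantClass.NONSENSE_SNV:
                protein = f"p.{_AA[aa % 20]}{aa}*"
            else:
                protein = ""  # splice site / synonymous / other
        return _VariantSpec(gene, self.gene_chrom[gene], pos, ref, alt, vclass, protein)

    def _pass_annotations(self) -> tuple[Optional[float], Optional[float], str, str]:
        """Annotations that satisfy the rarity and pathogenicity criteria."""
        gn_total = None if self.rng.random() < 0.5 else float(self.rng.uniform(0, 1e-3))
        gn_eas = None if self.rng.random() < 0.5 else float(self.rng.uniform(0, 1e-3))
        if self.rng.random() < 0.6:
            clinvar = str(self.rng.choice(["Pathogenic", "Likely pathogenic", "Drug response"]))
            oncokb = str(self.rng.choice(["Oncogenic", "Unknown", ""]))
        else:
            clinvar = str(self.rng.choice(["", "Uncertain significance"]))
            oncokb = str(self.rng.choice(["Oncogenic", "Likely Oncogenic", "Predicted Oncogenic"]))
        return gn_total, gn_eas, clinvar, oncokb

    def _record(
        self,
        patient_id: str,
        sample_id: str,
        role: SampleRole,
        spec: _VariantSpec,
        vaf: float,
        fate: str,
        annotations: Optional[tuple] = None,
    ) -> VariantRecord:
        if annotations is None:
            annotations = self._pass_annotations()
        gn_total, gn_eas, clinvar, oncokb = annotations
        self.truth.variant_fate[(sample_id, spec.chrom, spec.pos, spec.ref, spec.alt)] = fate
        if fate == "kept":
            self.truth.gene_mutations.setdefault((patient_id, role.value), set()).add(spec.gene)
        return VariantRecord(
            patient_id=patient_id,
            sample_id=sample_id,
            sample_role=role,
            gene=spec.gene,
            chrom=spec.chrom,
            pos=spec.pos,
            ref=spec.ref,
            alt=spec.alt,
            variant_class=spec.vclass,
            protein_change=spec.protein,
            vaf=round(vaf, 4),
            gnomad_af_total=gn_total,
            gnomad_af_eas=gn_eas,
            clinvar_sig=clinvar,
            oncokb_oncogenicity=oncokb,
        )

    def _truncal_vaf(self, role: SampleRole, gene: str) -> float:
        a, b = self.p.vaf_truncal
        v = float(self.rng.beta(a, b))
        if role is SampleRole.METASTATIC:
            v += self.p.gene_models[gene].vaf_shift
        return min(max(v, 0.001), 0.999)

    def _subclonal_vaf(self) -> float:
        a, b = self.p.vaf_subclonal
        return min(max(float(self.rng.beta(a, b)), 0.001), 0.999)

    # -- patients -------------------------------------------------------------

    def _n_variants(self, model: GeneModel) -> int:
        return 1 + int(self.rng.poisson(model.mean_variants - 1.0))

    def _gene_mutated(self, gene: str, msi_h: bool) -> bool:
        f = self.p.gene_models[gene].frequency
        if msi_h:
            f = min(1.0, f * self.p.msi_enrichment_odds.get(gene, 1.0))
        return bool(self.rng.random() < f)

    def _emit_pair(self, pid: str, prim_sid: str, met_sid: str, timing: Timing, msi_h: bool, variants: list) -> None:
        delta = self.p.concordance_delta / 2.0
        for gene in self.genes:
            if not self._gene_mutated(gene, msi_h):
                continue
            model = self.p.gene_models[gene]
            c = model.concordance + (delta if timing is Timing.SYNCHRONOUS else -delta)
            c = min(max(c, 0.0), 1.0)
            used: set[int] = set()
            for _ in range(self._n_variants(model)):
                spec = self._make_spec(gene, used)
                key = (pid, gene, spec.chrom, spec.pos, spec.ref, spec.alt)
                if self.rng.random() < c:
                    ann = self._pass_annotations()
                    variants.append(
                        self._record(pid, prim_sid, SampleRole.PRIMARY, spec,
                                     self._truncal_vaf(SampleRole.PRIMARY, gene), "kept", ann)
                    )
                    variants.append(
                        self._record(pid, met_sid, SampleRole.METASTATIC, spec,
                                     self._truncal_vaf(SampleRole.METASTATIC, gene), "kept", ann)
                    )
                    self.truth.bucket[key] = "shared"
                    self.truth.truncal[key] = True
                else:
                    to_primary = self.rng.random() < self.p.private_primary_share
                    sid = prim_sid if to_primary else met_sid
                    role = SampleRole.PRIMARY if to_primary else SampleRole.METASTATIC
                    variants.append(
                        self._record(pid, sid, role, spec, self._subclonal_vaf(), "kept")
                    )
                    self.truth.bucket[key] = "primary_only" if to_primary else "metastatic_only"
                    self.truth.truncal[key] = False

    def _emit_singleton(self, pid: str, sid: str, role: SampleRole, msi_h: bool, variants: list) -> None:
        for gene in self.genes:
            if not self._gene_mutated(gene, msi_h):
                continue
            model = self.p.gene_models[gene]
            used: set[int] = set()
            for _ in range(self._n_variants(model)):
                spec = self._make_spec(gene, used)
                vaf = (
                    self._truncal_vaf(role, gene)
                    if self.rng.random() < model.concordance
                    else self._subclonal_vaf()
                )
                variants.append(self._record(pid, sid, role, spec, vaf, "kept"))

    def _emit_decoys(self, patients: list[PatientPair], variants: list) -> None:
        n_kept = self.truth.n_kept
        samples = []
        for p in patients:
            if p.primary_sample_id:
                samples.append((p.patient_id, p.primary_sample_id, SampleRole.PRIMARY))
            if p.metastatic_sample_id:
                samples.append((p.patient_id, p.metastatic_sample_id, SampleRole.METASTATIC))
        used_by_sample: dict[str, set[int]] = {}
        for criterion, frac in self.p.decoy_fractions.items():
            for _ in range(round(frac * n_kept)):
                pid, sid, role = samples[int(self.rng.integers(len(samples)))]
                gene = self.genes[int(self.rng.integers(len(self.genes)))]
                used = used_by_sample.setdefault(sid, set())
                spec = self._make_spec(gene, used, decoy=True)
                if criterion is FilterCriterion.NOT_PROTEIN_ALTERING:
                    if spec.vclass is VariantClass.INDEL:
                        spec = _VariantSpec(
                            spec.gene, spec.chrom, spec.pos, _BASES[spec.pos % 4],
                            _BASES[(spec.pos + 1) % 4], spec.vclass, spec.protein
                        )
                    spec.vclass = VariantClass.SYNONYMOUS if self.rng.random() < 0.8 else VariantClass.OTHER
                    spec.protein = ""
                    ann = (None, None, "Pathogenic", "")
                elif criterion is FilterCriterion.COMMON_IN_GNOMAD:
                    ann = (float(self.rng.uniform(0.002, 0.2)), float(self.rng.uniform(0, 1e-3)), "Pathogenic", "")
                else:
                    ann = (None, None, str(self.rng.choice(["", "Benign", "Uncertain significance"])),
                           str(self.rng.choice(["", "Unknown", "Likely Neutral"])))
                variants.append(
                    self._record(pid, sid, role, spec, self._subclonal_vaf(), criterion.value, ann)
                )

    def _marker_calls(self, pid: str, msi_h: bool) -> tuple[list[MsiMarkerCall], MsiStatus]:
        markers = list(MsiMarker)
        if msi_h:
            n_unstable = 2 + int(self.rng.integers(4))
            unstable = set(self.rng.choice(len(markers), size=n_unstable, replace=False).tolist())
            status = MsiStatus.MSI_H
        else:
            unstable = set()
            status = MsiStatus.MSS
        calls = [
            MsiMarkerCall(patient_id=pid, marker=m, unstable=(i in unstable))
            for i, m in enumerate(markers)
        ]
        return calls, status

    def _survival(self, msi_h: bool, mutated_recurrence_gene: bool) -> tuple[float, bool, Optional[float]]:
        death = float(self.rng.exponential(self.p.os_mean_days))
        lo, hi = self.p.censor_range_days
        censor = float(self.rng.uniform(lo, hi))
        os_days = round(min(death, censor), 1)
        event = death <= censor
        recurrence = None
        if self.rng.random() < self.p.p_recurrence_recorded:
            median = (
                self.p.recurrence_median_mutant
                if mutated_recurrence_gene
                else self.p.recurrence_median_wild
            )
            recurrence = round(float(self.rng.exponential(median / _LN2)), 1)
        return os_days, event, recurrence

    # -- main -----------------------------------------------------------------

    def run(self) -> SimulationResult:
        p = self.p
        variants: list[VariantRecord] = []
        patients: list[PatientPair] = []
        marker_calls: list[MsiMarkerCall] = []
        sites = ["liver", "lung", "abdominopelvic", "soft_tissue", "brain", "lymph_node", "bone"]
        site_w = np.array([0.54, 0.25, 0.13, 0.04, 0.015, 0.015, 0.01])
        roster: list[tuple[str, str]] = (
            [("pair", f"P{i:04d}") for i in range(1, p.n_pairs + 1)]
            + [("primary_only", f"PO{i:04d}") for i in range(1, p.n_primary_only + 1)]
            + [("metastatic_only", f"MO{i:04d}") for i in range(1, p.n_metastatic_only + 1)]
        )
        for kind, pid in roster:
            msi_h = bool(self.rng.random() < p.p_msi_h)
            has_met = kind != "primary_only"
            timing = Timing.UNKNOWN
            if has_met:
                timing = (
                    Timing.SYNCHRONOUS
                    if self.rng.random() < p.p_synchronous
                    else Timing.METACHRONOUS
                )
            prim_sid = f"{pid}-P" if kind != "metastatic_only" else None
            met_sid = f"{pid}-M" if has_met else None
            if kind == "pair":
                self._emit_pair(pid, prim_sid, met_sid, timing, msi_h, variants)
            else:
                sid = prim_sid or met_sid
                role = SampleRole.PRIMARY if kind == "primary_only" else SampleRole.METASTATIC
                self._emit_singleton(pid, sid, role, msi_h, variants)
            calls, msi_status = self._marker_calls(pid, msi_h)
            marker_calls.extend(calls)
            mutated_rec_gene = p.recurrence_gene in (
                self.truth.gene_mutations.get((pid, "primary"), set())
                | self.truth.gene_mutations.get((pid, "metastatic"), set())
            )
            os_days, os_event, recurrence = self._survival(msi_h, mutated_rec_gene)
            site = sites[int(self.rng.choice(len(sites), p=site_w / site_w.sum()))] if has_met else ""
            patients.append(
                PatientPair(
                    patient_id=pid,
                    primary_sample_id=prim_sid,
                    metastatic_sample_id=met_sid,
                    metastasis_timing=timing,
                    metastasis_site=site,
                    msi_status=msi_status,
                    os_days=os_days,
                    os_event=os_event,
                    recurrence_days=recurrence,
                    clinical={
                        "t_stage": str(self.rng.choice(["1", "2", "3", "4"], p=[0.02, 0.05, 0.73, 0.20])),
                        "n_stage": str(self.rng.choice(["0", "1", "2"], p=[0.29, 0.355, 0.355])),
                    },
                )
            )
            self.truth.patient_timing[pid] = timing
            self.truth.patient_msi[pid] = msi_status
        self._emit_decoys(patients, variants)
        cohort = Cohort(variants=variants, patients=patients, name=p.name)
        return SimulationResult(cohort=cohort, marker_calls=marker_calls, truth=self.truth, params=p)


def generate(params: Optional[SimulationParams] = None) -> SimulationResult:
    """Generate a synthetic paired cohort; deterministic given ``params.seed``."""
    return _Generator(params or SimulationParams()).run()


# ---------------------------------------------------------------------------
# truth checking


@dataclass
class TruthCheckReport:
    n_checked: int
    mismatches: list[str]

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatches)


def truth_check(truth: GroundTruth, filter_decisions=None, classifications=None, msi_calls=None) -> TruthCheckReport:
    """Compare pipeline outputs label-by-label against generator bookkeeping.

    Checks whichever of filter decisions, pair classifications and MSI
    classifications are supplied; zero mismatches are expected on untampered
    outputs.  Raises ``ValueError`` when an output refers to an id the truth
    has never seen.
    """
    from pairconcord.msi import classify_cohort

    mismatches: list[str] = []
    n = 0
    if filter_decisions is not None:
        for d in filter_decisions:
            v = d.variant
            key = (v.sample_id, v.chrom, v.pos, v.ref, v.alt)
            if key not in truth.variant_fate:
                raise ValueError(f"unknown variant in outputs: {key}")
            n += 1
            fate = truth.variant_fate[key]
            if d.kept != (fate == "kept"):
                mismatches.append(f"filter fate of {key}: truth={fate}, kept={d.kept}")
            elif not d.kept and fate not in [c.value for c in d.failed_criteria]:
                mismatches.append(f"filter criteria of {key}: truth={fate}, got={d.failed_criteria}")
    if classifications is not None:
        for cls in classifications:
            buckets = (
                [(p, "shared") for p, _ in cls.shared]
                + [(v, "primary_only") for v in cls.primary_only]
                + [(v, "metastatic_only") for v in cls.metastatic_only]
            )
            for v, bucket in buckets:
                key = (cls.patient_id, v.gene, v.chrom, v.pos, v.ref, v.alt)
                if key not in truth.bucket:
                    raise ValueError(f"unknown pair event in outputs: {key}")
                n += 1
                if truth.bucket[key] != bucket:
                    mismatches.append(f"bucket of {key}: truth={truth.bucket[key]}, got={bucket}")
    if msi_calls is not None:
        for pid, status in classify_cohort(msi_calls).items():
            if pid not in truth.patient_msi:
                raise ValueError(f"unknown patient in MSI outputs: {pid}")
            n += 1
            if truth.patient_msi[pid] is not status:
                mismatches.append(
                    f"MSI of {pid}: truth={truth.patient_msi[pid].value}, got={status.value}"
                )
    return TruthCheckReport(n_checked=n, mismatches=mismatches)


# ---------------------------------------------------------------------------
# file emission


def write_ground_truth(truth: GroundTruth, path: Union[str, Path]) -> None:
    payload = {
        "variant_fate": {"|".join(map(str, k)): v for k, v in truth.variant_fate.items()},
        "bucket": {"|".join(map(str, k)): v for k, v in truth.bucket.items()},
        "truncal": {"|".join(map(str, k)): v for k, v in truth.truncal.items()},
        "patient_timing": {k: v.value for k, v in truth.patient_timing.items()},
        "patient_msi": {k: v.value for k, v in truth.patient_msi.items()},
        "gene_mutations": {"|".join(k): sorted(v) for k, v in truth.gene_mutations.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def write_simulation(result: SimulationResult, outdir: Union[str, Path]) -> dict[str, Path]:
    """Emit variant TSV, manifest TSV, marker-call TSV and ground-truth JSON."""
    from pairconcord import io as pio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants": outdir / "variants.tsv",
        "manifest": outdir / "manifest.tsv",
        "marker_calls": outdir / "msi_markers.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    pio.write_variant_table(result.cohort.variants, paths["variants"])
    pio.write_pair_manifest(result.cohort.patients, paths["manifest"])
    pio.write_marker_calls(result.marker_calls, paths["marker_calls"])
    write_ground_truth(result.truth, paths["ground_truth"])
    return paths
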