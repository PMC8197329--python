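"""Domain types: variants, patients, pairs, cohorts.

Coordinates are 1-based fully-closed in the MAF convention; indel alleles use
the MAF style where the absent side is written ``-`` (so a single-base
insertion is ``-/A`` and a single-base deletion ``A/-``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class SampleRole(str, Enum):
    PRIMARY = "primary"
    METASTATIC = "metastatic"


class VariantClass(str, Enum):
    MISSENSE_SNV = "missense_snv"
    NONSENSE_SNV = "nonsense_snv"
    INDEL = "indel"
    SPLICE_SITE = "splice_site"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Classes counted as protein-altering by the clinical-significance filter.
PROTEIN_ALTERING = frozenset(
    {
        VariantClass.MISSENSE_SNV,
        VariantClass.NONSENSE_SNV,
        VariantClass.INDEL,
        VariantClass.SPLICE_SITE,
    }
)


class Timing(str, Enum):
    SYNCHRONOUS = "synchronous"
    METACHRONOUS = "metachronous"
    UNKNOWN = "unknown"


#: Metastasis diagnosed within this many days of the primary diagnosis counts
#: as synchronous ("at the time or within 6 months"); an explicit label wins.
SYNCHRONOUS_CUTOFF_DAYS = 183


class MsiStatus(str, Enum):
    MSI_H = "MSI_H"
    MSI_L = "MSI_L"
    MSS = "MSS"
    UNKNOWN = "unknown"


def _is_indel_alleles(ref: str, alt: str) -> bool:
    return ref == "-" or alt == "-" or len(ref) != len(alt)


@dataclass(frozen=True)
class VariantRecord:
    """One annotated somatic variant observation in one tumor sample.

    ``vaf`` is the variant allele frequency, the fraction of reads supporting
    the alternate allele.  ``gnomad_af_total`` / ``gnomad_af_eas`` are
    population allele frequencies (total and East-Asian) used to exclude
    common, likely germline variants.  ``clinvar_sig`` and
    ``oncokb_oncogenicity`` carry curated pathogenicity / oncogenicity strings
    consumed by the significance filter; annotation is assumed to have been
    done upstream (VEP + OncoKB annotator).
    """

    patient_id: str
    sample_id: str
    sample_role: SampleRole
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: VariantClass
    protein_change: str = ""
    vaf: Optional[float] = None
    gnomad_af_total: Optional[float] = None
    gnomad_af_eas: Optional[float] = None
    clinvar_sig: str = ""
    oncokb_oncogenicity: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        for name in ("vaf", "gnomad_af_total", "gnomad_af_eas"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        is_indel = _is_indel_alleles(self.ref, self.alt)
        if is_indel != (self.variant_class is VariantClass.INDEL):
            raise ValueError(
                f"allele lengths ({self.ref}>{self.alt}) inconsistent with "
                f"variant_class={self.variant_class.value}"
            )


@dataclass
class PatientPair:
    """A patient's primary and/or metastatic sample with clinical covariates.

    A patient contributes to the paired concordance analysis only when both
    samples are present; singletons still contribute to cohort-level gene
    frequencies.  ``clinical`` holds categorical covariates (T/N stage, grade,
    invasion flags, primary location, ...) keyed by covariate name.
    """

    patient_id: str
    primary_sample_id: Optional[str] = None
    metastatic_sample_id: Optional[str] = None
    metastasis_timing: Timing = Timing.UNKNOWN
    metastasis_site: str = ""
    msi_status: MsiStatus = MsiStatus.UNKNOWN
    os_days: Optional[float] = None
    os_event: Optional[bool] = None
    recurrence_days: Optional[float] = None
    clinical: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.primary_sample_id is None and self.metastatic_sample_id is None:
            raise ValueError(f"patient {self.patient_id}: no sample at all")
        if self.os_days is not None and self.os_days < 0:
            raise ValueError(f"patient {self.patient_id}: negative os_days")
        if self.recurrence_days is not None and self.recurrence_days < 0:
            raise ValueError(f"patient {self.patient_id}: negative recurrence_days")

    @property
    def is_pair(self) -> bool:
        return self.primary_sample_id is not None and self.metastatic_sample_id is not None


@dataclass
class Cohort:
    """A set of variant observations plus the patient manifest they map onto."""

    variants: list[VariantRecord]
    patients: list[PatientPair]
    name: str = "cohort"

    def __post_init__(self) -> None:
        sample_roles: dict[tuple[str, str], SampleRole] = {}
        for p in self.patients:
            if p.primary_sample_id is not None:
                sample_roles[(p.patient_id, p.primary_sample_id)] = SampleRole.PRIMARY
            if p.metastatic_sample_id is not None:
                sample_roles[(p.patient_id, p.metastatic_sample_id)] = SampleRole.METASTATIC
        for v in self.variants:
            role = sample_roles.get((v.patient_id, v.sample_id))
            if role is None:
                raise ValueError(
                    f"variant sample ({v.patient_id}, {v.sample_id}) not in manifest"
                )
            if role is not v.sample_role:
                raise ValueError(
                    f"sample {v.sample_id}: variant says {v.sample_role.value}, "
                    f"manifest says {role.value}"
                )

    def patient(self, patient_id: str) -> PatientPair:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def variants_of(self, patient_id: str, role: SampleRole) -> list[VariantRecord]:
        return [
            v
            for v in self.variants
            if v.patient_id == patient_id and v.sample_role is role
        ]

    @property
    def pairs(self) -> list[PatientPair]:
        return [p for p in self.patients if p.is_pair]
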