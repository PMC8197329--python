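"""Clinical-significance variant filter.

Three criteria select "confident and clinically significant" somatic
variants, applied identically to the study cohort and to any reference
cohort:

1. protein-altering class (missense/nonsense SNV, indel, splice site);
2. rare in gnomAD: total AND East-Asian allele frequency <= 0.1%
   (a variant absent from gnomAD passes — absence means rare);
3. probable pathogenicity: ClinVar significance in {Pathogenic, Likely
   pathogenic, Drug response} OR OncoKB oncogenicity in {Oncogenic, Likely
   Oncogenic, Predicted Oncogenic}.

String matching is case-insensitive on exact tokens after normalizing
underscores to spaces; multi-valued ClinVar cells
("Pathogenic/Likely_pathogenic") pass if any token is accepted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from pairconcord.model import PROTEIN_ALTERING, VariantClass, VariantRecord

DEFAULT_MAF_THRESHOLD = 0.001
DEFAULT_CLINVAR_ACCEPT = frozenset({"Pathogenic", "Likely pathogenic", "Drug response"})
DEFAULT_ONCOKB_ACCEPT = frozenset({"Oncogenic", "Likely Oncogenic", "Predicted Oncogenic"})


class FilterCriterion(str, Enum):
    NOT_PROTEIN_ALTERING = "not_protein_altering"
    COMMON_IN_GNOMAD = "common_in_gnomad"
    NOT_PATHOGENIC_OR_ONCOGENIC = "not_pathogenic_or_oncogenic"


@dataclass(frozen=True)
class FilterConfig:
    """Tunable parameters of the significance filter.

    ``maf_threshold`` is a fraction: the default 0.001 is the 0.1%
    population-frequency cutoff.
    """

    maf_threshold: float = DEFAULT_MAF_THRESHOLD
    clinvar_accept: frozenset[str] = DEFAULT_CLINVAR_ACCEPT
    oncokb_accept: frozenset[str] = DEFAULT_ONCOKB_ACCEPT
    protein_altering_classes: frozenset[VariantClass] = PROTEIN_ALTERING

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_threshold < 1.0):
            raise ValueError(f"maf_threshold {self.maf_threshold} outside (0, 1)")
        if not self.clinvar_accept or not self.oncokb_accept:
            raise ValueError("accept sets must be non-empty")

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        kwargs = {}
        if "maf_threshold" in d:
            kwargs["maf_threshold"] = float(d["maf_threshold"])
        for key in ("clinvar_accept", "oncokb_accept"):
            if key in d:
                kwargs[key] = frozenset(d[key])
        if "protein_altering_classes" in d:
            kwargs["protein_altering_classes"] = frozenset(
                VariantClass(c) for c in d["protein_altering_classes"]
            )
        return cls(**kwargs)


@dataclass(frozen=True)
class FilterDecision:
    variant: VariantRecord
    kept: bool
    failed_criteria: tuple[FilterCriterion, ...] = ()

    def __post_init__(self) -> None:
        if self.kept != (len(self.failed_criteria) == 0):
            raise ValueError("kept must be True iff no criterion failed")


_TOKEN_SPLIT = re.compile(r"[/,;|]")


def _normalize(token: str) -> str:
    return token.strip().replace("_", " ").lower()


def _any_token_accepted(cell: str, accept: frozenset[str]) -> bool:
    accepted = {_normalize(a) for a in accept}
    return any(_normalize(tok) in accepted for tok in _TOKEN_SPLIT.split(cell) if tok.strip())


def _rare(af: Optional[float], threshold: float) -> bool:
    return af is None or af <= threshold


def evaluate(variant: VariantRecord, config: FilterConfig) -> FilterDecision:
    """Apply all three criteria to one variant."""
    failed = []
    if variant.variant_class not in config.protein_altering_classes:
        failed.append(FilterCriterion.NOT_PROTEIN_ALTERING)
    if not (
        _rare(variant.gnomad_af_total, config.maf_threshold)
        and _rare(variant.gnomad_af_eas, config.maf_threshold)
    ):
        failed.append(FilterCriterion.COMMON_IN_GNOMAD)
    if not (
        _any_token_accepted(variant.clinvar_sig, config.clinvar_accept)
        or _any_token_accepted(variant.oncokb_oncogenicity, config.oncokb_accept)
    ):
        failed.append(FilterCriterion.NOT_PATHOGENIC_OR_ONCOGENIC)
    return FilterDecision(variant=variant, kept=not failed, failed_criteria=tuple(failed))


def apply_filter(
    variants: Iterable[VariantRecord], config: FilterConfig | None = None
) -> list[FilterDecision]:
    """Filter a variant collection; decisions preserve input order."""
    config = config or FilterConfig()
    return [evaluate(v, config) for v in variants]


def kept_variants(decisions: Iterable[FilterDecision]) -> list[VariantRecord]:
    return [d.variant for d in decisions if d.kept]
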