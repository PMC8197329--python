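"""Readers and writers for the native variant TSV, the cBioPortal MAF
dialect, the patient/pair manifest, and MSI marker-call tables.

The native dialect is a plain TSV whose columns are exactly the
:class:`~pairconcord.model.VariantRecord` field names; it round-trips
field-for-field and is hand-writable in tests.  The cBioPortal dialect
accepts the standard MAF column names (``Hugo_Symbol``, ``Chromosome``,
``Start_Position``, ``Reference_Allele``, ``Tumor_Seq_Allele2``,
``Variant_Classification``, ``HGVSp_Short``, ``t_alt_count``/``t_depth``)
so that public reference cohorts can be compared under the same filter.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from pairconcord.model import (
    SYNCHRONOUS_CUTOFF_DAYS,
    Cohort,
    MsiStatus,
    PatientPair,
    SampleRole,
    Timing,
    VariantClass,
    VariantRecord,
)
from pairconcord.msi import MsiMarkerCall, MsiMarker

logger = logging.getLogger(__name__)

NATIVE_COLUMNS = [
    "patient_id",
    "sample_id",
    "sample_role",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "protein_change",
    "vaf",
    "gnomad_af_total",
    "gnomad_af_eas",
    "clinvar_sig",
    "oncokb_oncogenicity",
]

#: MAF ``Variant_Classification`` vocabulary -> native variant classes.
#: Anything not listed maps to ``other`` (multi-nucleotide substitutions,
#: UTR/intronic classes, ...), which the filter then discards.
CBIOPORTAL_CLASS_MAP = {
    "Missense_Mutation": VariantClass.MISSENSE_SNV,
    "Nonsense_Mutation": VariantClass.NONSENSE_SNV,
    "Frame_Shift_Del": VariantClass.INDEL,
    "Frame_Shift_Ins": VariantClass.INDEL,
    "In_Frame_Del": VariantClass.INDEL,
    "In_Frame_Ins": VariantClass.INDEL,
    "Splice_Site": VariantClass.SPLICE_SITE,
    "Silent": VariantClass.SYNONYMOUS,
}


def _parse_float(cell: str) -> Optional[float]:
    cell = cell.strip()
    if cell in ("", "NA", "NaN", "nan", "."):
        return None
    return float(cell)


def _dedup(records: list[VariantRecord]) -> list[VariantRecord]:
    seen: set[tuple] = set()
    out = []
    n_dup = 0
    for r in records:
        key = (r.sample_id, r.chrom, r.pos, r.ref, r.alt)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        out.append(r)
    if n_dup:
        logger.warning("dropped %d duplicate variant rows", n_dup)
    return out


def _read_native(path: Path) -> list[VariantRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, no header")
        missing = set(NATIVE_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    VariantRecord(
                        patient_id=row["patient_id"],
                        sample_id=row["sample_id"],
                        sample_role=SampleRole(row["sample_role"]),
                        gene=row["gene"],
                        chrom=row["chrom"],
                        pos=int(row["pos"]),
                        ref=row["ref"],
                        alt=row["alt"],
                        variant_class=VariantClass(row["variant_class"]),
                        protein_change=row["protein_change"],
                        vaf=_parse_float(row["vaf"]),
                        gnomad_af_total=_parse_float(row["gnomad_af_total"]),
                        gnomad_af_eas=_parse_float(row["gnomad_af_eas"]),
                        clinvar_sig=row["clinvar_sig"],
                        oncokb_oncogenicity=row["oncokb_oncogenicity"],
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
    return records


def _read_cbioportal(path: Path, default_role: SampleRole) -> list[VariantRecord]:
    records = []
    with open(path, newline="") as fh:
        # MAF files may start with '#version'-style comment lines
        rows = (line for line in fh if not line.startswith("#"))
        reader = csv.DictReader(rows, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, no header")
        for lineno, row in enumerate(reader, start=2):
            try:
                cls_token = row["Variant_Classification"].strip()
                vclass = CBIOPORTAL_CLASS_MAP.get(cls_token, VariantClass.OTHER)
                if vclass is VariantClass.OTHER:
                    logger.info(
                        "line %d: Variant_Classification %r mapped to 'other'",
                        lineno,
                        cls_token,
                    )
                barcode = row["Tumor_Sample_Barcode"]
                alt_count = _parse_float(row.get("t_alt_count", ""))
                depth = _parse_float(row.get("t_depth", ""))
                vaf = None
                if alt_count is not None and depth is not None and depth > 0:
                    vaf = alt_count / depth
                records.append(
                    VariantRecord(
                        patient_id=barcode,
                        sample_id=barcode,
                        sample_role=default_role,
                        gene=row["Hugo_Symbol"],
                        chrom=str(row["Chromosome"]),
                        pos=int(row["Start_Position"]),
                        ref=row["Reference_Allele"],
                        alt=row["Tumor_Seq_Allele2"],
                        variant_class=vclass,
                        protein_change=row.get("HGVSp_Short", "") or "",
                        vaf=vaf,
                        gnomad_af_total=_parse_float(row.get("gnomAD_AF", "")),
                        gnomad_af_eas=_parse_float(row.get("gnomAD_EAS_AF", "")),
                        clinvar_sig=row.get("CLIN_SIG", "") or "",
                        oncokb_oncogenicity=row.get("ONCOGENIC", "") or "",
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
    return records


def read_variant_table(
    path: Union[str, Path],
    dialect: str = "native",
    default_role: SampleRole = SampleRole.PRIMARY,
) -> list[VariantRecord]:
    """Read an annotated variant table.

    Parameters
    ----------
    path:
        TSV file with a header row.
    dialect:
        ``"native"`` (columns as VariantRecord fields) or
        ``"cbioportal_maf"`` (standard MAF column names).
    default_role:
        Sample role assigned to every record of a cBioPortal MAF, which
        carries no role column (reference cohorts are all-primary or
        all-metastatic).

    Exact duplicate rows (same sample, chrom, pos, ref, alt) are dropped
    with a logged warning.  Malformed rows raise ``ValueError`` naming the
    line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "native":
        records = _read_native(path)
    elif dialect == "cbioportal_maf":
        records = _read_cbioportal(path, default_role)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _dedup(records)


def write_variant_table(records: Iterable[VariantRecord], path: Union[str, Path]) -> None:
    """Write records in the native TSV dialect (round-trips with the reader)."""
    path = Path(path)

    def fmt(v) -> str:
        if v is None:
            return ""
        if isinstance(v, float):
            return repr(v)
        return str(v)

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(NATIVE_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    r.sample_id,
                    r.sample_role.value,
                    r.gene,
                    r.chrom,
                    r.pos,
                    r.ref,
                    r.alt,
                    r.variant_class.value,
                    r.protein_change,
                    fmt(r.vaf),
                    fmt(r.gnomad_af_total),
                    fmt(r.gnomad_af_eas),
                    r.clinvar_sig,
                    r.oncokb_oncogenicity,
                ]
            )


MANIFEST_CORE_COLUMNS = [
    "patient_id",
    "primary_sample_id",
    "metastatic_sample_id",
    "metastasis_timing",
    "metastasis_interval_days",
    "metastasis_site",
    "msi_status",
    "os_days",
    "os_event",
    "recurrence_days",
]


def read_pair_manifest(path: Union[str, Path]) -> list[PatientPair]:
    """Read the patient manifest (one row per patient).

    Timing resolution: an explicit ``metastasis_timing`` label wins; otherwise
    ``metastasis_interval_days`` <= 183 (six months) is synchronous, > 183
    metachronous.  Unknown timing tokens parse as ``unknown`` with a warning.
    Any column beyond the core set is kept as a categorical clinical covariate.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    extra_cols = [c for c in df.columns if c not in MANIFEST_CORE_COLUMNS]
    patients = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))

        def cell(name: str) -> str:
            return row.get(name, "").strip()

        primary = cell("primary_sample_id") or None
        metastatic = cell("metastatic_sample_id") or None
        if primary is None and metastatic is None:
            raise ValueError(f"{path}: line {lineno}: patient with no samples")

        timing = Timing.UNKNOWN
        token = cell("metastasis_timing").lower()
        if token:
            try:
                timing = Timing(token)
            except ValueError:
                logger.warning("line %d: unknown timing token %r", lineno, token)
        else:
            interval = _parse_float(cell("metastasis_interval_days"))
            if interval is not None:
                timing = (
                    Timing.SYNCHRONOUS
                    if interval <= SYNCHRONOUS_CUTOFF_DAYS
                    else Timing.METACHRONOUS
                )

        msi_token = cell("msi_status")
        try:
            msi = MsiStatus(msi_token) if msi_token else MsiStatus.UNKNOWN
        except ValueError:
            logger.warning("line %d: unknown MSI token %r", lineno, msi_token)
            msi = MsiStatus.UNKNOWN

        os_event_cell = cell("os_event")
        os_event = None
        if os_event_cell:
            os_event = os_event_cell.lower() in ("1", "true", "yes", "dead")

        patients.append(
            PatientPair(
                patient_id=cell("patient_id"),
                primary_sample_id=primary,
                metastatic_sample_id=metastatic,
                metastasis_timing=timing,
                metastasis_site=cell("metastasis_site"),
                msi_status=msi,
                os_days=_parse_float(cell("os_days")),
                os_event=os_event,
                recurrence_days=_parse_float(cell("recurrence_days")),
                clinical={c: cell(c) for c in extra_cols if cell(c)},
            )
        )
    return patients


def write_pair_manifest(patients: Iterable[PatientPair], path: Union[str, Path]) -> None:
    """Write a manifest that round-trips with :func:`read_pair_manifest`."""
    patients = list(patients)
    clinical_cols = sorted({k for p in patients for k in p.clinical})
    cols = [c for c in MANIFEST_CORE_COLUMNS if c != "metastasis_interval_days"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols + clinical_cols)
        for p in patients:
            writer.writerow(
                [
                    p.patient_id,
                    p.primary_sample_id or "",
                    p.metastatic_sample_id or "",
                    "" if p.metastasis_timing is Timing.UNKNOWN else p.metastasis_timing.value,
                    p.metastasis_site,
                    "" if p.msi_status is MsiStatus.UNKNOWN else p.msi_status.value,
                    "" if p.os_days is None else repr(float(p.os_days)),
                    "" if p.os_event is None else ("1" if p.os_event else "0"),
                    "" if p.recurrence_days is None else repr(float(p.recurrence_days)),
                ]
                + [p.clinical.get(c, "") for c in clinical_cols]
            )


def read_marker_calls(path: Union[str, Path]) -> list[MsiMarkerCall]:
    """Read a Bethesda marker-call TSV (patient_id, marker, unstable)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    calls = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        token = row.unstable.strip().lower()
        unstable = None if token in ("", "na") else token in ("1", "true", "yes")
        try:
            marker = MsiMarker(row.marker)
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
        calls.append(MsiMarkerCall(patient_id=row.patient_id, marker=marker, unstable=unstable))
    return calls


def write_marker_calls(calls: Iterable[MsiMarkerCall], path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["patient_id", "marker", "unstable"])
        for c in calls:
            writer.writerow(
                [c.patient_id, c.marker.value, "" if c.unstable is None else int(c.unstable)]
            )


def load_cohort(
    variant_path: Union[str, Path],
    manifest_path: Union[str, Path],
    name: str = "cohort",
) -> Cohort:
    return Cohort(
        variants=read_variant_table(variant_path),
        patients=read_pair_manifest(manifest_path),
        name=name,
    )
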