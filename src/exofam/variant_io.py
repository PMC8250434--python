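"""Readers and writers for every on-disk format the pipeline touches.

Dialects
--------
* VCF 4.x with GT fields (read via cyvcf2; multi-allelic records are
  decomposed into one :class:`~exofam.model.Variant` per alternate
  allele).
* 6-column whitespace-delimited PED (family, id, father, mother, sex,
  status); ``0`` means no parent, status 1/2/0 maps to
  unaffected/affected/unknown.
* Tab-delimited, UTF-8 TSV with a header row for the annotation table,
  gene sets, clinical table and ranked report. An empty cell or ``.``
  means absent.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .config import CATEGORY_ORDER
from .model import (
    CandidateVariant,
    Consequence,
    FormatError,
    GeneEvidence,
    Genotype,
    GenotypeMatrix,
    Individual,
    Pedigree,
    PopulationFrequencies,
    PredictionProfile,
    Sex,
    Status,
    ToolCall,
    ValidationError,
    Variant,
    variant_key,
    CATEGORICAL_TOOLS,
)

# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str) -> tuple[list[Variant], GenotypeMatrix]:
    """Read a multi-sample VCF into variants and a genotype matrix.

    Multi-allelic records are decomposed into one variant per alternate
    allele; for each decomposed record a sample's genotype counts only
    that alt's alleles (a different alt at the same site counts as
    reference). Any genotype containing an uncalled allele is
    ``missing``.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - environment guard
        raise ImportError("cyvcf2 is required to read VCF files") from exc

    variants: list[Variant] = []
    matrix = GenotypeMatrix()
    try:
        vcf = VCF(path)
    except Exception as exc:
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    try:
        for record in vcf:
            alts = record.ALT or []
            genotypes = record.genotypes  # [[a0, a1, phased], ...]
            for alt_index, alt in enumerate(alts, start=1):
                v = Variant(chrom=record.CHROM, pos=record.POS, ref=record.REF, alt=alt)
                variants.append(v)
                vkey = variant_key(v)
                for sample, gt in zip(samples, genotypes):
                    alleles = [a for a in gt[:-1]]
                    if not alleles or any(a is None or a < 0 for a in alleles):
                        matrix.set(vkey, sample, Genotype.MISSING)
                        continue
                    dosage = sum(1 for a in alleles if a == alt_index)
                    if dosage == 0:
                        matrix.set(vkey, sample, Genotype.HOM_REF)
                    elif dosage == 1:
                        matrix.set(vkey, sample, Genotype.HET)
                    else:
                        matrix.set(vkey, sample, Genotype.HOM_ALT)
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"malformed VCF {path}: {exc}") from exc
    finally:
        vcf.close()
    return variants, matrix


def write_vcf(
    path: str,
    variants: Sequence[Variant],
    matrix: GenotypeMatrix,
    samples: Sequence[str],
) -> None:
    """Write biallelic records with GT-only genotypes (VCF 4.2)."""
    gt_repr = {
        Genotype.HOM_REF: "0/0",
        Genotype.HET: "0/1",
        Genotype.HOM_ALT: "1/1",
        Genotype.MISSING: "./.",
    }
    contigs: list[str] = []
    for v in variants:
        if v.chrom not in contigs:
            contigs.append(v.chrom)
    with open(path, "w", newline="") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for v in variants:
            vkey = variant_key(v)
            gts = "\t".join(gt_repr[matrix.get(vkey, s)] for s in samples)
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# PED

_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE}
_STATUS_CODES = {"1": Status.UNAFFECTED, "2": Status.AFFECTED}


def read_ped(path: str) -> list[Pedigree]:
    """Read a 6-column PED file into per-family pedigrees."""
    rows: dict[str, list[Individual]] = {}
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(
                    f"{path}:{lineno}: expected 6 whitespace-delimited columns, "
                    f"got {len(fields)}"
                )
            fam, iid, fid, mid, sex, status = fields[:6]
            if (fam, iid) in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate individual ({fam}, {iid})")
            seen.add((fam, iid))
            if iid in (fid, mid):
                raise ValidationError(
                    f"{path}:{lineno}: individual {iid!r} listed as its own parent"
                )
            rows.setdefault(fam, []).append(
                Individual(
                    id=iid,
                    family_id=fam,
                    father_id=None if fid == "0" else fid,
                    mother_id=None if mid == "0" else mid,
                    sex=_SEX_CODES.get(sex, Sex.UNKNOWN),
                    declared_status=_STATUS_CODES.get(status, Status.UNKNOWN),
                )
            )
    return [Pedigree(family_id=fam, members=members) for fam, members in rows.items()]


def write_ped(path: str, pedigrees: Sequence[Pedigree]) -> None:
    sex_code = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    status_code = {Status.UNAFFECTED: "1", Status.AFFECTED: "2", Status.UNKNOWN: "0"}
    with open(path, "w", newline="") as fh:
        for ped in pedigrees:
            for m in ped.members:
                fh.write(
                    "\t".join(
                        [
                            ped.family_id,
                            m.id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            sex_code[m.sex],
                            status_code[m.declared_status],
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Annotation table

_FREQ_COLUMNS = ("maf_exac", "maf_1000g", "maf_gnomad", "popmax_filtering_af")
_KEY_COLUMNS = ("chrom", "pos", "ref", "alt")
_OPTIONAL_COLUMNS = ("gene", "transcript", "cdna_hgvs")
ANNOTATION_COLUMNS = (
    _KEY_COLUMNS
    + _OPTIONAL_COLUMNS
    + ("consequence",)
    + _FREQ_COLUMNS
    + CATEGORICAL_TOOLS
    + ("dann",)
)


@dataclass(frozen=True)
class AnnotationRecord:
    frequencies: PopulationFrequencies
    profile: PredictionProfile
    consequence: Consequence
    gene: Optional[str] = None
    transcript: Optional[str] = None
    cdna_hgvs: Optional[str] = None


def _absent(cell: object) -> bool:
    if cell is None:
        return True
    if isinstance(cell, float) and math.isnan(cell):
        return True
    s = str(cell).strip()
    return s in ("", ".")


def _parse_call(cell: object, column: str, context: str) -> ToolCall:
    if _absent(cell):
        return ToolCall.MISSING
    s = str(cell).strip().lower()
    if s in ("d", "damaging"):
        return ToolCall.DAMAGING
    if s in ("t", "tolerated", "n", "neutral", "b", "benign"):
        return ToolCall.TOLERATED
    raise FormatError(f"{context}: unrecognized {column} call {cell!r}")


def read_annotation_table(path: str) -> dict[str, AnnotationRecord]:
    """Read the per-variant annotation TSV keyed by canonical variant key.

    Columns outside the documented set are rejected so that a silently
    renamed tool column cannot drop evidence on the floor.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    unknown = set(df.columns) - set(ANNOTATION_COLUMNS)
    if unknown:
        raise FormatError(
            f"{path}: unknown annotation column(s) {sorted(unknown)}; "
            f"expected a subset of {list(ANNOTATION_COLUMNS)}"
        )
    missing = set(_KEY_COLUMNS + ("consequence",)) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")

    records: dict[str, AnnotationRecord] = {}
    for idx, row in df.iterrows():
        context = f"{path} row {idx + 2}"  # +2: header + 1-based
        try:
            variant = Variant(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
            )
        except (ValueError, ValidationError) as exc:
            raise FormatError(f"{context}: bad variant fields: {exc}") from exc
        freqs = {}
        for col in _FREQ_COLUMNS:
            cell = row.get(col)
            if _absent(cell):
                freqs[col] = None
                continue
            try:
                freqs[col] = float(cell)
            except ValueError as exc:
                raise FormatError(f"{context}: non-numeric {col} {cell!r}") from exc
        calls = {
            tool: _parse_call(row.get(tool), tool, context)
            for tool in CATEGORICAL_TOOLS
        }
        dann = None
        if not _absent(row.get("dann")):
            try:
                dann = float(row["dann"])
            except ValueError as exc:
                raise FormatError(f"{context}: non-numeric dann {row['dann']!r}") from exc
        try:
            frequencies = PopulationFrequencies(**freqs)
            profile = PredictionProfile(dann_score=dann, **calls)
        except ValidationError as exc:
            raise ValidationError(f"{context}: {exc}") from exc
        try:
            consequence = Consequence(str(row["consequence"]).strip())
        except ValueError as exc:
            raise ValidationError(
                f"{context}: unknown consequence {row['consequence']!r}"
            ) from exc
        records[variant_key(variant)] = AnnotationRecord(
            frequencies=frequencies,
            profile=profile,
            consequence=consequence,
            gene=None if _absent(row.get("gene")) else str(row["gene"]),
            transcript=None if _absent(row.get("transcript")) else str(row["transcript"]),
            cdna_hgvs=None if _absent(row.get("cdna_hgvs")) else str(row["cdna_hgvs"]),
        )
    return records


def write_annotation_table(path: str, rows: Iterable[tuple[Variant, AnnotationRecord]]) -> None:
    def fmt(value: object) -> str:
        if value is None:
            return "."
        if isinstance(value, float):
            return format(value, "g")
        return str(value)

    call_code = {ToolCall.DAMAGING: "D", ToolCall.TOLERATED: "T", ToolCall.MISSING: "."}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for variant, rec in rows:
            writer.writerow(
                [
                    variant.chrom,
                    variant.pos,
                    variant.ref,
                    variant.alt,
                    fmt(rec.gene),
                    fmt(rec.transcript),
                    fmt(rec.cdna_hgvs),
                    rec.consequence.value,
                    fmt(rec.frequencies.maf_exac),
                    fmt(rec.frequencies.maf_1000g),
                    fmt(rec.frequencies.maf_gnomad),
                    fmt(rec.frequencies.popmax_filtering_af),
                    *[call_code[rec.profile.call(t)] for t in CATEGORICAL_TOOLS],
                    fmt(rec.profile.dann_score),
                ]
            )


# ---------------------------------------------------------------------------
# Gene sets

GENE_SET_FILENAMES = {
    "known_hm": "known_hm_genes.txt",
    "hm_related": "hm_related_genes.txt",
    "ocular_disease": "ocular_disease_genes.txt",
    "myp_map": "myp_loci.tsv",
    "expressed_adult": "expressed_adult_ocular.txt",
    "expressed_embryonic": "expressed_embryonic_ocular.txt",
}


def _read_gene_list(path: Optional[str], set_name: str) -> set[str]:
    if path is None or not os.path.exists(path):
        return set()
    try:
        with open(path) as fh:
            return {
                line.strip()
                for line in fh
                if line.strip() and not line.startswith("#")
            }
    except OSError as exc:
        raise FormatError(f"cannot read gene set {set_name!r} from {path}: {exc}") from exc


def read_gene_sets(
    known_hm: Optional[str] = None,
    hm_related: Optional[str] = None,
    ocular_disease: Optional[str] = None,
    myp_map: Optional[str] = None,
    expressed_adult: Optional[str] = None,
    expressed_embryonic: Optional[str] = None,
) -> dict[str, GeneEvidence]:
    """Merge gene-set files into per-gene evidence.

    Genes absent from every set get no entry; look up with
    ``.get(gene, NO_GENE_EVIDENCE)`` to obtain an all-false record.
    """
    known = _read_gene_list(known_hm, "known_hm")
    related = _read_gene_list(hm_related, "hm_related")
    ocular = _read_gene_list(ocular_disease, "ocular_disease")
    adult = _read_gene_list(expressed_adult, "expressed_adult")
    embryonic = _read_gene_list(expressed_embryonic, "expressed_embryonic")
    loci: dict[str, str] = {}
    if myp_map is not None and os.path.exists(myp_map):
        try:
            with open(myp_map) as fh:
                for lineno, line in enumerate(fh, start=1):
                    line = line.strip()
                    if not line or line.startswith("#"):
                        continue
                    parts = line.split("\t")
                    if len(parts) != 2:
                        raise FormatError(
                            f"{myp_map}:{lineno}: MYP map needs exactly two "
                            f"tab-separated columns (gene, locus)"
                        )
                    loci[parts[0].strip()] = parts[1].strip()
        except OSError as exc:
            raise FormatError(f"cannot read gene set 'myp_map' from {myp_map}: {exc}") from exc

    evidence: dict[str, GeneEvidence] = {}
    for gene in known | related | ocular | adult | embryonic | set(loci):
        evidence[gene] = GeneEvidence(
            is_known_hm_gene=gene in known,
            is_hm_related=gene in related,
            is_ocular_disease_gene=gene in ocular,
            myp_locus=loci.get(gene),
            expressed_adult_ocular=gene in adult,
            expressed_embryonic_ocular=gene in embryonic,
        )
    return evidence


def read_gene_sets_dir(directory: str) -> dict[str, GeneEvidence]:
    """Read the conventional gene-set file layout from one directory."""
    paths = {
        key: os.path.join(directory, fname)
        for key, fname in GENE_SET_FILENAMES.items()
    }
    return read_gene_sets(
        known_hm=paths["known_hm"],
        hm_related=paths["hm_related"],
        ocular_disease=paths["ocular_disease"],
        myp_map=paths["myp_map"],
        expressed_adult=paths["expressed_adult"],
        expressed_embryonic=paths["expressed_embryonic"],
    )


def write_gene_sets(directory: str, evidence: dict[str, GeneEvidence]) -> None:
    os.makedirs(directory, exist_ok=True)
    buckets: dict[str, list[str]] = {key: [] for key in GENE_SET_FILENAMES}
    myp_rows: list[tuple[str, str]] = []
    for gene in sorted(evidence):
        ev = evidence[gene]
        if ev.is_known_hm_gene:
            buckets["known_hm"].append(gene)
        if ev.is_hm_related:
            buckets["hm_related"].append(gene)
        if ev.is_ocular_disease_gene:
            buckets["ocular_disease"].append(gene)
        if ev.expressed_adult_ocular:
            buckets["expressed_adult"].append(gene)
        if ev.expressed_embryonic_ocular:
            buckets["expressed_embryonic"].append(gene)
        if ev.myp_locus is not None:
            myp_rows.append((gene, ev.myp_locus))
    for key, fname in GENE_SET_FILENAMES.items():
        path = os.path.join(directory, fname)
        with open(path, "w", newline="") as fh:
            if key == "myp_map":
                for gene, locus in myp_rows:
                    fh.write(f"{gene}\t{locus}\n")
            else:
                for gene in buckets[key]:
                    fh.write(gene + "\n")


# ---------------------------------------------------------------------------
# Clinical table

CLINICAL_COLUMNS = (
    "family",
    "proband_age",
    "affected_individuals",
    "se_range",
    "se_median",
    "al_range",
    "al_median",
)


@dataclass(frozen=True)
class ClinicalRow:
    family_id: str
    proband_age: Optional[int]
    affected_count: int
    se_range: tuple[float, float]  # (min, max), numerically ordered
    se_median: float
    al_range: tuple[float, float]
    al_median: float


def _to_float(cell: str, context: str) -> float:
    # Tolerate typeset minus signs in tables transcribed from print.
    s = str(cell).strip().replace("−", "-").replace("–", "-")
    try:
        return float(s)
    except ValueError as exc:
        raise FormatError(f"{context}: non-numeric value {cell!r}") from exc


def _parse_range(cell: str, context: str) -> tuple[float, float]:
    parts = str(cell).split("/")
    if len(parts) != 2:
        raise FormatError(f"{context}: range must be 'a/b', got {cell!r}")
    a = _to_float(parts[0], context)
    b = _to_float(parts[1], context)
    return (min(a, b), max(a, b))


def read_clinical_table(path: str) -> list[ClinicalRow]:
    """Read the per-family clinical summary TSV.

    Ranges are encoded ``a/b`` and returned numerically ordered
    (min, max); myopic spherical equivalents are negative diopters.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing clinical column(s) {sorted(missing)}")
    rows: list[ClinicalRow] = []
    for _, row in df.iterrows():
        fam = str(row["family"]).strip()
        context = f"{path} family {fam}"
        rows.append(
            ClinicalRow(
                family_id=fam,
                proband_age=None if _absent(row["proband_age"]) else int(row["proband_age"]),
                affected_count=int(row["affected_individuals"]),
                se_range=_parse_range(row["se_range"], context),
                se_median=_to_float(row["se_median"], context),
                al_range=_parse_range(row["al_range"], context),
                al_median=_to_float(row["al_median"], context),
            )
        )
    return rows


def write_clinical_table(path: str, rows: Sequence[ClinicalRow]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CLINICAL_COLUMNS)
        for r in rows:
            writer.writerow(
                [
                    r.family_id,
                    "." if r.proband_age is None else r.proband_age,
                    r.affected_count,
                    f"{r.se_range[0]:g}/{r.se_range[1]:g}",
                    f"{r.se_median:g}",
                    f"{r.al_range[0]:g}/{r.al_range[1]:g}",
                    f"{r.al_median:g}",
                ]
            )


# ---------------------------------------------------------------------------
# Ranked report

RANKED_COLUMNS = (
    ("family", "gene", "variant_key", "cdna_hgvs")
    + CATEGORY_ORDER
    + ("weighted_total", "frequency_class", "acmg_class")
)


def write_ranked_table(path: str, candidates: Sequence[CandidateVariant]) -> None:
    """Write the ranked candidate report, one row per candidate in the
    given (already ranked) order.

    Category columns are serialized 0/1 in the fixed report order.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(RANKED_COLUMNS)
        for c in candidates:
            if c.evidence is None or c.acmg is None:
                raise ValidationError(
                    f"candidate {c.variant.key} in family {c.family_id} is not scored"
                )
            writer.writerow(
                [
                    c.family_id,
                    c.variant.gene or ".",
                    c.variant.key,
                    c.variant.cdna_hgvs or ".",
                    *[int(getattr(c.evidence, cat)) for cat in CATEGORY_ORDER],
                    format(c.evidence.weighted_total, "g"),
                    c.evidence.frequency_class,
                    c.acmg.classification,
                ]
            )


def read_ranked_table(path: str) -> list[dict[str, object]]:
    """Read the ranked report back into plain records (round-trip aid)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if tuple(df.columns) != RANKED_COLUMNS:
        raise FormatError(
            f"{path}: ranked-report columns do not match the documented order"
        )
    records: list[dict[str, object]] = []
    for _, row in df.iterrows():
        rec: dict[str, object] = {
            "family": row["family"],
            "gene": None if row["gene"] == "." else row["gene"],
            "variant_key": row["variant_key"],
            "cdna_hgvs": None if row["cdna_hgvs"] == "." else row["cdna_hgvs"],
            "weighted_total": float(row["weighted_total"]),
            "frequency_class": row["frequency_class"],
            "acmg_class": row["acmg_class"],
        }
        for cat in CATEGORY_ORDER:
            rec[cat] = bool(int(row[cat]))
        records.append(rec)
    return records
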