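"""Readers and writers for the pipeline's interchange formats.

The canonical interchange is a fixed-schema tab-separated variant table
(one row per variant per sample); a minimal VCF dialect with 1:1 INFO-key
mapping is supported as an alternative input. Phenotypes travel as TSV,
ground truth as JSON, gene panels as YAML (see :mod:`cpgburden.panel`).
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import pysam
from pydantic import ValidationError

from .clinical import PhenotypeRecord
from .simulate import GroundTruth
from .variants import POPULATION_DATABASES, AnnotatedVariant

logger = logging.getLogger("cpgburden")

#: Canonical variant-table columns, in order.
VARIANT_COLUMNS = (
    "sample_id",
    "variant_id",
    "gene",
    "quality",
    "in_repeat_region",
    "consequence",
    "intron_offset",
    "in_last_exon",
    "maf_supercontrols",
    "maf_gnomAD",
    "maf_1000Genomes",
    "maf_ESP",
    "maf_ExAC",
    "clinvar",
    "known_sequencing_error",
    "known_pathogenic_whitelisted",
)

_MISSING = "."

#: VCF INFO keys <-> variant fields (documented dialect).
_VCF_MAF_KEYS = {
    "gnomAD": "MAF_GNOMAD",
    "1000Genomes": "MAF_1KG",
    "ESP": "MAF_ESP",
    "ExAC": "MAF_EXAC",
}


def _fmt_float(x: Optional[float]) -> str:
    return _MISSING if x is None else f"{x:g}"


def _fmt_bool(x: bool) -> str:
    return "1" if x else "0"


def _variant_to_row(v: AnnotatedVariant) -> List[str]:
    return [
        v.sample_id,
        v.variant_id,
        v.gene,
        f"{v.quality:g}",
        _fmt_bool(v.in_repeat_region),
        v.consequence,
        str(v.intron_offset),
        _fmt_bool(v.in_last_exon),
        _fmt_float(v.maf_supercontrols),
        *(_fmt_float(v.maf_population.get(db)) for db in POPULATION_DATABASES),
        v.clinvar,
        _fmt_bool(v.known_sequencing_error),
        _fmt_bool(v.known_pathogenic_whitelisted),
    ]


def _row_to_variant(row: Dict[str, str]) -> AnnotatedVariant:
    def opt_float(key: str) -> Optional[float]:
        val = row[key]
        return None if val in (_MISSING, "", None) else float(val)

    maf_population = {
        db: maf
        for db in POPULATION_DATABASES
        if (maf := opt_float(f"maf_{db}")) is not None
    }
    return AnnotatedVariant(
        sample_id=row["sample_id"],
        variant_id=row["variant_id"],
        gene=row["gene"],
        quality=float(row["quality"]),
        in_repeat_region=row["in_repeat_region"] == "1",
        consequence=row["consequence"],
        intron_offset=int(row["intron_offset"]),
        in_last_exon=row["in_last_exon"] == "1",
        maf_supercontrols=opt_float("maf_supercontrols"),
        maf_population=maf_population,
        clinvar=row["clinvar"],
        known_sequencing_error=row["known_sequencing_error"] == "1",
        known_pathogenic_whitelisted=row["known_pathogenic_whitelisted"] == "1",
    )


def write_variant_table(
    variants: Sequence[AnnotatedVariant], path: str | Path, dialect: str = "tsv"
) -> None:
    if dialect == "tsv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(VARIANT_COLUMNS)
            for v in variants:
                writer.writerow(_variant_to_row(v))
    elif dialect == "vcf":
        _write_vcf(variants, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'vcf'")


def read_variant_table(
    path: str | Path, dialect: str = "tsv", on_error: str = "raise"
) -> List[AnnotatedVariant]:
    """Read an annotated variant table.

    ``on_error='raise'`` (default) aborts on the first malformed record
    with its row number; ``'skip'`` logs the record and continues.
    """
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'vcf'")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in VARIANT_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"variant table {path} is missing columns: {missing}")
        variants: List[AnnotatedVariant] = []
        for i, row in enumerate(reader, start=2):  # 1-based, after header
            try:
                variants.append(_row_to_variant(row))
            except (ValidationError, ValueError) as exc:
                msg = f"{path}:{i}: invalid variant record: {exc}"
                if on_error == "skip":
                    logger.warning(msg)
                    continue
                raise ValueError(msg) from exc
    return variants


def variants_to_frame(variants: Sequence[AnnotatedVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        [_variant_to_row(v) for v in variants], columns=list(VARIANT_COLUMNS)
    )


# ---------------------------------------------------------------------------
# VCF dialect

_VCF_HEADER_INFO = [
    ('##INFO=<ID=SMP,Number=1,Type=String,Description="Sample identifier">'),
    ('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">'),
    ('##INFO=<ID=CSQ_CLASS,Number=1,Type=String,Description="Consequence class">'),
    ('##INFO=<ID=INTRON_OFFSET,Number=1,Type=Integer,Description="Signed bp distance from nearest exon boundary">'),
    ('##INFO=<ID=LASTEX,Number=0,Type=Flag,Description="Located in last exon">'),
    ('##INFO=<ID=REPEAT,Number=0,Type=Flag,Description="Repetitive/low-complexity region">'),
    ('##INFO=<ID=MAF_SC,Number=1,Type=Float,Description="Super-control allele frequency">'),
    ('##INFO=<ID=MAF_GNOMAD,Number=1,Type=Float,Description="gnomAD allele frequency">'),
    ('##INFO=<ID=MAF_1KG,Number=1,Type=Float,Description="1000 Genomes allele frequency">'),
    ('##INFO=<ID=MAF_ESP,Number=1,Type=Float,Description="NHLBI GO ESP allele frequency">'),
    ('##INFO=<ID=MAF_EXAC,Number=1,Type=Float,Description="ExAC allele frequency">'),
    ('##INFO=<ID=CLNSIG,Number=1,Type=String,Description="ClinVar interpretation">'),
    ('##INFO=<ID=SEQERR,Number=0,Type=Flag,Description="Known panel sequencing error">'),
    ('##INFO=<ID=KNOWN_PV,Number=0,Type=Flag,Description="Whitelisted known pathogenic variant">'),
]


def _write_vcf(variants: Sequence[AnnotatedVariant], path: str | Path) -> None:
    header = pysam.VariantHeader()
    for line in _VCF_HEADER_INFO:
        header.add_line(line)
    header.contigs.add("synthetic", length=2**29)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for pos, v in enumerate(variants, start=1):
            rec = vcf.new_record(
                contig="synthetic",
                start=pos - 1,
                stop=pos,
                alleles=("N", "A"),
                id=v.variant_id.replace(";", "_").replace(" ", "_"),
                qual=v.quality,
            )
            rec.info["SMP"] = v.sample_id
            rec.info["GENE"] = v.gene
            rec.info["CSQ_CLASS"] = v.consequence
            rec.info["INTRON_OFFSET"] = v.intron_offset
            if v.in_last_exon:
                rec.info["LASTEX"] = True
            if v.in_repeat_region:
                rec.info["REPEAT"] = True
            if v.maf_supercontrols is not None:
                rec.info["MAF_SC"] = v.maf_supercontrols
            for db, key in _VCF_MAF_KEYS.items():
                if db in v.maf_population:
                    rec.info[key] = v.maf_population[db]
            rec.info["CLNSIG"] = v.clinvar
            if v.known_sequencing_error:
                rec.info["SEQERR"] = True
            if v.known_pathogenic_whitelisted:
                rec.info["KNOWN_PV"] = True
            vcf.write(rec)


def _read_vcf(path: str | Path) -> List[AnnotatedVariant]:
    variants: List[AnnotatedVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            for key in ("SMP", "GENE", "CSQ_CLASS", "CLNSIG"):
                if key not in info:
                    raise ValueError(
                        f"{path}: record {rec.id or rec.pos} missing INFO key {key}"
                    )
            # htslib stores floats in 32 bits; round back to the written
            # precision (<= 7 decimals for MAF, 3 for quality).
            maf_population = {
                db: round(float(info[key]), 7)
                for db, key in _VCF_MAF_KEYS.items()
                if key in info
            }
            variants.append(
                AnnotatedVariant(
                    sample_id=str(info["SMP"]),
                    gene=str(info["GENE"]),
                    variant_id=str(rec.id),
                    quality=round(float(rec.qual), 3) if rec.qual is not None else 0.0,
                    in_repeat_region="REPEAT" in info,
                    consequence=str(info["CSQ_CLASS"]),
                    intron_offset=int(info.get("INTRON_OFFSET", 0)),
                    in_last_exon="LASTEX" in info,
                    maf_supercontrols=round(float(info["MAF_SC"]), 7)
                    if "MAF_SC" in info
                    else None,
                    maf_population=maf_population,
                    clinvar=str(info["CLNSIG"]),
                    known_sequencing_error="SEQERR" in info,
                    known_pathogenic_whitelisted="KNOWN_PV" in info,
                )
            )
    return variants


# ---------------------------------------------------------------------------
# Phenotype table

_PHENO_FIXED = (
    "sample_id",
    "group",
    "age_at_dx",
    "sex",
    "etiology",
    "cirrhosis",
    "microangioinvasion",
    "cholangio_differentiation",
    "recurrence_post_tx",
    "multiple_primary_tumors",
    "diabetes",
    "obesity",
    "smoking",
    "family_history",
    "survival_months",
    "event",
)
_PHENO_BOOLS = frozenset(
    {
        "cirrhosis",
        "microangioinvasion",
        "cholangio_differentiation",
        "recurrence_post_tx",
        "multiple_primary_tumors",
        "diabetes",
        "obesity",
        "smoking",
        "family_history",
        "event",
    }
)


def write_phenotype_table(
    records: Sequence[PhenotypeRecord], path: str | Path
) -> None:
    flags: List[str] = []
    for r in records:
        for f in r.carrier_flags:
            if f not in flags:
                flags.append(f)
    header = list(_PHENO_FIXED) + [f"carrier_{f}" for f in flags]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for r in records:
            row = []
            for col in _PHENO_FIXED:
                val = getattr(r, col)
                if col in _PHENO_BOOLS:
                    row.append(_fmt_bool(val))
                elif isinstance(val, float):
                    row.append(f"{val:g}")
                else:
                    row.append(str(val))
            row += [_fmt_bool(r.carrier_flags.get(f, False)) for f in flags]
            writer.writerow(row)


def read_phenotype_table(path: str | Path) -> List[PhenotypeRecord]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in _PHENO_FIXED if c not in header]
        if missing:
            raise ValueError(f"phenotype table {path} is missing columns: {missing}")
        flag_cols = [c for c in header if c.startswith("carrier_")]
        records: List[PhenotypeRecord] = []
        for i, row in enumerate(reader, start=2):
            try:
                kwargs = {
                    col: (row[col] == "1") if col in _PHENO_BOOLS else row[col]
                    for col in _PHENO_FIXED
                }
                kwargs["carrier_flags"] = {
                    c[len("carrier_"):]: row[c] == "1" for c in flag_cols
                }
                records.append(PhenotypeRecord(**kwargs))
            except (ValidationError, ValueError) as exc:
                raise ValueError(f"{path}:{i}: invalid phenotype record: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# Ground truth sidecar

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "planted_carriers": sorted(list(t) for t in truth.planted_carriers),
        "nuisance_labels": dict(sorted(truth.nuisance_labels.items())),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return GroundTruth(
        planted_carriers={tuple(t) for t in payload["planted_carriers"]},
        nuisance_labels=dict(payload["nuisance_labels"]),
    )
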