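"""Readers and writers for the formats the pipeline consumes and produces.

SAM parsing goes through pysam and VCF reading through cyvcf2; VCF writing
emits plain VCF 4.2 text so fixtures stay bit-exact.  Population allele
frequencies live in four INFO floats (AF_1000G, AF_ESP6500, AF_INHOUSE,
AF_EXAC), the consequence in INFO/CSQ and the gene symbol in INFO/GENE.
Malformed lines are reported with their line number.
"""

from __future__ import annotations

import math
from pathlib import Path

import cyvcf2
import pandas as pd
import pysam
from Bio import SeqIO

from .cohort_genomics import GeneSetDB
from .errors import DataFormatError
from .variant_filtering import POP_AF_DATABASES, VariantCall

CELL_COLUMNS = [
    "cell_id", "sample_id", "diameter_um", "nc_ratio",
    "abnormal_karyotype", "hyperchromatic_uneven_nucleus",
    "irregular_nuclear_membrane", "large_nucleoli",
    "abnormal_nuclear_division", "cluster_id",
]
COHORT_COLUMNS = ["patient_id", "ctc_count", "malignant", "lung_rads",
                  "nodule_nature"]
STUDY_COLUMNS = ["study_id", "case_exposed", "case_unexposed",
                 "control_exposed", "control_unexposed"]

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "yes": True, "no": False}


def _to_bool(value, column: str, line: int):
    if isinstance(value, (bool,)):
        return value
    key = str(value).strip().lower()
    if key not in _BOOL_MAP:
        raise DataFormatError(
            f"column {column!r}: cannot parse {value!r} as boolean", line=line
        )
    return _BOOL_MAP[key]


def read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise DataFormatError(f"cannot parse TSV {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataFormatError(
            f"{path}: missing required column(s) {missing}; header has "
            f"{list(df.columns)}", line=1
        )
    return df


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Cell morphology TSV -> typed table (see CELL_COLUMNS for the header)."""
    df = read_tsv(path, CELL_COLUMNS[:-1])  # cluster_id optional
    if "cluster_id" not in df.columns:
        df["cluster_id"] = None
    for i, col in enumerate(df.columns):
        if col in ("diameter_um", "nc_ratio"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        elif col.startswith("abnormal") or col in (
            "hyperchromatic_uneven_nucleus", "irregular_nuclear_membrane",
            "large_nucleoli",
        ):
            df[col] = [
                _to_bool(v, col, line=j + 2) for j, v in enumerate(df[col])
            ]
    df["cluster_id"] = df["cluster_id"].where(df["cluster_id"].notna(), None)
    if "is_tumour_like" in df.columns:
        df["is_tumour_like"] = [
            _to_bool(v, "is_tumour_like", j + 2)
            for j, v in enumerate(df["is_tumour_like"])
        ]
    return df


def write_cell_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, COHORT_COLUMNS)
    df["ctc_count"] = pd.to_numeric(df["ctc_count"], errors="raise").astype(int)
    df["malignant"] = [
        _to_bool(v, "malignant", j + 2) for j, v in enumerate(df["malignant"])
    ]
    return df


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_study_table(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, STUDY_COLUMNS)
    for col in STUDY_COLUMNS[1:]:
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    return df


# ---------------------------------------------------------------------------
# FASTA / SAM
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"no such file: {path}")
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise DataFormatError(f"{path}: no FASTA records found", line=1)
    return seqs


def read_sam(path: str | Path) -> list[pysam.AlignedSegment]:
    """Parse a SAM file into aligned segments, validating line structure."""
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"no such file: {path}")
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            if len(line.split("\t")) < 11:
                raise DataFormatError(
                    f"{path}: SAM record has fewer than 11 fields", line=lineno
                )
    try:
        with pysam.AlignmentFile(str(path), "r") as af:
            return list(af)
    except Exception as exc:
        raise DataFormatError(f"{path}: SAM parse error: {exc}") from exc


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_INFO_KEYS = tuple(f"AF_{db}" for db in POP_AF_DATABASES)


def write_vcf(
    calls: list[VariantCall], contigs: dict[str, int], path: str | Path
) -> None:
    """Plain VCF 4.2 with DP/AO/VAF, the four population AFs, CSQ and GENE."""
    lines = ["##fileformat=VCFv4.2", "##source=ctcdx"]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##INFO=<ID=AO,Number=1,Type=Integer,Description="Alt-supporting reads">',
        '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">',
    ]
    for key in _VCF_INFO_KEYS:
        lines.append(
            f'##INFO=<ID={key},Number=1,Type=Float,'
            f'Description="Population AF ({key[3:]})">'
        )
    lines += [
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##FILTER=<ID=PASS,Description="All filters passed">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for call in sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt)):
        info = [f"DP={call.depth}", f"AO={call.alt_reads}"]
        vaf = 0.0 if math.isnan(call.vaf) else call.vaf
        info.append(f"VAF={vaf:.6g}")
        for db in POP_AF_DATABASES:
            info.append(f"AF_{db}={call.pop_af.get(db, 0.0):.6g}")
        info.append(f"CSQ={call.consequence.replace(' ', '_')}")
        if call.gene:
            info.append(f"GENE={call.gene}")
        filt = "PASS" if call.passed else ";".join(sorted(call.filter_flags))
        lines.append(
            f"{call.chrom}\t{call.pos}\t.\t{call.ref}\t{call.alt}\t.\t"
            f"{filt}\t{';'.join(info)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> list[VariantCall]:
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"no such file: {path}")
    calls: list[VariantCall] = []
    try:
        vcf = cyvcf2.VCF(str(path))
    except Exception as exc:
        raise DataFormatError(f"{path}: VCF parse error: {exc}") from exc
    try:
        for rec in vcf:
            depth = int(rec.INFO.get("DP", 0))
            alt_reads = int(rec.INFO.get("AO", 0))
            vaf = alt_reads / depth if depth > 0 else 0.0
            pop_af = {
                db: float(rec.INFO.get(f"AF_{db}", 0.0))
                for db in POP_AF_DATABASES
            }
            csq = str(rec.INFO.get("CSQ", "non-synonymous")).replace("_", " ")
            gene = rec.INFO.get("GENE")
            flags = set()
            if rec.FILTER:  # cyvcf2 reports PASS as None
                flags = set(str(rec.FILTER).split(";"))
            calls.append(
                VariantCall(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=rec.ALT[0] if rec.ALT else ".",
                    alt_reads=alt_reads,
                    depth=depth,
                    vaf=vaf,
                    pop_af=pop_af,
                    consequence=csq,
                    gene=str(gene) if gene else None,
                    filter_flags=flags,
                )
            )
    finally:
        vcf.close()
    return calls


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(
    path: str | Path, background: set[str] | None = None
) -> GeneSetDB:
    """GMT gene sets: one pathway per line (name, description, genes...).

    A duplicate pathway name is an error.  When no explicit background is
    given, the union of all pathway members is used.
    """
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"no such file: {path}")
    pathways: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataFormatError(
                    f"{path}: GMT line needs name, description and >=1 gene",
                    line=lineno,
                )
            name = fields[0]
            if name in pathways:
                raise DataFormatError(
                    f"{path}: duplicate pathway name {name!r}", line=lineno
                )
            pathways[name] = {g for g in fields[2:] if g}
    if background is None:
        background = set().union(*pathways.values())
    return GeneSetDB(pathways=pathways, background=background)


def write_gmt(db: GeneSetDB, path: str | Path) -> None:
    lines = [
        "\t".join([name, "ctcdx"] + sorted(genes))
        for name, genes in db.pathways.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
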