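"""Readers and writers for the tabular formats the pipeline touches.

All tables are tab-separated UTF-8 with one header line; ``#``-prefixed
lines are comments. Coordinates are 1-based inclusive (MAF/SEG convention);
BED input (0-based half-open) is converted at the boundary. Readers never
silently drop rows: a row that fails parsing or validation is either raised
(strict mode) or collected with its line number in ``ReadResult.rejected``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Generic, Iterable, Iterator, Sequence, TypeVar

import numpy as np
import pandas as pd

from .config import normalize_chrom
from .exceptions import TableFormatError, ValidationError
from .records import EffectClass, GeneInterval, SegmentRecord, VariantRecord
from .variants import classify_effect

logger = logging.getLogger(__name__)

T = TypeVar("T")

#: tolerance for clipping cellular prevalences that stray outside [0, 1]
CP_CLIP_TOL = 1e-6

MAF_MANDATORY = (
    "Tumor_Sample_Barcode",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "t_depth",
    "t_alt_count",
    "caller_evidence",
)

SEG_MANDATORY = ("sample_id", "chrom", "start", "end", "total_copy_number")

LOCI_MANDATORY = ("mutation_id", "cluster_id", "cellular_prevalence")


@dataclass
class ReadResult(Generic[T]):
    """Parsed records plus the rows rejected with line number and reason."""

    records: list[T]
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def __iter__(self) -> Iterator[T]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _read_tsv(path: str | Path, mandatory: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    return df


def _line_number(df_index: int) -> int:
    """1-based file line of a data row (header is line 1, comments aside)."""
    return df_index + 2


def _parse_caller_evidence(text: str) -> dict[str, str]:
    """Parse 'mutect:KEEP;strelka:PASS' into a caller->flag mapping."""
    evidence = {}
    for item in str(text).split(";"):
        item = item.strip()
        if not item:
            continue
        if ":" not in item:
            raise ValueError(f"malformed caller evidence entry {item!r}")
        caller, flag = item.split(":", 1)
        evidence[caller.strip().lower()] = flag.strip()
    if not evidence:
        raise ValueError("empty caller evidence")
    return evidence


def format_caller_evidence(evidence: dict[str, str]) -> str:
    return ";".join(f"{c}:{f}" for c, f in evidence.items())


# ---------------------------------------------------------------------------
# variant tables (MAF-like)
# ---------------------------------------------------------------------------

def read_variant_table(
    path: str | Path,
    dialect: str = "maf_like",
    strict: bool = False,
) -> ReadResult[VariantRecord]:
    """Read a MAF-like variant TSV.

    Effect class is taken from an ``effect_class`` column when present,
    otherwise derived from ``Variant_Classification`` (and
    ``distance_to_splice_site``). With ``strict=True`` the first bad row
    raises; otherwise bad rows are collected in ``rejected``.
    """
    if dialect != "maf_like":
        raise TableFormatError(f"unknown variant-table dialect {dialect!r}")
    df = _read_tsv(path, MAF_MANDATORY)
    records: list[VariantRecord] = []
    rejected: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        line = _line_number(int(idx))
        try:
            records.append(_parse_variant_row(row))
        except (ValueError, ValidationError) as exc:
            if strict:
                raise TableFormatError(f"{path} line {line}: {exc}") from exc
            rejected.append((line, str(exc)))
            logger.warning("%s line %d rejected: %s", path, line, exc)
    logger.info("%s: %d variants read, %d rejected", path, len(records), len(rejected))
    return ReadResult(records=records, rejected=rejected)


def _parse_variant_row(row: pd.Series) -> VariantRecord:
    dist = row.get("distance_to_splice_site", "")
    dist = int(dist) if str(dist).strip() not in ("", "NA", ".") else None
    if "effect_class" in row.index and str(row["effect_class"]).strip():
        effect = EffectClass(str(row["effect_class"]).strip())
    else:
        effect = classify_effect(str(row["Variant_Classification"]).strip(), dist)
    vaf_text = str(row.get("vaf", "")).strip()
    return VariantRecord(
        sample_id=str(row["Tumor_Sample_Barcode"]),
        chrom=str(row["Chromosome"]),
        pos=int(row["Start_Position"]),
        ref=str(row["Reference_Allele"]),
        alt=str(row["Tumor_Seq_Allele2"]),
        effect_class=effect,
        caller_evidence=_parse_caller_evidence(row["caller_evidence"]),
        depth=int(row["t_depth"]),
        alt_count=int(row["t_alt_count"]),
        vaf=float(vaf_text) if vaf_text not in ("", "NA", ".") else None,
        distance_to_splice_site=dist,
        gene=str(row["Hugo_Symbol"]) if "Hugo_Symbol" in row.index else None,
        variant_classification=str(row["Variant_Classification"]),
    )


def write_variant_table(
    records: Iterable[VariantRecord], path: str | Path
) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "Hugo_Symbol": r.gene or "",
                "Tumor_Sample_Barcode": r.sample_id,
                "Chromosome": r.chrom,
                "Start_Position": r.pos,
                "Reference_Allele": r.ref,
                "Tumor_Seq_Allele2": r.alt,
                "Variant_Classification": r.variant_classification or "",
                "effect_class": r.effect_class.value,
                "distance_to_splice_site": (
                    "" if r.distance_to_splice_site is None else r.distance_to_splice_site
                ),
                "t_depth": r.depth,
                "t_alt_count": r.alt_count,
                "vaf": r.vaf,
                "caller_evidence": format_caller_evidence(r.caller_evidence),
            }
        )
    pd.DataFrame(rows, columns=[
        "Hugo_Symbol", "Tumor_Sample_Barcode", "Chromosome", "Start_Position",
        "Reference_Allele", "Tumor_Seq_Allele2", "Variant_Classification",
        "effect_class", "distance_to_splice_site", "t_depth", "t_alt_count",
        "vaf", "caller_evidence",
    ]).to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# segment tables (SEG-like)
# ---------------------------------------------------------------------------

def read_segments(
    path: str | Path, neutral_copy_number: int = 2
) -> list[SegmentRecord]:
    """Read a SEG-like TSV; segments are sorted per sample/chromosome and
    overlapping segments within a sample raise a validation error naming the
    pair. ``is_altered`` is taken from the optional column, else derived as
    ``total_copy_number != neutral_copy_number``.
    """
    df = _read_tsv(path, SEG_MANDATORY)
    segments: list[SegmentRecord] = []
    for idx, row in df.iterrows():
        try:
            cn = int(row["total_copy_number"])
            altered_text = str(row.get("is_altered", "")).strip().lower()
            is_altered = (
                altered_text in ("true", "1", "yes")
                if altered_text
                else cn != neutral_copy_number
            )
            segments.append(
                SegmentRecord(
                    sample_id=str(row["sample_id"]),
                    chrom=str(row["chrom"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    total_copy_number=cn,
                    is_altered=is_altered,
                )
            )
        except (ValueError, ValidationError) as exc:
            raise TableFormatError(
                f"{path} line {_line_number(int(idx))}: {exc}"
            ) from exc
    segments.sort(key=lambda s: (s.sample_id, normalize_chrom(s.chrom), s.start))
    for a, b in zip(segments, segments[1:]):
        if (
            a.sample_id == b.sample_id
            and normalize_chrom(a.chrom) == normalize_chrom(b.chrom)
            and b.start <= a.end
        ):
            raise ValidationError(
                f"{path}: overlapping segments in {a.sample_id} {a.chrom}: "
                f"[{a.start},{a.end}] and [{b.start},{b.end}]"
            )
    logger.info("%s: %d segments read", path, len(segments))
    return segments


def write_segments(segments: Iterable[SegmentRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "total_copy_number": s.total_copy_number,
                "is_altered": s.is_altered,
            }
            for s in segments
        ],
        columns=["sample_id", "chrom", "start", "end", "total_copy_number", "is_altered"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clonal-inference loci tables
# ---------------------------------------------------------------------------

def read_loci_table(path: str | Path) -> pd.DataFrame:
    """Read a clonal-inference loci TSV into a validated DataFrame.

    The ``vaf`` column is filled from ref/alt counts when absent. Cellular
    prevalences outside [0, 1] by at most ``CP_CLIP_TOL`` are clipped with a
    warning; larger excursions raise. Duplicate mutation ids within a sample
    raise.
    """
    df = _read_tsv(path, LOCI_MANDATORY)
    out = pd.DataFrame(
        {
            "mutation_id": df["mutation_id"].astype(str),
            "cluster_id": df["cluster_id"].astype(int),
            "cellular_prevalence": df["cellular_prevalence"].astype(float),
        }
    )
    if "sample_id" in df.columns:
        out.insert(1, "sample_id", df["sample_id"].astype(str))
    else:
        out.insert(1, "sample_id", "")

    has_counts = "ref_count" in df.columns and "alt_count" in df.columns
    if has_counts:
        out["ref_count"] = df["ref_count"].astype(int)
        out["alt_count"] = df["alt_count"].astype(int)
    vaf_col = next(
        (c for c in ("vaf", "variant_allele_frequency") if c in df.columns), None
    )
    if vaf_col is not None and (df[vaf_col].str.strip() != "").all():
        out["vaf"] = df[vaf_col].astype(float)
    elif has_counts:
        depth = out["ref_count"] + out["alt_count"]
        out["vaf"] = np.where(depth > 0, out["alt_count"] / depth, 0.0)
    else:
        raise TableFormatError(
            f"{path}: vaf column absent and not computable (no ref/alt counts)"
        )

    cp = out["cellular_prevalence"].to_numpy()
    bad = (cp < -CP_CLIP_TOL) | (cp > 1 + CP_CLIP_TOL)
    if bad.any():
        raise ValidationError(
            f"{path}: {int(bad.sum())} cellular prevalence value(s) outside "
            f"[-{CP_CLIP_TOL}, 1+{CP_CLIP_TOL}]"
        )
    outside = (cp < 0) | (cp > 1)
    if outside.any():
        logger.warning(
            "%s: clipped %d cellular prevalence value(s) into [0, 1]",
            path,
            int(outside.sum()),
        )
        out["cellular_prevalence"] = np.clip(cp, 0.0, 1.0)

    dup = out.duplicated(subset=["sample_id", "mutation_id"])
    if dup.any():
        dups = out.loc[dup, "mutation_id"].tolist()
        raise ValidationError(f"{path}: duplicate mutation_id within sample: {dups}")
    logger.info("%s: %d loci read", path, len(out))
    return out


def write_loci_table(loci: pd.DataFrame, path: str | Path) -> None:
    loci.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# gene intervals (BED-like) and cohort tables
# ---------------------------------------------------------------------------

def read_gene_intervals(path: str | Path, dialect: str = "bed") -> list[GeneInterval]:
    """Read gene intervals. BED input (0-based, half-open, columns
    chrom/start/end/name) is converted to 1-based inclusive coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genes: list[GeneInterval] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise TableFormatError(
                    f"{path} line {line_no}: expected chrom/start/end/name"
                )
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if dialect == "bed":
                start, end = start + 1, end  # half-open 0-based -> inclusive 1-based
            genes.append(GeneInterval(gene_id=name, chrom=chrom, start=start, end=end))
    return genes


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read a cohort metadata/metrics TSV (sample_id plus arbitrary columns)."""
    df = _read_tsv(path, ("sample_id",))
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample_id values")
    # convert numeric-looking columns back from text; empty cells become NaN
    for col in df.columns:
        if col == "sample_id":
            continue
        blanked = df[col].mask(df[col].str.strip() == "")
        converted = pd.to_numeric(blanked, errors="coerce")
        if converted.notna().equals(blanked.notna()):
            df[col] = converted
    return df


def write_cohort_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
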