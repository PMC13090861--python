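"""CNV burden and gene-level amplification/deletion calls.

CNV burden is the fraction of the genome covered by copy-number-altered
segments. A gene is called amplified (deleted) when at least ``min_overlap``
(default 80%) of its length is covered by the union of segments at or above
the amplification threshold (at or below the deletion threshold).
"""
from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .config import normalize_chrom
from .exceptions import ValidationError
from .records import CnvBurdenResult, GeneCall, GeneCnvCall, GeneInterval, SegmentRecord

logger = logging.getLogger(__name__)


def _check_non_overlapping(segments: Sequence[SegmentRecord]) -> None:
    by_key: dict[tuple[str, str], list[SegmentRecord]] = {}
    for seg in segments:
        by_key.setdefault((seg.sample_id, normalize_chrom(seg.chrom)), []).append(seg)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"overlapping segments in {sample} chr{chrom}: "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )


def _is_altered(seg: SegmentRecord, neutral_copy_number: int) -> bool:
    return seg.is_altered or seg.total_copy_number != neutral_copy_number


def cnv_burden(
    segments: Iterable[SegmentRecord],
    genome_size_bp: int,
    neutral_copy_number: int = 2,
    sample_id: str | None = None,
) -> CnvBurdenResult:
    """Fraction of the genome covered by altered segments of one sample."""
    segments = list(segments)
    if genome_size_bp <= 0:
        raise ValidationError(f"genome_size_bp must be > 0, got {genome_size_bp}")
    _check_non_overlapping(segments)
    if sample_id is None:
        sample_id = segments[0].sample_id if segments else ""
    altered_bp = sum(
        seg.span for seg in segments if _is_altered(seg, neutral_copy_number)
    )
    if altered_bp > genome_size_bp:
        raise ValidationError(
            f"{sample_id}: altered span {altered_bp} bp exceeds genome size "
            f"{genome_size_bp} bp"
        )
    burden = min(1.0, max(0.0, altered_bp / genome_size_bp))
    logger.info("%s: CNV burden %.4f (%d bp altered)", sample_id, burden, altered_bp)
    return CnvBurdenResult(
        sample_id=sample_id,
        altered_bp=altered_bp,
        genome_size_bp=genome_size_bp,
        burden=burden,
    )


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for start, end in intervals[1:]:
        if start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _covered_bp(gene: GeneInterval, intervals: list[tuple[int, int]]) -> int:
    covered = 0
    for start, end in intervals:
        lo = max(gene.start, start)
        hi = min(gene.end, end)
        if lo <= hi:
            covered += hi - lo + 1
    return covered


def annotate_gene_cnv(
    segments: Iterable[SegmentRecord],
    genes: Iterable[GeneInterval],
    amp_threshold: int = 3,
    del_threshold: int = 1,
    min_overlap: float = 0.8,
    sample_id: str | None = None,
) -> list[GeneCnvCall]:
    """Classify genes as amplified/deleted by fractional overlap.

    Overlap is computed against the union of same-direction altered segments
    per chromosome; a direction wins when it covers at least ``min_overlap``
    of the gene. If both directions reach the threshold the larger coverage
    wins, with exact ties reported as ``none`` with a warning.
    """
    segments = list(segments)
    _check_non_overlapping(segments)
    if sample_id is None:
        sample_id = segments[0].sample_id if segments else ""

    amp_by_chrom: dict[str, list[tuple[int, int]]] = {}
    del_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for seg in segments:
        chrom = normalize_chrom(seg.chrom)
        if seg.total_copy_number >= amp_threshold:
            amp_by_chrom.setdefault(chrom, []).append((seg.start, seg.end))
        elif seg.total_copy_number <= del_threshold:
            del_by_chrom.setdefault(chrom, []).append((seg.start, seg.end))
    amp_by_chrom = {c: _merge_intervals(v) for c, v in amp_by_chrom.items()}
    del_by_chrom = {c: _merge_intervals(v) for c, v in del_by_chrom.items()}

    calls: list[GeneCnvCall] = []
    for gene in genes:
        if gene.length <= 0:
            raise ValidationError(f"gene {gene.gene_id} has non-positive length")
        chrom = normalize_chrom(gene.chrom)
        amp_frac = _covered_bp(gene, amp_by_chrom.get(chrom, [])) / gene.length
        del_frac = _covered_bp(gene, del_by_chrom.get(chrom, [])) / gene.length
        call = GeneCall.NONE
        overlap = max(amp_frac, del_frac)
        if amp_frac >= min_overlap and del_frac >= min_overlap:
            if amp_frac > del_frac:
                call = GeneCall.AMPLIFIED
            elif del_frac > amp_frac:
                call = GeneCall.DELETED
            else:
                logger.warning(
                    "%s gene %s: amplified and deleted coverage tie at %.3f -> none",
                    sample_id,
                    gene.gene_id,
                    amp_frac,
                )
        elif amp_frac >= min_overlap:
            call = GeneCall.AMPLIFIED
        elif del_frac >= min_overlap:
            call = GeneCall.DELETED
        calls.append(
            GeneCnvCall(
                gene_id=gene.gene_id,
                sample_id=sample_id,
                call=call,
                overlap_fraction=overlap,
            )
        )
        logger.debug(
            "%s gene %s: amp %.3f del %.3f -> %s",
            sample_id,
            gene.gene_id,
            amp_frac,
            del_frac,
            call.value,
        )
    return calls
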