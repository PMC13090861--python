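"""Somatic-variant retention filters, effect classification, and TMB.

Retention keeps high-confidence calls only: allele frequency >= 5%, read
depth >= 10x, consensus of at least two callers, and per-caller
high-confidence flags ("KEEP" for MuTect, "PASS" for Strelka) for every
caller that reported the variant. TMB is the count of nonsilent mutations
(splicing included) divided by the sequenced exome size in megabases, and is
classified with the childhood-cancer thresholds: "pediatric high" for
2-10 muts/Mb (inclusive) and "hypermutator" above 10 muts/Mb.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .exceptions import ValidationError
from .records import EffectClass, TmbCategory, TmbResult, VariantRecord

logger = logging.getLogger(__name__)

#: MAF Variant_Classification values treated as nonsilent (impact-based).
NONSILENT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Translation_Start_Site",
        "Splice_Site",
        "Splice_Region",
    }
)

SILENT_CLASSES = frozenset({"Silent", "Synonymous"})

#: distance (bp) from a splice site at or under which a variant is splicing
SPLICE_DISTANCE_BP = 2

PEDIATRIC_HIGH_MIN = 2.0
HYPERMUTATOR_MIN = 10.0


@dataclass
class FilterResult:
    """Retained records plus every rejection with its first failing criterion."""

    retained: list[VariantRecord]
    rejected: list[tuple[VariantRecord, str]]

    def __iter__(self):
        return iter(self.retained)

    def __len__(self) -> int:
        return len(self.retained)


def filter_variants(
    records: Iterable[VariantRecord],
    af_min: float = 0.05,
    depth_min: int = 10,
    min_callers: int = 2,
    required_flags: Mapping[str, str] | None = None,
) -> FilterResult:
    """Apply the variant-retention filters, preserving input order.

    A record is retained iff vaf >= af_min, depth >= depth_min, at least
    ``min_callers`` callers reported it, and every caller in
    ``required_flags`` that appears in its evidence carries the required
    flag. Rejections are reported with the first failing criterion, checked
    in the order af, depth, callers, flag.
    """
    if required_flags is None:
        required_flags = {"mutect": "KEEP", "strelka": "PASS"}
    retained: list[VariantRecord] = []
    rejected: list[tuple[VariantRecord, str]] = []
    for rec in records:
        reason = _first_failure(rec, af_min, depth_min, min_callers, required_flags)
        if reason is None:
            retained.append(rec)
        else:
            rejected.append((rec, reason))
            logger.debug(
                "rejected %s %s:%s (%s)", rec.sample_id, rec.chrom, rec.pos, reason
            )
    logger.info(
        "variant filter: %d retained, %d rejected", len(retained), len(rejected)
    )
    return FilterResult(retained=retained, rejected=rejected)


def _first_failure(rec, af_min, depth_min, min_callers, required_flags):
    if rec.vaf < af_min:
        return "af"
    if rec.depth < depth_min:
        return "depth"
    if len(rec.caller_evidence) < min_callers:
        return "callers"
    for caller, flag in rec.caller_evidence.items():
        required = required_flags.get(caller.lower())
        if required is not None and flag != required:
            return "flag"
    return None


def classify_effect(
    variant_classification: str,
    distance_to_splice_site: int | None = None,
) -> EffectClass:
    """Classify a variant's functional effect.

    Splicing takes precedence: any variant within ``SPLICE_DISTANCE_BP`` of a
    splice site is splicing regardless of its annotation string. Unknown
    classification strings fall through to ``other`` with a warning, never an
    exception.
    """
    if (
        distance_to_splice_site is not None
        and abs(distance_to_splice_site) <= SPLICE_DISTANCE_BP
    ):
        return EffectClass.SPLICING
    if variant_classification in NONSILENT_CLASSES:
        return EffectClass.NONSILENT
    if variant_classification in SILENT_CLASSES:
        return EffectClass.SILENT
    logger.warning(
        "unknown variant classification %r -> other", variant_classification
    )
    return EffectClass.OTHER


def classify_tmb(tmb: float) -> TmbCategory:
    """Childhood-cancer TMB class: >10 hypermutator, 2-10 pediatric high."""
    if tmb < 0:
        raise ValidationError(f"negative TMB {tmb}")
    if tmb > HYPERMUTATOR_MIN:
        return TmbCategory.HYPERMUTATOR
    if tmb >= PEDIATRIC_HIGH_MIN:
        return TmbCategory.PEDIATRIC_HIGH
    return TmbCategory.LOW


def compute_tmb(
    records: Sequence[VariantRecord],
    exome_size_mb: float,
    sample_id: str | None = None,
) -> TmbResult:
    """TMB of an already-filtered variant set.

    Counts records whose effect class is nonsilent or splicing and divides by
    the exome size in megabases.
    """
    if exome_size_mb is None or exome_size_mb <= 0:
        raise ValidationError(f"exome_size_mb must be > 0, got {exome_size_mb}")
    records = list(records)
    if sample_id is None:
        sample_id = records[0].sample_id if records else ""
    n_nonsilent = sum(
        1
        for r in records
        if r.effect_class in (EffectClass.NONSILENT, EffectClass.SPLICING)
    )
    tmb = n_nonsilent / exome_size_mb
    return TmbResult(
        sample_id=sample_id,
        n_nonsilent=n_nonsilent,
        exome_size_mb=exome_size_mb,
        tmb=tmb,
        category=classify_tmb(tmb),
    )
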