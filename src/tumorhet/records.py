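"""Core domain records shared across the pipeline.

Coordinates are 1-based and inclusive on both ends (MAF/SEG convention);
half-open input dialects such as BED are converted at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ValidationError

#: absolute tolerance for vaf == alt_count/depth when both are given;
#: covers text output rounded to >= 4 decimal places.
VAF_ROUNDING_TOL = 5e-4


class EffectClass(str, Enum):
    """Functional impact class of a somatic variant."""

    NONSILENT = "nonsilent"
    SILENT = "silent"
    SPLICING = "splicing"
    OTHER = "other"


class TmbCategory(str, Enum):
    """Childhood-cancer TMB class."""

    LOW = "low"
    PEDIATRIC_HIGH = "pediatric_high"
    HYPERMUTATOR = "hypermutator"


class GeneCall(str, Enum):
    AMPLIFIED = "amplified"
    DELETED = "deleted"
    NONE = "none"


@dataclass
class VariantRecord:
    """One annotated somatic variant with multi-caller evidence.

    ``caller_evidence`` maps caller name to the flag it reported for this
    variant (e.g. ``{"mutect": "KEEP", "strelka": "PASS"}``).
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    effect_class: EffectClass
    caller_evidence: Mapping[str, str]
    depth: int
    alt_count: int
    vaf: float | None = None
    distance_to_splice_site: int | None = None
    gene: str | None = None
    variant_classification: str | None = None

    def __post_init__(self) -> None:
        self.effect_class = EffectClass(self.effect_class)
        self.caller_evidence = dict(self.caller_evidence)
        if not self.caller_evidence:
            raise ValidationError(
                f"{self.sample_id} {self.chrom}:{self.pos}: caller_evidence is empty"
            )
        if self.depth < 0 or self.alt_count < 0:
            raise ValidationError(
                f"{self.sample_id} {self.chrom}:{self.pos}: negative read counts"
            )
        if self.alt_count > self.depth:
            raise ValidationError(
                f"{self.sample_id} {self.chrom}:{self.pos}: "
                f"alt_count {self.alt_count} > depth {self.depth}"
            )
        if self.vaf is None:
            self.vaf = self.alt_count / self.depth if self.depth else 0.0
        elif self.depth > 0:
            implied = self.alt_count / self.depth
            if abs(self.vaf - implied) > VAF_ROUNDING_TOL:
                raise ValidationError(
                    f"{self.sample_id} {self.chrom}:{self.pos}: vaf {self.vaf} "
                    f"inconsistent with alt_count/depth = {implied:.6f}"
                )


@dataclass
class SegmentRecord:
    """A copy-number segment: 1-based inclusive interval with total copy number."""

    sample_id: str
    chrom: str
    start: int
    end: int
    total_copy_number: int
    is_altered: bool

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"{self.sample_id} {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.total_copy_number < 0:
            raise ValidationError(
                f"{self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                "negative copy number"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneInterval:
    """A gene locus as a 1-based inclusive interval."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene_id}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class LocusObservation:
    """One somatic mutation's read evidence and inferred cellular prevalence."""

    mutation_id: str
    cellular_prevalence: float
    vaf: float
    ref_count: int | None = None
    alt_count: int | None = None


@dataclass
class CloneCluster:
    """A subclone: a non-empty set of mutations sharing a cellular prevalence.

    Means are computed from the members, so they stay consistent through
    merging by construction.
    """

    label: str
    members: list[LocusObservation]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"cluster {self.label} has no members")

    @property
    def mean_cp(self) -> float:
        return float(np.mean([m.cellular_prevalence for m in self.members]))

    @property
    def mean_vaf(self) -> float:
        return float(np.mean([m.vaf for m in self.members]))

    @property
    def cp_values(self) -> np.ndarray:
        return np.array([m.cellular_prevalence for m in self.members], dtype=float)

    @property
    def vaf_values(self) -> np.ndarray:
        return np.array([m.vaf for m in self.members], dtype=float)

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class MergeEvent:
    """One merge decision, for the audit log."""

    stage: int
    merged_labels: tuple[str, ...]
    distance: float | None = None
    p_cp: float | None = None
    p_vaf: float | None = None


@dataclass
class ClonalStructure:
    """Per-sample subclonal decomposition and its Shannon-diversity ITH score."""

    sample_id: str
    clusters: list[CloneCluster]
    proportions: np.ndarray
    ith_score: float
    provenance: str  # "ingested" | "builtin_clustering"
    merge_log: list[MergeEvent] = field(default_factory=list)
    n_clusters_initial: int = 0
    n_after_stage1: int = 0
    n_after_stage2: int = 0


@dataclass
class TmbResult:
    """Tumor mutational burden of one sample, in mutations per megabase."""

    sample_id: str
    n_nonsilent: int
    exome_size_mb: float
    tmb: float
    category: TmbCategory


@dataclass
class CnvBurdenResult:
    """Fraction of the genome covered by copy-number-altered segments."""

    sample_id: str
    altered_bp: int
    genome_size_bp: int
    burden: float


@dataclass
class GeneCnvCall:
    """Amplification/deletion call for one gene in one sample."""

    gene_id: str
    sample_id: str
    call: GeneCall
    overlap_fraction: float


@dataclass
class GroupComparison:
    """Two-sided rank-sum comparison of a metric between two sample groups."""

    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    p_value: float
    method: str  # "exact" | "normal_approx"
    n_excluded: int = 0
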