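"""Pipeline configuration: thresholds, genome constants, YAML round trip."""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigurationError

#: Sum of the GRCh37/hg19 autosome lengths (chr1-22). The CNV-burden
#: denominator defaults to the autosomal genome; include sex chromosomes by
#: overriding ``genome_size_bp``.
GRCH37_AUTOSOMAL_BP = 2_881_033_286


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline with their defaults.

    Variant retention: ``af_min`` (allele-frequency floor), ``depth_min``
    (read-depth floor), ``min_callers`` (multi-caller consensus), and
    ``required_flags`` (per-caller high-confidence flags, enforced only for
    callers present in a record's evidence).

    ITH: ``merge_cutoff`` is the average-linkage dendrogram cut height in
    CP/VAF units for stage-1 merging; ``wilcoxon_alpha`` the stage-2 merge
    threshold (clusters merge when both CP and VAF rank-sum p-values exceed
    it); ``k_max`` the largest mixture size tried by the built-in clustering.
    """

    af_min: float = 0.05
    depth_min: int = 10
    min_callers: int = 2
    required_flags: dict[str, str] = field(
        default_factory=lambda: {"mutect": "KEEP", "strelka": "PASS"}
    )

    # TMB; no default denominator: the captured footprint must be stated.
    exome_size_mb: float | None = None

    # CNV
    genome_size_bp: int = GRCH37_AUTOSOMAL_BP
    neutral_copy_number: int = 2
    amp_threshold: int = 3
    del_threshold: int = 1
    min_overlap: float = 0.8

    # ITH
    merge_cutoff: float = 0.05
    wilcoxon_alpha: float = 0.05
    k_max: int = 6
    stage1_scope: str = "all"  # "all" | "singletons_only"
    stage1_features: str = "cp_vaf"  # "cp_vaf" | "cp"

    # chromosome-name comparison
    strip_chr_prefix: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.af_min <= 1.0:
            raise ConfigurationError(f"af_min must be in [0,1], got {self.af_min}")
        if self.stage1_scope not in ("all", "singletons_only"):
            raise ConfigurationError(f"unknown stage1_scope {self.stage1_scope!r}")
        if self.stage1_features not in ("cp_vaf", "cp"):
            raise ConfigurationError(f"unknown stage1_features {self.stage1_features!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


def normalize_chrom(chrom: str, strip_prefix: bool = True) -> str:
    """Canonical chromosome name for comparisons ('chr17' == '17')."""
    c = str(chrom).strip()
    if strip_prefix and c.lower().startswith("chr"):
        c = c[3:]
    return c
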