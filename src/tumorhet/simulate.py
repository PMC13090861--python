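"""Synthetic tumors, segment tables, variant tables, and cohorts.

The generators emulate the statistical structure the downstream statistics
assume, at desk scale: subclonal tumors with known cellular prevalences and
binomial read sampling, copy-number segment tables with a prescribed
altered-genome fraction, variant tables that satisfy (or deliberately
violate) the retention filters, and cohorts of samples with group-wise
metric shifts. Everything is deterministic given its seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .clonal import expected_vaf, vaf_to_cp
from .exceptions import ConfigurationError, ValidationError
from .records import SegmentRecord, VariantRecord
from .variants import NONSILENT_CLASSES

logger = logging.getLogger(__name__)

LN6 = float(np.log(6.0))


# ---------------------------------------------------------------------------
# subclonal tumors
# ---------------------------------------------------------------------------

@dataclass
class SubcloneTruth:
    """Ground truth of a simulated tumor.

    ``subclone_cp`` holds one cellular prevalence per subclone;
    ``mutations_per_subclone`` the matching mutation counts. Read depth is
    Poisson with mean ``mean_depth`` (floored at 1 read).
    """

    subclone_cp: Sequence[float]
    mutations_per_subclone: Sequence[int]
    purity: float = 1.0
    mean_depth: float = 500.0
    tumor_copy_number: int = 2
    seed: int = 0
    sample_id: str = "synthetic"

    def __post_init__(self) -> None:
        self.subclone_cp = [float(c) for c in self.subclone_cp]
        self.mutations_per_subclone = [int(n) for n in self.mutations_per_subclone]
        if len(self.subclone_cp) != len(self.mutations_per_subclone):
            raise ValidationError("subclone_cp and mutations_per_subclone differ in length")
        if not self.subclone_cp:
            raise ValidationError("at least one subclone is required")
        if any(not 0 < c <= 1 for c in self.subclone_cp):
            raise ValidationError("subclone CPs must be in (0, 1]")
        if any(n <= 0 for n in self.mutations_per_subclone):
            raise ValidationError("mutation counts must be positive")
        if not 0 < self.purity <= 1:
            raise ValidationError(f"purity must be in (0, 1], got {self.purity}")
        if self.mean_depth <= 0:
            raise ValidationError("mean_depth must be positive")

    @property
    def n_subclones(self) -> int:
        return len(self.subclone_cp)

    def true_ith(self) -> float:
        """Shannon index of the normalized true subclone CPs."""
        cps = np.asarray(self.subclone_cp, dtype=float)
        p = cps / cps.sum()
        if p.size == 1:
            return 0.0
        return float(-(p * np.log(p)).sum())


def simulate_subclonal_tumor(truth: SubcloneTruth) -> tuple[pd.DataFrame, SubcloneTruth]:
    """Simulate the loci table of one subclonal tumor.

    For each mutation of subclone j, depth ~ max(1, Poisson(mean_depth)),
    alt_count ~ Binomial(depth, E[VAF]) with
    E[VAF] = purity * CP_j / (purity * CN_t + 2 (1 - purity)), and the
    ``cellular_prevalence`` column holds the per-mutation maximum-likelihood
    CP implied by the observed VAF (inverse mapping, clipped to [0, 1]) —
    the same shape as an external clonal-inference tool's loci output.
    """
    rng = np.random.default_rng(truth.seed)
    rows = []
    mut_idx = 0
    for j, (cp, n_mut) in enumerate(
        zip(truth.subclone_cp, truth.mutations_per_subclone)
    ):
        evaf = expected_vaf(cp, truth.purity, truth.tumor_copy_number)
        if evaf > 1:
            raise ConfigurationError(
                f"subclone {j}: expected VAF {evaf:.3f} > 1 under the CP->VAF mapping"
            )
        depth = np.maximum(1, rng.poisson(truth.mean_depth, size=n_mut))
        alt = rng.binomial(depth, evaf)
        vaf = alt / depth
        for d, a, v in zip(depth, alt, vaf):
            rows.append(
                {
                    "mutation_id": f"m{mut_idx:05d}",
                    "sample_id": truth.sample_id,
                    "cluster_id": j,
                    "cellular_prevalence": vaf_to_cp(
                        float(v), truth.purity, truth.tumor_copy_number
                    ),
                    "vaf": float(v),
                    "ref_count": int(d - a),
                    "alt_count": int(a),
                }
            )
            mut_idx += 1
    loci = pd.DataFrame(rows)
    logger.info(
        "simulated tumor %s: %d subclones, %d mutations",
        truth.sample_id,
        truth.n_subclones,
        len(loci),
    )
    return loci, truth


# ---------------------------------------------------------------------------
# segment tables
# ---------------------------------------------------------------------------

def _integer_split(total: int, parts: int, rng, min_part: int = 0) -> np.ndarray:
    """Split ``total`` into ``parts`` non-negative integers (each >= min_part)."""
    if parts == 0:
        return np.zeros(0, dtype=np.int64)
    spare = total - parts * min_part
    if spare < 0:
        raise ValidationError(f"cannot split {total} into {parts} parts of >= {min_part}")
    cuts = np.sort(rng.integers(0, spare + 1, size=parts - 1))
    pieces = np.diff(np.concatenate([[0], cuts, [spare]]))
    return pieces + min_part


def simulate_segments(
    genome_size_bp: int,
    altered_fraction: float,
    n_segments: int,
    seed: int = 0,
    sample_id: str = "synthetic",
    chrom: str = "1",
    neutral_copy_number: int = 2,
) -> list[SegmentRecord]:
    """Simulate a non-overlapping segment table on one synthetic chromosome.

    ``n_segments`` altered segments are interleaved with neutral gaps so the
    altered spans sum exactly to round(altered_fraction * genome_size_bp).
    Altered copy numbers are drawn from {0, 1, 3, 4, 5}.
    """
    if not 0 <= altered_fraction <= 1:
        raise ValidationError(f"altered_fraction must be in [0, 1], got {altered_fraction}")
    if genome_size_bp <= 0 or n_segments <= 0:
        raise ValidationError("genome_size_bp and n_segments must be positive")
    rng = np.random.default_rng(seed)
    target = int(round(altered_fraction * genome_size_bp))
    if target > genome_size_bp:
        raise ValidationError("requested altered span exceeds the genome")

    if target == 0:
        bounds = np.cumsum(_integer_split(genome_size_bp, n_segments, rng, min_part=1))
        starts = np.concatenate([[1], bounds[:-1] + 1])
        return [
            SegmentRecord(sample_id, chrom, int(s), int(e), neutral_copy_number, False)
            for s, e in zip(starts, bounds)
        ]

    n_alt = min(n_segments, target)  # each altered segment needs >= 1 bp
    alt_lengths = _integer_split(target, n_alt, rng, min_part=1)
    gap_lengths = _integer_split(genome_size_bp - target, n_alt + 1, rng, min_part=0)
    altered_cns = [
        cn for cn in rng.choice([0, 1, 3, 4, 5], size=n_alt)
    ]

    segments: list[SegmentRecord] = []
    pos = 1
    for i in range(n_alt):
        gap = int(gap_lengths[i])
        if gap > 0:
            segments.append(
                SegmentRecord(
                    sample_id, chrom, pos, pos + gap - 1, neutral_copy_number, False
                )
            )
            pos += gap
        span = int(alt_lengths[i])
        segments.append(
            SegmentRecord(sample_id, chrom, pos, pos + span - 1, int(altered_cns[i]), True)
        )
        pos += span
    tail = int(gap_lengths[-1])
    if tail > 0:
        segments.append(
            SegmentRecord(sample_id, chrom, pos, pos + tail - 1, neutral_copy_number, False)
        )
    return segments


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

_FAILURE_MODES = ("low_depth", "low_vaf", "single_caller")


def simulate_variant_table(
    n_nonsilent: int,
    n_silent: int,
    exome_size_mb: float = 60.0,
    seed: int = 0,
    sample_id: str = "synthetic",
    spike_failures: int = 0,
) -> list[VariantRecord]:
    """Simulate an annotated variant table.

    All regular records satisfy the retention filters by construction
    (two-caller evidence with the required flags, depth >= 10, VAF >= 5%).
    ``spike_failures`` appends that many known-bad nonsilent rows cycling
    through the failure modes depth < 10, VAF < 5%, and single-caller.
    """
    if n_nonsilent < 0 or n_silent < 0 or spike_failures < 0:
        raise ValidationError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    exome_bp = int(exome_size_mb * 1e6)
    records: list[VariantRecord] = []
    nonsilent_vocab = sorted(NONSILENT_CLASSES - {"Splice_Site", "Splice_Region"})

    def base_fields():
        return {
            "sample_id": sample_id,
            "chrom": str(rng.integers(1, 23)),
            "pos": int(rng.integers(1, max(exome_bp, 2))),
            "ref": str(rng.choice(list("ACGT"))),
            "alt": str(rng.choice(list("ACGT"))),
        }

    def passing_counts():
        depth = int(rng.integers(50, 200))
        alt = max(int(np.ceil(0.05 * depth)), int(rng.binomial(depth, 0.3)))
        return depth, min(alt, depth)

    for classification, n in (("nonsilent", n_nonsilent), ("silent", n_silent)):
        for _ in range(n):
            depth, alt = passing_counts()
            vc = (
                str(rng.choice(nonsilent_vocab))
                if classification == "nonsilent"
                else "Silent"
            )
            evidence = {"mutect": "KEEP", "strelka": "PASS"}
            if rng.random() < 0.5:
                evidence["varscan2"] = "PASS"
            records.append(
                VariantRecord(
                    **base_fields(),
                    effect_class=classification,
                    caller_evidence=evidence,
                    depth=depth,
                    alt_count=alt,
                    variant_classification=vc,
                )
            )

    for i in range(spike_failures):
        mode = _FAILURE_MODES[i % len(_FAILURE_MODES)]
        if mode == "low_depth":
            depth, alt = 9, 3
            evidence = {"mutect": "KEEP", "strelka": "PASS"}
        elif mode == "low_vaf":
            depth, alt = 200, 5  # VAF 0.025
            evidence = {"mutect": "KEEP", "strelka": "PASS"}
        else:
            depth, alt = passing_counts()
            evidence = {"mutect": "KEEP"}
        records.append(
            VariantRecord(
                **base_fields(),
                effect_class="nonsilent",
                caller_evidence=evidence,
                depth=depth,
                alt_count=alt,
                variant_classification="Missense_Mutation",
            )
        )
    logger.info(
        "simulated variant table %s: %d nonsilent, %d silent, %d spiked failures",
        sample_id,
        n_nonsilent,
        n_silent,
        spike_failures,
    )
    return records


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class MetricDistribution:
    """A named sampling distribution for a per-sample metric."""

    name: str
    params: dict = field(default_factory=dict)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = self.params
        if self.name == "normal":
            return rng.normal(p.get("loc", 0.0), p.get("scale", 1.0), size=n)
        if self.name == "lognormal":
            return rng.lognormal(p.get("mean", 0.0), p.get("sigma", 1.0), size=n)
        if self.name == "beta":
            raw = rng.beta(p["a"], p["b"], size=n)
            return p.get("loc", 0.0) + p.get("scale", 1.0) * raw
        if self.name == "uniform":
            return rng.uniform(p.get("low", 0.0), p.get("high", 1.0), size=n)
        if self.name == "gamma":
            return rng.gamma(p["shape"], p.get("scale", 1.0), size=n)
        raise ConfigurationError(f"unknown distribution {self.name!r}")


@dataclass
class GroupSpec:
    label: str
    n_samples: int
    distribution: MetricDistribution

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError(f"group {self.label}: n_samples must be >= 1")


@dataclass
class CohortSpec:
    groups: list[GroupSpec]
    metric: str = "ith"
    group_field: str = "group"
    seed: int = 0


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a cohort table: one row per sample with its group label and
    metric value drawn i.i.d. from the group's distribution."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    idx = 0
    for group in spec.groups:
        values = group.distribution.sample(rng, group.n_samples)
        for v in values:
            rows.append(
                {
                    "sample_id": f"s{idx:04d}",
                    spec.group_field: group.label,
                    spec.metric: float(v),
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def disease_status_cohort_spec(seed: int = 0) -> CohortSpec:
    """Default ITH cohort mirroring a primary/recurrent/metastasis contrast.

    Group sizes follow a realistic Ewing-sarcoma disease-status composition
    (17 primary, 9 recurrent, 13 metastatic samples); ITH
    scores are Beta-distributed and rescaled to [0, ln 6], the Shannon-index
    range for up to six subclones, with recurrent and metastatic tumors
    shifted toward higher heterogeneity.
    """
    return CohortSpec(
        groups=[
            GroupSpec("primary", 17, MetricDistribution("beta", {"a": 2, "b": 6, "scale": LN6})),
            GroupSpec("recurrent", 9, MetricDistribution("beta", {"a": 6, "b": 3, "scale": LN6})),
            GroupSpec("metastasis", 13, MetricDistribution("beta", {"a": 5, "b": 3, "scale": LN6})),
        ],
        metric="ith",
        group_field="disease_status",
        seed=seed,
    )
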