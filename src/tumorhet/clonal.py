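"""Intratumoral-heterogeneity pipeline.

The per-sample procedure:

1. Every somatic mutation carries a cellular prevalence (CP) — the fraction
   of tumor cells harboring it — either ingested from an external
   clonal-inference tool's loci table or derived from the VAF through the
   purity/copy-number mapping ``vaf_to_cp``.
2. Mutations are grouped into subclone clusters: either the ingested cluster
   assignments are used, or a built-in stand-in fits a one-dimensional
   binomial mixture over read counts by EM, selecting the number of
   components with BIC.
3. Two merging stages reduce noise: stage 1 applies average-linkage
   hierarchical clustering to cluster centroids in (mean CP, mean VAF) space
   and merges groups within a 0.05 cut height; stage 2 iteratively merges
   cluster pairs whose CP and VAF distributions are both indistinguishable
   by a two-sided rank-sum test (P > 0.05 on both).
4. Mean CPs of the final subclones are normalized to proportions p_i and the
   ITH score is the Shannon diversity index H' = -sum p_i ln p_i (nats).
"""
from __future__ import annotations

import itertools
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import gammaln

from .exceptions import MissingPurityError, ValidationError
from .ranksum import rank_sum_test
from .records import ClonalStructure, CloneCluster, LocusObservation, MergeEvent

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# CP <-> VAF mapping
# ---------------------------------------------------------------------------

def expected_vaf(
    cp: float,
    purity: float,
    tumor_copy_number: int = 2,
    multiplicity: int = 1,
) -> float:
    """Expected VAF of a mutation at cellular prevalence ``cp``.

    Assumes the mutation is present on ``multiplicity`` of the
    ``tumor_copy_number`` tumor alleles and that normal cells are diploid:

        E[VAF] = purity * cp * m / (purity * CN_t + 2 * (1 - purity))
    """
    if not 0 < purity <= 1:
        raise ValidationError(f"purity must be in (0, 1], got {purity}")
    denom = purity * tumor_copy_number + 2.0 * (1.0 - purity)
    return purity * cp * multiplicity / denom


def vaf_to_cp(
    vaf: float,
    purity: float,
    tumor_copy_number: int = 2,
    multiplicity: int = 1,
) -> float:
    """Maximum-likelihood cellular prevalence implied by an observed VAF.

    Inverse of :func:`expected_vaf`, clipped to [0, 1].
    """
    if not 0 < purity <= 1:
        raise ValidationError(f"purity must be in (0, 1], got {purity}")
    denom = purity * tumor_copy_number + 2.0 * (1.0 - purity)
    cp = vaf * denom / (purity * multiplicity)
    return float(min(1.0, max(0.0, cp)))


# ---------------------------------------------------------------------------
# built-in clustering stand-in (binomial mixture + BIC)
# ---------------------------------------------------------------------------

def _em_binomial_mixture(alt, depth, k, theta0, weights0, max_iter=500, tol=1e-8):
    """EM for a k-component binomial mixture on (alt, depth) counts.

    Returns (log_likelihood, theta, weights, responsibilities).
    """
    alt = np.asarray(alt, float)
    depth = np.asarray(depth, float)
    n = alt.size
    theta = np.clip(np.asarray(theta0, float), 1e-6, 1 - 1e-6)
    w = np.asarray(weights0, float)
    w = w / w.sum()
    log_binom = gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)
    ll_prev = -np.inf
    resp = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        # E step: log p(x_i | c) + log w_c
        logp = (
            log_binom[:, None]
            + alt[:, None] * np.log(theta)[None, :]
            + (depth - alt)[:, None] * np.log1p(-theta)[None, :]
            + np.log(np.maximum(w, 1e-300))[None, :]
        )
        m = logp.max(axis=1, keepdims=True)
        norm = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        resp = np.exp(logp - norm[:, None])
        ll = float(norm.sum())
        # M step
        nk = resp.sum(axis=0)
        w = nk / n
        num = resp.T @ alt
        den = resp.T @ depth
        theta = np.where(den > 0, num / np.maximum(den, 1e-300), theta)
        theta = np.clip(theta, 1e-6, 1 - 1e-6)
        if abs(ll - ll_prev) < tol:
            break
        ll_prev = ll
    return ll, theta, w, resp


def builtin_cluster(
    loci: pd.DataFrame,
    k_max: int = 6,
    seed: int = 0,
) -> list[CloneCluster]:
    """Cluster loci into subclones with a BIC-selected binomial-mixture EM.

    A stand-in for an external Bayesian clonal-inference tool: mixtures with
    k = 1..k_max components and binomial read-count emissions are fitted to
    (alt_count, depth) by EM from a fixed multi-start schedule, the k with
    the lowest BIC is selected (ties to the smaller k), and each locus is
    assigned to its maximum-responsibility component. Deterministic given
    ``seed``. Requires ``ref_count``/``alt_count`` columns.
    """
    if len(loci) == 0:
        raise ValidationError("builtin_cluster requires at least one locus")
    if "alt_count" not in loci.columns or "ref_count" not in loci.columns:
        raise ValidationError(
            "builtin_cluster requires ref_count and alt_count columns"
        )
    observations = _loci_to_observations(loci)
    alt = loci["alt_count"].to_numpy(float)
    depth = alt + loci["ref_count"].to_numpy(float)
    if np.any(depth <= 0):
        raise ValidationError("builtin_cluster requires positive read depths")
    n = alt.size
    vaf = alt / depth
    if n == 1:
        return [CloneCluster(label="0", members=observations)]

    rng = np.random.default_rng(seed)
    best = None  # (bic, k, assignment)
    for k in range(1, min(k_max, n) + 1):
        starts = [np.quantile(vaf, (np.arange(k) + 0.5) / k)]
        for _ in range(3):
            starts.append(np.sort(rng.uniform(vaf.min(), max(vaf.max(), 1e-3), k)))
        best_ll, best_fit = -np.inf, None
        for theta0 in starts:
            ll, theta, w, resp = _em_binomial_mixture(
                alt, depth, k, theta0, np.full(k, 1.0 / k)
            )
            if ll > best_ll:
                best_ll, best_fit = ll, (theta, w, resp)
        n_params = 2 * k - 1  # k thetas + k-1 free weights
        bic = -2.0 * best_ll + n_params * math.log(n)
        assignment = best_fit[2].argmax(axis=1)
        logger.debug("builtin_cluster k=%d: ll=%.3f bic=%.3f", k, best_ll, bic)
        if best is None or bic < best[0] - 1e-9:
            best = (bic, k, assignment)
    _, k_sel, assignment = best
    logger.info("builtin_cluster selected k=%d for %d loci", k_sel, n)

    clusters = []
    for label in range(k_sel):
        members = [observations[i] for i in np.flatnonzero(assignment == label)]
        if members:  # components may end empty after hard assignment
            clusters.append(CloneCluster(label=str(label), members=members))
    return clusters


def _loci_to_observations(loci: pd.DataFrame) -> list[LocusObservation]:
    has_counts = "ref_count" in loci.columns and "alt_count" in loci.columns
    obs = []
    for row in loci.itertuples(index=False):
        obs.append(
            LocusObservation(
                mutation_id=str(row.mutation_id),
                cellular_prevalence=float(row.cellular_prevalence),
                vaf=float(row.vaf),
                ref_count=int(row.ref_count) if has_counts else None,
                alt_count=int(row.alt_count) if has_counts else None,
            )
        )
    return obs


def clusters_from_loci(loci: pd.DataFrame) -> list[CloneCluster]:
    """Build clusters from an ingested ``cluster_id`` column."""
    observations = _loci_to_observations(loci)
    cluster_ids = loci["cluster_id"].to_numpy()
    clusters = []
    for label in pd.unique(cluster_ids):
        members = [observations[i] for i in np.flatnonzero(cluster_ids == label)]
        clusters.append(CloneCluster(label=str(label), members=members))
    return clusters


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def _merged_label(clusters: Sequence[CloneCluster]) -> str:
    return "|".join(sorted(c.label for c in clusters))


def _centroid(cluster: CloneCluster, features: str) -> np.ndarray:
    if features == "cp":
        return np.array([cluster.mean_cp])
    return np.array([cluster.mean_cp, cluster.mean_vaf])


def merge_stage1(
    clusters: Sequence[CloneCluster],
    cutoff: float = 0.05,
    features: str = "cp_vaf",
    scope: str = "all",
    merge_log: list[MergeEvent] | None = None,
) -> list[CloneCluster]:
    """Average-linkage centroid merging at a fixed dendrogram cut height.

    Cluster centroids in (mean CP, mean VAF) space (or CP only, with
    ``features='cp'``) are agglomerated by average linkage; groups within
    cophenetic distance ``cutoff`` are merged. With
    ``scope='singletons_only'`` only single-mutation clusters are absorbed:
    each singleton joins the nearest co-grouped non-singleton (or pools with
    co-grouped singletons), while non-singleton clusters stay separate.
    """
    clusters = list(clusters)
    if len(clusters) < 2:
        return clusters
    cent = np.vstack([_centroid(c, features) for c in clusters])
    Z = linkage(cent, method="average")
    groups = fcluster(Z, t=cutoff, criterion="distance")

    merged: list[CloneCluster] = []
    for g in np.unique(groups):
        group = [clusters[i] for i in np.flatnonzero(groups == g)]
        if len(group) == 1:
            merged.append(group[0])
            continue
        if scope == "all":
            merged.append(_merge_group(group, features, merge_log))
        else:
            merged.extend(_merge_singletons_only(group, features, merge_log))
    logger.info("stage 1: %d -> %d clusters", len(clusters), len(merged))
    return merged


def _merge_group(group, features, merge_log):
    members = [m for c in group for m in c.members]
    new = CloneCluster(label=_merged_label(group), members=members)
    if merge_log is not None:
        cents = np.vstack([_centroid(c, features) for c in group])
        dmax = max(
            float(np.linalg.norm(a - b))
            for a, b in itertools.combinations(cents, 2)
        )
        merge_log.append(
            MergeEvent(
                stage=1,
                merged_labels=tuple(c.label for c in group),
                distance=dmax,
            )
        )
    return new


def _merge_singletons_only(group, features, merge_log):
    non_singletons = [c for c in group if not c.is_singleton]
    singletons = [c for c in group if c.is_singleton]
    if not non_singletons:
        return [_merge_group(group, features, merge_log)] if len(group) > 1 else group
    pools: dict[int, list[CloneCluster]] = {i: [c] for i, c in enumerate(non_singletons)}
    for s in singletons:
        dists = [
            float(np.linalg.norm(_centroid(s, features) - _centroid(c, features)))
            for c in non_singletons
        ]
        pools[int(np.argmin(dists))].append(s)
    out = []
    for pool in pools.values():
        out.append(pool[0] if len(pool) == 1 else _merge_group(pool, features, merge_log))
    return out


def merge_stage2(
    clusters: Sequence[CloneCluster],
    alpha: float = 0.05,
    merge_log: list[MergeEvent] | None = None,
) -> list[CloneCluster]:
    """Rank-sum refinement: merge statistically indistinguishable clusters.

    Iteratively, every unordered cluster pair is tested with a two-sided
    rank-sum test on member CPs and member VAFs; a pair is mergeable iff
    both p-values exceed ``alpha`` (strict). The mergeable pair with the
    largest min(p_cp, p_vaf) is merged first (ties: larger p-sum, then
    smaller centroid distance, then lexicographic labels), means are
    recomputed, and the scan repeats until no pair is mergeable.
    """
    clusters = list(clusters)
    while len(clusters) > 1:
        best_key, best_pair, best_ps = None, None, None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            ci, cj = clusters[i], clusters[j]
            p_cp = rank_sum_test(ci.cp_values, cj.cp_values).p_value
            p_vaf = rank_sum_test(ci.vaf_values, cj.vaf_values).p_value
            if p_cp > alpha and p_vaf > alpha:
                d = float(
                    np.hypot(ci.mean_cp - cj.mean_cp, ci.mean_vaf - cj.mean_vaf)
                )
                labels = tuple(sorted((ci.label, cj.label)))
                # maximize min(p), then sum(p), then -distance, then labels
                key = (min(p_cp, p_vaf), p_cp + p_vaf, -d, _neg_labels(labels))
                if best_key is None or key > best_key:
                    best_key, best_pair, best_ps = key, (i, j), (p_cp, p_vaf)
        if best_pair is None:
            break
        i, j = best_pair
        ci, cj = clusters[i], clusters[j]
        new = CloneCluster(
            label=_merged_label([ci, cj]), members=ci.members + cj.members
        )
        if merge_log is not None:
            merge_log.append(
                MergeEvent(
                    stage=2,
                    merged_labels=(ci.label, cj.label),
                    p_cp=best_ps[0],
                    p_vaf=best_ps[1],
                )
            )
        logger.debug(
            "stage 2 merge %s + %s (p_cp=%.4f, p_vaf=%.4f)",
            ci.label,
            cj.label,
            best_ps[0],
            best_ps[1],
        )
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        clusters.append(new)
    return clusters


class _neg_labels:
    """Orders label tuples so that lexicographically smaller compares greater."""

    def __init__(self, labels):
        self.labels = labels

    def __lt__(self, other):
        return self.labels > other.labels

    def __gt__(self, other):
        return self.labels < other.labels

    def __eq__(self, other):
        return self.labels == other.labels


# ---------------------------------------------------------------------------
# Shannon index
# ---------------------------------------------------------------------------

def shannon_ith(
    clusters: Sequence[CloneCluster],
    sample_id: str = "",
    provenance: str = "ingested",
    merge_log: list[MergeEvent] | None = None,
) -> ClonalStructure:
    """Shannon diversity of the subclonal composition.

    Mean CPs are normalized to proportions p_i and
    H' = -sum p_i ln p_i (nats). Clusters with zero mean CP are dropped with
    a warning before normalization; a single remaining cluster scores
    exactly 0.
    """
    clusters = list(clusters)
    if not clusters:
        raise ValidationError("shannon_ith requires at least one cluster")
    kept = [c for c in clusters if c.mean_cp > 0]
    if len(kept) < len(clusters):
        logger.warning(
            "%s: dropped %d zero-CP cluster(s) before Shannon normalization",
            sample_id,
            len(clusters) - len(kept),
        )
    if not kept:
        raise ValidationError(
            f"{sample_id}: all clusters have zero mean CP; ITH undefined"
        )
    mean_cps = np.array([c.mean_cp for c in kept], dtype=float)
    proportions = mean_cps / mean_cps.sum()
    if len(kept) == 1:
        score = 0.0
    else:
        score = float(-(proportions * np.log(proportions)).sum())
    return ClonalStructure(
        sample_id=sample_id,
        clusters=kept,
        proportions=proportions,
        ith_score=score,
        provenance=provenance,
        merge_log=list(merge_log) if merge_log is not None else [],
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def run_ith_pipeline(
    loci: pd.DataFrame,
    purity: float | None,
    sample_id: str | None = None,
    cutoff: float = 0.05,
    alpha: float = 0.05,
    k_max: int = 6,
    seed: int = 0,
    stage1_scope: str = "all",
    stage1_features: str = "cp_vaf",
    tumor_copy_number: int = 2,
    use_ingested_clusters: bool = True,
) -> ClonalStructure:
    """Full per-sample ITH pipeline: cluster, merge twice, score.

    Uses the ingested ``cluster_id`` column when present (provenance
    "ingested") unless ``use_ingested_clusters=False``, in which case the
    built-in binomial-mixture clustering is run. A missing purity raises
    :class:`MissingPurityError` — such samples are excluded from ITH, as
    purity is required to interpret CP.
    """
    if purity is None or (isinstance(purity, float) and math.isnan(purity)):
        raise MissingPurityError(
            f"sample {sample_id or '?'}: no tumor purity; excluded from ITH"
        )
    if not 0 < purity <= 1:
        raise ValidationError(f"purity must be in (0, 1], got {purity}")
    if len(loci) == 0:
        raise ValidationError("run_ith_pipeline requires a non-empty loci table")
    loci = loci.copy()
    if sample_id is None:
        sample_id = (
            str(loci["sample_id"].iloc[0]) if "sample_id" in loci.columns else ""
        )
    if "cellular_prevalence" not in loci.columns:
        loci["cellular_prevalence"] = [
            vaf_to_cp(v, purity, tumor_copy_number) for v in loci["vaf"]
        ]

    merge_log: list[MergeEvent] = []
    if use_ingested_clusters and "cluster_id" in loci.columns:
        clusters = clusters_from_loci(loci)
        provenance = "ingested"
    else:
        clusters = builtin_cluster(loci, k_max=k_max, seed=seed)
        provenance = "builtin_clustering"
    n_initial = len(clusters)
    clusters = merge_stage1(
        clusters,
        cutoff=cutoff,
        features=stage1_features,
        scope=stage1_scope,
        merge_log=merge_log,
    )
    n_stage1 = len(clusters)
    clusters = merge_stage2(clusters, alpha=alpha, merge_log=merge_log)
    n_stage2 = len(clusters)
    structure = shannon_ith(
        clusters, sample_id=sample_id, provenance=provenance, merge_log=merge_log
    )
    structure.n_clusters_initial = n_initial
    structure.n_after_stage1 = n_stage1
    structure.n_after_stage2 = n_stage2
    logger.info(
        "%s: clusters %d -> %d -> %d, ITH %.4f (%s)",
        sample_id,
        n_initial,
        n_stage1,
        n_stage2,
        structure.ith_score,
        provenance,
    )
    return structure
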