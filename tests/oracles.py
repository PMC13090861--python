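"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package paths they check: the
rank-sum oracle enumerates every subset assignment with itertools, and the
CNV oracle scans base pairs one by one.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def exact_ranksum_p(x, y) -> float:
    """Two-sided rank-sum p-value by full enumeration of C(n+m, n) subsets.

    Midranks for ties; p = min(1, 2 * min(lower tail, upper tail)) with the
    observed point included in both tails.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:n1].sum()
    sums = np.array(
        [ranks[list(c)].sum() for c in itertools.combinations(range(len(pooled)), n1)]
    )
    tol = 1e-9
    p_le = np.mean(sums <= w_obs + tol)
    p_ge = np.mean(sums >= w_obs - tol)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def brute_force_altered_bp(segments, neutral_copy_number=2) -> int:
    """Altered base pairs by marking each genomic position individually."""
    if not segments:
        return 0
    altered = 0
    by_chrom: dict[str, set[int]] = {}
    for seg in segments:
        if seg.is_altered or seg.total_copy_number != neutral_copy_number:
            marked = by_chrom.setdefault(seg.chrom, set())
            for pos in range(seg.start, seg.end + 1):
                marked.add(pos)
    for marked in by_chrom.values():
        altered += len(marked)
    return altered


def brute_force_gene_overlap(gene, segments, direction, amp_threshold=3,
                             del_threshold=1) -> float:
    """Fraction of a gene's base pairs covered by amp- or del-direction
    segments, scanning position by position."""
    covered = 0
    for pos in range(gene.start, gene.end + 1):
        for seg in segments:
            if seg.chrom != gene.chrom or not (seg.start <= pos <= seg.end):
                continue
            if direction == "amp" and seg.total_copy_number >= amp_threshold:
                covered += 1
                break
            if direction == "del" and seg.total_copy_number <= del_threshold:
                covered += 1
                break
    return covered / (gene.end - gene.start + 1)
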