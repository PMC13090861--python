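"""Group-wise comparison of sample-level metrics (ITH, TMB, CNV burden).

Two-sided rank-sum tests with exact enumeration for small groups and a
tie/continuity-corrected normal approximation for large ones, plus median
summaries. Raw p-values are reported by default; Benjamini-Hochberg
adjustment is available behind a flag.
"""
from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .ranksum import rank_sum_test
from .records import GroupComparison

logger = logging.getLogger(__name__)


def _group_values(
    table: pd.DataFrame, metric: str, group_field: str, label: str
) -> tuple[np.ndarray, int]:
    if metric not in table.columns:
        raise ValidationError(f"unknown metric column {metric!r}")
    if group_field not in table.columns:
        raise ValidationError(f"unknown group field {group_field!r}")
    rows = table.loc[table[group_field] == label, metric]
    values = pd.to_numeric(rows, errors="coerce")
    n_excluded = int(values.isna().sum())
    usable = values.dropna().to_numpy(dtype=float)
    if usable.size == 0:
        raise ValidationError(f"group {label!r} has no usable {metric!r} values")
    return usable, n_excluded


def compare_groups(
    table: pd.DataFrame,
    metric: str,
    group_field: str,
    pair: tuple[str, str],
) -> GroupComparison:
    """Two-sided rank-sum comparison of one metric between two groups.

    Samples with missing metric values are excluded and counted in
    ``n_excluded``; medians are computed on the included samples.
    """
    label_a, label_b = pair
    a, excl_a = _group_values(table, metric, group_field, label_a)
    b, excl_b = _group_values(table, metric, group_field, label_b)
    result = rank_sum_test(a, b)
    logger.info(
        "%s %s vs %s: median %.4g vs %.4g, p=%.4g (%s)",
        metric, label_a, label_b,
        float(np.median(a)), float(np.median(b)),
        result.p_value, result.method,
    )
    return GroupComparison(
        metric=metric,
        group_a=label_a,
        group_b=label_b,
        n_a=a.size,
        n_b=b.size,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        p_value=result.p_value,
        method=result.method,
        n_excluded=excl_a + excl_b,
    )


def summarize_medians(
    table: pd.DataFrame, metric: str, group_field: str
) -> pd.DataFrame:
    """Per-group n/median/min/max summary (even-n medians are midpoints)."""
    if len(table) == 0:
        raise ValidationError("summarize_medians requires a non-empty table")
    if metric not in table.columns or group_field not in table.columns:
        raise ValidationError(
            f"unknown metric {metric!r} or group field {group_field!r}"
        )
    rows = []
    for label in pd.unique(table[group_field]):
        values = pd.to_numeric(
            table.loc[table[group_field] == label, metric], errors="coerce"
        ).dropna()
        if values.empty:
            continue
        rows.append(
            {
                "group": label,
                "n": int(values.size),
                "median": float(values.median()),
                "min": float(values.min()),
                "max": float(values.max()),
            }
        )
    return pd.DataFrame(rows, columns=["group", "n", "median", "min", "max"])


def compare_pairs(
    table: pd.DataFrame,
    metric: str,
    group_field: str,
    pairs: Sequence[tuple[str, str]],
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Run several pairwise comparisons; optional Benjamini-Hochberg column."""
    comparisons = [compare_groups(table, metric, group_field, p) for p in pairs]
    out = pd.DataFrame(
        [
            {
                "metric": c.metric,
                "group_a": c.group_a,
                "group_b": c.group_b,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "median_a": c.median_a,
                "median_b": c.median_b,
                "p_value": c.p_value,
                "method": c.method,
            }
            for c in comparisons
        ]
    )
    if bh_adjust and len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
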