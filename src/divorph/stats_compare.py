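"""Downstream statistics for divergence calls.

Enrichment of divergent calls in a gene subset (2x2 chi-squared with
Yates continuity correction by default), property comparisons between
predicted classes (two-sided rank-sum test, Cohen's d), and a
length-controlled enrichment re-test. Property values (disorder, dN/dS,
GC content, ...) are externally supplied annotations; nothing is
computed from sequence here. All tests are pure functions of their
numeric inputs.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "chi_squared",
    "wilcoxon_rank_sum",
    "cohens_d",
    "enrichment_table",
    "length_controlled_enrichment",
]


def chi_squared(
    table: Sequence[Sequence[int]] | np.ndarray,
    continuity_correction: bool = True,
) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table; Yates correction on by default
    (the uncorrected statistic is always >= the corrected one).

    Returns (statistic, p-value).
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (arr < 0).any():
        raise ValueError("cell counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero margin")
    res = stats.chi2_contingency(arr, correction=continuity_correction)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test.

    Exact enumeration for small tie-free samples (both n <= 50), normal
    approximation with tie correction otherwise. Fully tied degenerate
    input returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(combined)) < len(combined)
    small = max(len(x), len(y)) <= 50
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Standardized mean difference with (n-1)-weighted pooled sd."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least 2 values")
    nx, ny = len(x), len(y)
    pooled_var = (
        (nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)
    ) / (nx + ny - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def enrichment_table(
    calls: pd.DataFrame, subset_ids: Iterable[str]
) -> np.ndarray:
    """2x2 counts (subset, rest) x (divergent, non-divergent).

    ``calls`` needs columns ``query_id`` and boolean ``divergent``.
    """
    subset = set(subset_ids)
    in_subset = calls["query_id"].isin(subset)
    div = calls["divergent"].astype(bool)
    return np.array([
        [int((in_subset & div).sum()), int((in_subset & ~div).sum())],
        [int((~in_subset & div).sum()), int((~in_subset & ~div).sum())],
    ])


def length_controlled_enrichment(
    annotated: pd.DataFrame,
    subset_ids: Iterable[str],
    continuity_correction: bool = True,
) -> tuple[np.ndarray, float, float]:
    """Enrichment re-test controlling for length.

    The length threshold is the mean length of the subset; BOTH groups
    are restricted to proteins no longer than the threshold before the
    chi-squared is recomputed. ``annotated`` needs columns ``query_id``,
    ``divergent`` and ``length``.

    Returns (filtered 2x2 table, statistic, p-value).
    """
    subset = set(subset_ids)
    if annotated["length"].isna().any():
        raise ValueError("lengths required for every protein")
    in_subset = annotated["query_id"].isin(subset)
    if not in_subset.any():
        raise ValueError("subset is empty")
    threshold = float(annotated.loc[in_subset, "length"].mean())
    kept = annotated[annotated["length"] <= threshold]
    if not kept["query_id"].isin(subset).any():
        raise ValueError("subset empty after length filtering")
    if kept["query_id"].isin(subset).all():
        raise ValueError("rest group empty after length filtering")
    table = enrichment_table(kept, subset)
    stat, p = chi_squared(table, continuity_correction)
    return table, stat, p
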