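"""The 11 statistical features computed from a query's band hits.

All statistics are taken over the hits with E-value inside the
significance band. Length-dependent quantities are normalized by query
length (alignment count, bit scores, coverages); average alignment
length deliberately is not. ``total_query_coverage`` is the fraction of
query residues covered by the union of hit intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import SimilarityHit
from .orphan_pipeline import OrphanCall, OrphanStatus

__all__ = [
    "FEATURE_NAMES",
    "extract_features",
    "feature_table",
    "ScalerParams",
    "fit_scaler",
    "apply_scaler",
    "inverse_scaler",
]

FEATURE_NAMES = (
    "alignment_count",
    "avg_pident",
    "avg_evalue",
    "avg_bitscore",
    "avg_coverage",
    "min_evalue",
    "max_pident",
    "avg_align_len",
    "max_bitscore",
    "max_align_len",
    "total_query_coverage",
)

#: Columns that are metadata rather than model inputs.
NON_FEATURE_COLUMNS = ("CLASS", "SUBSET", "query_id")


def extract_features(
    query_length: int, band_hits: Sequence[SimilarityHit]
) -> dict[str, float]:
    """Compute the 11 features for one eligible query.

    Raises if ``band_hits`` is empty - eligibility must already hold.
    Permutation-invariant in hit order.
    """
    if query_length < 1:
        raise ValueError("query_length must be >= 1")
    if not band_hits:
        raise ValueError("eligible query must have at least one band hit")
    L = float(query_length)
    pid = np.array([h.pident for h in band_hits])
    ev = np.array([h.evalue for h in band_hits])
    bits = np.array([h.bitscore for h in band_hits])
    alen = np.array([h.align_len for h in band_hits], dtype=float)

    covered = np.zeros(query_length, dtype=bool)
    for h in band_hits:
        covered[h.qstart - 1:h.qend] = True

    return {
        "alignment_count": len(band_hits) / L,
        "avg_pident": float(pid.mean()),
        "avg_evalue": float(ev.mean()),
        "avg_bitscore": float(bits.mean()) / L,
        "avg_coverage": float((alen / L).mean()),
        "min_evalue": float(ev.min()),
        "max_pident": float(pid.max()),
        "avg_align_len": float(alen.mean()),
        "max_bitscore": float(bits.max()) / L,
        "max_align_len": float(alen.max()) / L,
        "total_query_coverage": float(covered.sum()) / L,
    }


def feature_table(calls: Iterable[OrphanCall]) -> pd.DataFrame:
    """Feature rows for every eligible call (others are skipped).

    Requires ``query_length`` on each eligible call.
    """
    rows = []
    for call in calls:
        if call.status is not OrphanStatus.ELIGIBLE_ORPHAN:
            continue
        if call.query_length is None:
            raise ValueError(
                f"query {call.query_id!r}: query_length required for features"
            )
        row = {"query_id": call.query_id}
        row.update(extract_features(call.query_length, call.band_hits))
        rows.append(row)
    return pd.DataFrame(rows, columns=["query_id", *FEATURE_NAMES])


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature mean/sd fitted on a reference table (population sd,
    matching the usual ML-library standardization)."""

    mean: pd.Series
    std: pd.Series
    dropped: tuple[str, ...] = ()


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in NON_FEATURE_COLUMNS]


def fit_scaler(table: pd.DataFrame) -> ScalerParams:
    """Fit z-score parameters; constant columns are dropped with a warning."""
    if len(table) < 2:
        raise ValueError("need at least 2 rows to fit a scaler")
    cols = _feature_columns(table)
    mean = table[cols].mean()
    std = table[cols].std(ddof=0)
    dropped = tuple(std.index[std == 0.0])
    if dropped:
        warnings.warn(
            f"dropping constant feature columns: {', '.join(dropped)}",
            stacklevel=2,
        )
        keep = [c for c in cols if c not in dropped]
        mean, std = mean[keep], std[keep]
    return ScalerParams(mean=mean, std=std, dropped=dropped)


def apply_scaler(table: pd.DataFrame, params: ScalerParams) -> pd.DataFrame:
    """Z-score the feature columns; CLASS and other metadata untouched."""
    out = table.drop(columns=list(params.dropped), errors="ignore").copy()
    cols = list(params.mean.index)
    out[cols] = (out[cols] - params.mean) / params.std
    return out


def inverse_scaler(table: pd.DataFrame, params: ScalerParams) -> pd.DataFrame:
    out = table.copy()
    cols = list(params.mean.index)
    out[cols] = out[cols] * params.std + params.mean
    return out
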