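"""Positive/negative rating-deviation statistics and descriptive summaries.

A review's deviation is the gap between its star rating and the app's
overall rating.  The positive part (PD) measures how far the review exceeds
the aggregate — satisfaction beyond expectation — and the negative part
(ND, absolute-valued) how far it falls short.  The two are mutually
exclusive (pd * nd = 0) and each lies in [0, 4], the span of a 1–5 star
scale.  Satisfaction rates and topic-share tables reproduce the usual
descriptive arithmetic on review tables.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "app_overall_rating",
    "compute_pd_nd",
    "deviation_table",
    "satisfaction_rate",
    "topic_share_table",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching how report tables are printed."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def app_overall_rating(table: pd.DataFrame) -> pd.Series:
    """Unrounded mean star rating per app (proxy for the store-displayed
    aggregate; pass a pre-computed column instead to use the true store
    value)."""
    if len(table) == 0:
        raise DataError("empty review table")
    counts = table.groupby("app_id")["rating"].count()
    if (counts == 0).any():
        bad = counts[counts == 0].index[0]
        raise DataError(f"app {bad!r} has zero reviews")
    return table.groupby("app_id")["rating"].mean()


def compute_pd_nd(rating, overall):
    """Split rating - overall into its clamped positive and negative parts.

    Scalar or vectorized.  Returns (pd, nd) with pd = clamp(d, 0, 4),
    nd = clamp(-d, 0, 4); exactly one of the pair is nonzero unless d = 0.
    """
    rating_arr = np.asarray(rating, dtype=float)
    overall_arr = np.asarray(overall, dtype=float)
    if ((rating_arr < 1) | (rating_arr > 5)).any():
        raise DataError("rating outside [1, 5]")
    if ((overall_arr < 1) | (overall_arr > 5)).any():
        raise DataError("overall rating outside [1, 5]")
    d = rating_arr - overall_arr
    pd_val = np.clip(d, 0.0, 4.0)
    nd_val = np.clip(-d, 0.0, 4.0)
    if np.isscalar(rating) and np.isscalar(overall):
        return float(pd_val), float(nd_val)
    return pd_val, nd_val


def deviation_table(
    table: pd.DataFrame, overall: pd.Series | None = None
) -> pd.DataFrame:
    """Per-review deviation pairs joined with the app's overall rating.

    ``overall`` may supply the true store aggregates (indexed by app_id);
    otherwise the per-app mean of the observed ratings is used.
    """
    if overall is None:
        overall = app_overall_rating(table)
    ov = table["app_id"].map(overall)
    if ov.isna().any():
        bad = table.loc[ov.isna(), "app_id"].iloc[0]
        raise DataError(f"no overall rating for app {bad!r}")
    pd_v, nd_v = compute_pd_nd(table["rating"].to_numpy(), ov.to_numpy())
    return pd.DataFrame(
        {
            "review_id": table["review_id"].to_numpy(),
            "app_id": table["app_id"].to_numpy(),
            "overall_rating": ov.to_numpy(),
            "pd": pd_v,
            "nd": nd_v,
        }
    )


def satisfaction_rate(table: pd.DataFrame, threshold: int = 4) -> float:
    """Percentage of reviews rated at or above the threshold, to 2 decimals."""
    if len(table) == 0:
        raise DataError("empty review table")
    n_sat = int((table["rating"] >= threshold).sum())
    return round_half_up(100.0 * n_sat / len(table))


def topic_share_table(
    assignments: Sequence[int] | np.ndarray,
    topic_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Review counts and percentage shares per assigned topic.

    Topics are listed by descending count; percentages are rounded to
    2 decimals and sum to 100 up to rounding error.
    """
    assignments = np.asarray(assignments)
    n = assignments.shape[0]
    topics, counts = np.unique(assignments, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    rows = []
    for i in order:
        t = int(topics[i])
        label = topic_labels[t] if topic_labels is not None else f"topic_{t}"
        rows.append(
            {
                "topic": t,
                "label": label,
                "count": int(counts[i]),
                "percentage": round_half_up(100.0 * counts[i] / n),
            }
        )
    return pd.DataFrame(rows)
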