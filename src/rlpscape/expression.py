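"""Wounded vs. non-wounded expression comparison.

Treatment intensities are averaged over the paired conditions of each
treatment (equal weights).  A gene is "expressed" when either treatment mean
clears the background threshold; the expression category is a step function
of the larger treatment mean (<=4000 low/medium, 4000-10000 higher, >10000
very high).  Fold change is the ratio of pseudocount-stabilized treatment
means; induction is binned as none (<1.5), slight (1.5-5), or strong (>=5) —
bands chosen so that "slightly (<2-fold)" and "strongly (~10-fold)" induced
genes are labelled as such.  No between-array normalization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clusters import AssociationTable, Cluster

CATEGORY_BELOW = "below_background"
CATEGORY_LOW = "low_medium"
CATEGORY_HIGHER = "higher"
CATEGORY_VERY_HIGH = "very_high"


@dataclass
class ExpressionThresholds:
    background: float = 200.0
    low_max: float = 4000.0
    high_max: float = 10000.0
    pseudocount: float = 1.0
    slight_min: float = 1.5
    strong_min: float = 5.0


def categorize(mean_level: float, thresholds: ExpressionThresholds) -> str:
    if mean_level <= thresholds.low_max:
        return CATEGORY_LOW
    if mean_level <= thresholds.high_max:
        return CATEGORY_HIGHER
    return CATEGORY_VERY_HIGH


def summarize_expression(
    matrix_nonwounded: pd.DataFrame,
    matrix_wounded: pd.DataFrame,
    background: float = 200.0,
    pseudocount: float = 1.0,
    slight_min: float = 1.5,
    strong_min: float = 5.0,
    low_max: float = 4000.0,
    high_max: float = 10000.0,
) -> pd.DataFrame:
    """Per-gene treatment means, category, fold change, and induction call.

    Both matrices must cover the same genes with the same number of condition
    columns.  Returns a DataFrame indexed by gene id with columns
    ``mean_nonwounded``, ``mean_wounded``, ``expressed``, ``category``,
    ``fold_change``, ``induction``.
    """
    if matrix_nonwounded.shape[1] != matrix_wounded.shape[1]:
        raise ValueError(
            f"condition-count mismatch: {matrix_nonwounded.shape[1]} vs "
            f"{matrix_wounded.shape[1]} columns"
        )
    if set(matrix_nonwounded.index) != set(matrix_wounded.index):
        raise ValueError("the two matrices cover different gene sets")
    w = matrix_wounded.loc[matrix_nonwounded.index]
    th = ExpressionThresholds(
        background=background, pseudocount=pseudocount,
        slight_min=slight_min, strong_min=strong_min,
        low_max=low_max, high_max=high_max,
    )
    mean_nw = matrix_nonwounded.mean(axis=1)
    mean_w = w.mean(axis=1)
    expressed = (mean_nw > background) | (mean_w > background)
    fc = (mean_w + pseudocount) / (mean_nw + pseudocount)
    level = np.maximum(mean_nw, mean_w)
    category = [
        categorize(lv, th) if ex else CATEGORY_BELOW
        for lv, ex in zip(level, expressed)
    ]
    induction = np.where(fc >= strong_min, "strong",
                         np.where(fc >= slight_min, "slight", "none"))
    return pd.DataFrame(
        {
            "mean_nonwounded": mean_nw,
            "mean_wounded": mean_w,
            "expressed": expressed,
            "category": category,
            "fold_change": fc,
            "induction": induction,
        }
    )


def regression_wounded_vs_nonwounded(
    results: pd.DataFrame,
) -> tuple[float, float, float]:
    """OLS of the wounded mean on the non-wounded mean: (slope, intercept, r2)."""
    x = results["mean_nonwounded"].to_numpy(dtype=float)
    y = results["mean_wounded"].to_numpy(dtype=float)
    if len(x) < 2 or np.ptp(x) == 0:
        raise ValueError("need at least 2 genes with varying non-wounded means")
    if np.ptp(y) == 0:
        return (0.0, float(y[0]), 0.0)
    fit = stats.linregress(x, y)
    return (float(fit.slope), float(fit.intercept), float(fit.rvalue**2))


def coexpressed_pairs(
    clusters: list[Cluster],
    association: AssociationTable,
    results: pd.DataFrame,
    spuf_ids: set[str],
    matrix_nonwounded: pd.DataFrame | None = None,
    matrix_wounded: pd.DataFrame | None = None,
    background: float = 200.0,
) -> pd.DataFrame:
    """Receptor/SPUF pairs within clusters that are both expressed.

    For each cluster, every pair of a member receptor with an associated SPUF
    where both treatment-level means clear the background is emitted.  When
    the condition matrices are supplied and at least 4 paired conditions
    exist, the Pearson correlation of the two genes' intensities across all
    paired conditions (both treatments concatenated) is included.
    """
    rows = []
    have_profiles = (
        matrix_nonwounded is not None
        and matrix_wounded is not None
        and matrix_nonwounded.shape[1] + matrix_wounded.shape[1] >= 4
    )

    def profile(gid: str) -> np.ndarray:
        return np.concatenate(
            [matrix_nonwounded.loc[gid].to_numpy(), matrix_wounded.loc[gid].to_numpy()]
        )

    def above(gid: str) -> bool:
        if gid not in results.index:
            return False
        row = results.loc[gid]
        return max(row["mean_nonwounded"], row["mean_wounded"]) > background

    for cluster in clusters:
        spufs_in_cluster: dict[str, list[str]] = {}
        for rid in cluster.members:
            spufs_in_cluster[rid] = sorted(
                gid for gid, _ in association.per_receptor.get(rid, [])
                if gid in spuf_ids
            )
        for rid in cluster.members:
            if not above(rid):
                continue
            for sid in spufs_in_cluster[rid]:
                if not above(sid):
                    continue
                corr = np.nan
                if have_profiles:
                    pr, ps = profile(rid), profile(sid)
                    if np.ptp(pr) > 0 and np.ptp(ps) > 0:
                        corr = float(stats.pearsonr(pr, ps).statistic)
                rows.append(
                    {
                        "cluster_id": cluster.cluster_id,
                        "receptor": rid,
                        "spuf": sid,
                        "mean_receptor": float(
                            max(results.loc[rid, ["mean_nonwounded", "mean_wounded"]])
                        ),
                        "mean_spuf": float(
                            max(results.loc[sid, ["mean_nonwounded", "mean_wounded"]])
                        ),
                        "correlation": corr,
                    }
                )
    return pd.DataFrame(
        rows, columns=["cluster_id", "receptor", "spuf",
                       "mean_receptor", "mean_spuf", "correlation"]
    )


__all__ = [
    "CATEGORY_BELOW",
    "CATEGORY_LOW",
    "CATEGORY_HIGHER",
    "CATEGORY_VERY_HIGH",
    "ExpressionThresholds",
    "categorize",
    "summarize_expression",
    "regression_wounded_vs_nonwounded",
    "coexpressed_pairs",
]
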