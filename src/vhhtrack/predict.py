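"""Hit-cluster prediction from bit-score trajectories.

For each cluster, every member sequence contributes one trajectory point per
isotype: its week of first appearance against its V-region bit score.  An
unweighted ordinary-least-squares line through these points summarizes the
lineage: the slope measures the pace of somatic hypermutation (negative =
ongoing maturation) and the intercept at week 0 — the initial bit score —
measures how germline-like the hypothetical founder was.  A third, turnover
statistic captures whether newly appearing clones keep displacing the weekly
dominant clone.

A cluster is predicted to contain antigen-responsive VHHs when all three
criteria hold: (1) negative slope, (2) initial bit score above the threshold
(default 380 bits on the configured scoring scale), and (3) sequence
turnover — positive rank correlation between week and the dominant clone's
first-appearance week, with at least three distinct weekly dominants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .chronology import first_week, week_columns, weeks_of
from .clustering import Cluster

__all__ = [
    "trajectory",
    "fit_bitscore_line",
    "turnover_index",
    "percentage_appearance",
    "max_percentage_appearance",
    "predict_hits",
    "ClusterPrediction",
]


def isotype_weekly_totals(ct: pd.DataFrame) -> pd.DataFrame:
    """Total reads per (isotype, week) across the whole repertoire."""
    wcols = week_columns(ct)
    return ct.groupby("isotype")[wcols].sum()


def trajectory(cluster: Cluster, ct: pd.DataFrame, germ: pd.DataFrame) -> pd.DataFrame:
    """One point per member row: first week, bit score, weekly share.

    IgG2 and IgG3 observations of the same nucleotide sequence are separate
    points.  ``weekly_share`` columns give the row's fraction of that
    isotype's reads per week.
    """
    wcols = week_columns(ct)
    rows = ct.loc[ct["sequence_id"].isin(cluster.member_ids)].merge(
        germ[["sequence_id", "v_bitscore"]], on="sequence_id"
    )
    totals = isotype_weekly_totals(ct)
    points = []
    for _, r in rows.iterrows():
        shares = {}
        for c in wcols:
            tot = totals.loc[r["isotype"], c]
            shares[f"share_{c.split('_')[1]}"] = (
                float(r[c]) / tot if tot > 0 else 0.0
            )
        points.append(
            {
                "sequence_id": r["sequence_id"],
                "isotype": r["isotype"],
                "first_week": first_week(r, wcols),
                "v_bitscore": float(r["v_bitscore"]),
                **shares,
            }
        )
    return pd.DataFrame(points)


def fit_bitscore_line(points: pd.DataFrame) -> tuple[float, float]:
    """Unweighted OLS of bit score on first-appearance week.

    Returns ``(slope, intercept)``; the intercept is the fitted value at
    week 0 (the initial bit score).  With fewer than two distinct weeks the
    line is undefined and ``(nan, nan)`` is returned.
    """
    x = points["first_week"].to_numpy(dtype=float)
    y = points["v_bitscore"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        return float("nan"), float("nan")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def weighted_fit_bitscore_line(points: pd.DataFrame, ct: pd.DataFrame) -> tuple[float, float]:
    """Frequency-weighted variant of the regression (sensitivity analysis)."""
    wcols = week_columns(ct)
    freq = ct.set_index("sequence_id")[wcols].sum(axis=1)
    w = points["sequence_id"].map(freq).to_numpy(dtype=float)
    x = points["first_week"].to_numpy(dtype=float)
    y = points["v_bitscore"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        return float("nan"), float("nan")
    slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
    return float(slope), float(intercept)


def turnover_index(
    cluster: Cluster,
    ct: pd.DataFrame,
    min_weeks: int = 3,
    min_dominants: int = 3,
) -> tuple[float, int, bool]:
    """Spearman correlation between week and the weekly dominant's first week.

    For each week in which the cluster is present, the dominant member is the
    nucleotide sequence with the highest summed IgG2+IgG3 frequency (ties to
    the lexicographically smaller sequence).  Continuous turnover — newly
    appearing clones predominating week after week — yields a positive index
    with several distinct dominants.  Returns ``(index, n_distinct_dominants,
    pass)``; clusters present in fewer than ``min_weeks`` weeks fail.
    """
    wcols = week_columns(ct)
    rows = ct.loc[ct["sequence_id"].isin(cluster.member_ids)]
    by_seq = rows.groupby("sequence")[wcols].sum()
    seq_first = {
        s: first_week(r, wcols) for s, r in by_seq.iterrows()
    }
    weeks, dom_first, dominants = [], [], []
    for c in wcols:
        col = by_seq[c]
        if col.sum() == 0:
            continue
        top = col.max()
        dom = min(col.index[col == top])
        weeks.append(int(c.split("_")[1]))
        dom_first.append(seq_first[dom])
        dominants.append(dom)
    n_dom = len(set(dominants))
    if len(weeks) < min_weeks:
        return 0.0, n_dom, False
    if len(set(dom_first)) < 2 or len(set(weeks)) < 2:
        index = 0.0
    else:
        index = float(stats.spearmanr(weeks, dom_first).statistic)
        if np.isnan(index):
            index = 0.0
    return index, n_dom, bool(index > 0 and n_dom >= min_dominants)


def percentage_appearance(
    cluster: Cluster, ct: pd.DataFrame, week: int, mode: str = "sum"
) -> float:
    """Weekly cluster share, as the paper's sum of per-isotype percentages.

    ``mode="sum"`` (default) adds the cluster's percentage occupancy among
    IgG2 reads and among IgG3 reads (an isotype absent that week contributes
    0; ceiling 200%).  ``mode="pooled"`` divides the cluster's combined count
    by the combined total (ceiling 100%).
    """
    col = f"freq_{week}"
    rows = ct.loc[ct["sequence_id"].isin(cluster.member_ids)]
    totals = ct.groupby("isotype")[col].sum()
    if mode == "pooled":
        denom = totals.sum()
        return 100.0 * rows[col].sum() / denom if denom > 0 else 0.0
    if mode != "sum":
        raise ValueError("mode must be 'sum' or 'pooled'")
    pct = 0.0
    for iso, tot in totals.items():
        if tot > 0:
            pct += 100.0 * rows.loc[rows["isotype"] == iso, col].sum() / tot
    return float(pct)


def max_percentage_appearance(
    cluster: Cluster, ct: pd.DataFrame, mode: str = "sum"
) -> float:
    """Largest post-immunization weekly percentage appearance (weeks > 0)."""
    post = [w for w in weeks_of(ct) if w > 0]
    if not post:
        return 0.0
    return max(percentage_appearance(cluster, ct, w, mode) for w in post)


@dataclass
class ClusterPrediction:
    cluster_id: str
    slope: float
    intercept: float
    turnover_idx: float
    n_dominants: int
    turnover_pass: bool
    max_pct_appearance: float
    predicted_hit: bool


def predict_hits(
    clusters: list[Cluster],
    ct: pd.DataFrame,
    germ: pd.DataFrame,
    intercept_threshold: float = 380.0,
    pct_mode: str = "sum",
    weight_by_frequency: bool = False,
    min_dominants: int = 3,
) -> pd.DataFrame:
    """Score every cluster and call hits by the three-criterion conjunction.

    A cluster whose regression is undefined (all points in one week) fails
    the slope criterion by convention.  The report is sorted by descending
    maximum percentage appearance.
    """
    preds = []
    for cl in clusters:
        pts = trajectory(cl, ct, germ)
        if weight_by_frequency:
            slope, intercept = weighted_fit_bitscore_line(pts, ct)
        else:
            slope, intercept = fit_bitscore_line(pts)
        idx, n_dom, t_pass = turnover_index(cl, ct, min_dominants=min_dominants)
        mpa = max_percentage_appearance(cl, ct, pct_mode)
        hit = bool(
            not np.isnan(slope)
            and slope < 0
            and intercept > intercept_threshold
            and t_pass
        )
        preds.append(
            ClusterPrediction(
                cl.cluster_id, slope, intercept, idx, n_dom, t_pass, mpa, hit
            )
        )
    df = pd.DataFrame([p.__dict__ for p in preds])
    if len(df):
        df = df.sort_values(
            "max_pct_appearance", ascending=False, kind="mergesort"
        ).reset_index(drop=True)
    return df
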