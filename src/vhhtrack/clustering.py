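"""Clonal-lineage cluster isolation.

Surviving sequences are partitioned into clusters that proxy clonal
lineages: after dropping noisy rows (maximum frequency 1, unless protected)
and lonely rows (U40 < 10), sequences are grouped by exact length and
assigned V/J genes, pairwise Jukes-Cantor (JC69) distances are computed
within each group, and connected components of the graph with edges at
distance <= 0.04 become clusters when they hold more than seven unique
sequences.  Clusters containing any sequence already present before
immunization (week 0) are discarded: a de novo response cannot predate its
antigen.

Distances are computed from positional substitutions; group members share an
exact length, so under substitution-only divergence a multiple alignment is
the identity and the JC69 closed form applies directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj

from .chronology import week_columns

__all__ = [
    "u40_counts",
    "prefilter",
    "group_sequences",
    "jc69_distance",
    "pairwise_jc69",
    "isolate_clusters",
    "discard_preimmune",
    "assign_cluster_ids",
    "build_nj_tree",
    "Cluster",
]


def _encode(seqs: list[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
        len(seqs), -1
    )


def u40_counts(ct: pd.DataFrame, radius: int = 40, chunk: int = 256) -> pd.Series:
    """U40 per row: other unique equal-length sequences within < ``radius`` bp.

    Counts distinct sequences (a clone shared between isotypes is one
    sequence) at Hamming distance 1..radius-1 from the row's sequence; the
    sequence itself is excluded.  Low U40 marks lonely, likely artifactual
    reads.
    """
    result = pd.Series(0, index=ct.index, dtype=int)
    seqs = ct["sequence"]
    for _, idx in seqs.groupby(seqs.str.len()).groups.items():
        uniq = sorted(set(seqs.loc[idx]))
        if len(uniq) == 1:
            continue
        enc = _encode(uniq)
        counts = np.zeros(len(uniq), dtype=int)
        for start in range(0, len(uniq), chunk):
            block = enc[start : start + chunk]
            d = (block[:, None, :] != enc[None, :, :]).sum(axis=2)
            counts[start : start + chunk] = (
                (d >= 1) & (d < radius)
            ).sum(axis=1)
        lookup = dict(zip(uniq, counts))
        result.loc[idx] = [lookup[s] for s in seqs.loc[idx]]
    return result


def prefilter(
    ct: pd.DataFrame,
    protected: set[str] | frozenset[str] = frozenset(),
    min_u40: int = 10,
    u40: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Noise filters ahead of clustering, in the stated order.

    First rows with ``max_freq == 1`` are dropped unless their sequence is in
    ``protected`` (empirically identified clones, e.g. from phage display);
    then rows with U40 < ``min_u40`` are dropped.  U40 is computed on the full
    table before any row is removed.  Returns the filtered table and an
    attrition accounting.
    """
    if u40 is None:
        u40 = u40_counts(ct)
    ct = ct.copy()
    ct["u40"] = u40

    is_minor = (ct["max_freq"] == 1) & ~ct["sequence"].isin(protected)
    after_minor = ct.loc[~is_minor]
    lonely = after_minor["u40"] < min_u40
    out = after_minor.loc[~lonely].reset_index(drop=True)
    attrition = {
        "input": len(ct),
        "dropped_max_freq_1": int(is_minor.sum()),
        "dropped_low_u40": int(lonely.sum()),
        "kept": len(out),
    }
    return out, attrition


def group_sequences(
    ct: pd.DataFrame, germ: pd.DataFrame, min_group: int = 8
) -> dict[tuple[int, str, str], pd.DataFrame]:
    """Partition rows by (length, V gene, J gene); drop small groups.

    Groups with fewer than ``min_group`` unique sequences are removed (their
    members cannot form a valid cluster).  Unassigned rows are excluded.
    """
    merged = ct.merge(
        germ[["sequence_id", "v_gene", "j_gene"]], on="sequence_id", how="left"
    )
    merged = merged.dropna(subset=["v_gene", "j_gene"])
    merged["length"] = merged["sequence"].str.len()
    groups = {}
    for key, sub in merged.groupby(["length", "v_gene", "j_gene"], sort=True):
        if sub["sequence"].nunique() >= min_group:
            groups[(int(key[0]), key[1], key[2])] = sub.reset_index(drop=True)
    return groups


def jc69_distance(a: str, b: str) -> float:
    """Jukes-Cantor distance ``-(3/4) ln(1 - 4p/3)`` from the mismatch fraction.

    Saturates to +inf at p >= 0.75.  Sequences must be equal length.
    """
    if len(a) != len(b):
        raise ValueError("JC69 requires equal-length sequences")
    p = sum(x != y for x, y in zip(a, b)) / len(a)
    return jc69_from_p(p)


def jc69_from_p(p: float | np.ndarray):
    arg = 1.0 - 4.0 * np.asarray(p, dtype=float) / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(arg > 0, -0.75 * np.log(np.where(arg > 0, arg, 1.0)), np.inf)
    if np.isscalar(p) or np.ndim(p) == 0:
        return float(d)
    return d


def pairwise_jc69(seqs: list[str]) -> np.ndarray:
    """Symmetric JC69 distance matrix for equal-length sequences."""
    enc = _encode(seqs)
    diffs = (enc[:, None, :] != enc[None, :, :]).sum(axis=2)
    return jc69_from_p(diffs / enc.shape[1])


@dataclass
class Cluster:
    cluster_id: str | None
    group_key: tuple[int, str, str]
    sequences: list[str]                # unique nucleotide sequences
    member_ids: list[str]               # sequence_ids (rows, both isotypes)
    seq_ids: dict[str, list[str]] = field(default_factory=dict)
    weekly_totals: dict[int, int] = field(default_factory=dict)
    contains_preimmune: bool = False

    @property
    def size(self) -> int:
        return len(self.sequences)


def isolate_clusters(
    group: pd.DataFrame,
    group_key: tuple[int, str, str],
    threshold: float = 0.04,
    min_cluster: int = 8,
) -> list[Cluster]:
    """Connected components of the thresholded JC69 graph within one group.

    An edge joins two unique sequences when their distance is <= threshold
    (the boundary is inclusive: only distances *surpassing* the threshold
    break links).  Components with more than ``min_cluster - 1`` unique
    sequences are emitted; smaller ones are discarded.
    """
    uniq = sorted(group["sequence"].unique())
    dm = pairwise_jc69(uniq)
    g = nx.Graph()
    g.add_nodes_from(range(len(uniq)))
    ii, jj = np.where(np.triu(dm <= threshold, k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    clusters = []
    for comp in nx.connected_components(g):
        if len(comp) < min_cluster:
            continue
        seqs = sorted(uniq[i] for i in comp)
        rows = group.loc[group["sequence"].isin(seqs)]
        seq_ids = {
            s: sorted(rows.loc[rows["sequence"] == s, "sequence_id"])
            for s in seqs
        }
        clusters.append(
            Cluster(
                None,
                group_key,
                seqs,
                sorted(rows["sequence_id"]),
                seq_ids=seq_ids,
            )
        )
    return clusters


def _fill_weekly_totals(cluster: Cluster, ct: pd.DataFrame) -> None:
    rows = ct.loc[ct["sequence_id"].isin(cluster.member_ids)]
    cluster.weekly_totals = {
        int(c.split("_")[1]): int(rows[c].sum()) for c in week_columns(ct)
    }


def discard_preimmune(
    clusters: list[Cluster], ct: pd.DataFrame, baseline_week: int = 0
) -> tuple[list[Cluster], list[Cluster]]:
    """Split clusters into (kept, discarded-as-preimmune).

    Any member row with a nonzero frequency at the baseline (pre-immunization)
    week condemns the whole cluster; protection of individual clones does not
    override this.
    """
    col = f"freq_{baseline_week}"
    kept, dropped = [], []
    for cl in clusters:
        rows = ct.loc[ct["sequence_id"].isin(cl.member_ids)]
        pre = bool((rows[col] > 0).any()) if col in ct else False
        cl.contains_preimmune = pre
        (dropped if pre else kept).append(cl)
    return kept, dropped


def assign_cluster_ids(
    clusters: list[Cluster], ct: pd.DataFrame, prefix: str = "C"
) -> list[Cluster]:
    """Rank clusters by maximum weekly summed member frequency, descending.

    IDs are ``<prefix>-1``, ``<prefix>-2``, ... ; ties break by earlier peak
    week, then by the lexicographically smallest member ID.
    """
    for cl in clusters:
        _fill_weekly_totals(cl, ct)

    def sort_key(cl: Cluster):
        peak = max(cl.weekly_totals.values()) if cl.weekly_totals else 0
        peak_week = min(
            (w for w, v in cl.weekly_totals.items() if v == peak), default=0
        )
        anchor = cl.member_ids[0] if cl.member_ids else ""
        return (-peak, peak_week, anchor)

    ordered = sorted(clusters, key=sort_key)
    for i, cl in enumerate(ordered, start=1):
        cl.cluster_id = f"{prefix}-{i}"
    return ordered


def build_nj_tree(cluster: Cluster) -> str:
    """Neighbor-joining newick tree on the cluster's JC69 distance matrix.

    One tip per unique sequence, labelled by its first sequence ID (a clone
    shared between isotypes appears once).  Fewer than three sequences yields
    a trivial star tree.
    """
    labels = [
        cluster.seq_ids.get(s, [f"seq{i}"])[0]
        for i, s in enumerate(cluster.sequences)
    ]
    if len(cluster.sequences) < 3:
        return "(" + ",".join(labels) + ");"
    dm = pairwise_jc69(cluster.sequences)
    tree = nj(DistanceMatrix(dm, ids=labels))
    return str(tree).strip()
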