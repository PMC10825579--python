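"""Frequency-driven sequencing-error cleanup.

Amplicon sequencing scatters each true molecule into a cloud of rare
error-derived neighbours.  The cleanup walks the sequence-frequency table in
descending frequency order: the current most-frequent sequence becomes the
reference sequence (RS), every equal-length sequence within a
frequency-dependent Hamming radius ``n`` is collected, genuinely independent
minor variants (frequency ratio to the RS above a diff-count-dependent
threshold ``r``) and their derivatives are set aside, and the remainder is
absorbed into the RS's integrated frequency.  Iteration stops once the top
frequency is 1; untouched singletons pass through.

Total read count is conserved exactly, and independent variants return to the
pool so each eventually becomes an RS of its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "error_number_threshold",
    "independence_threshold",
    "build_integration_set",
    "mark_independent_and_derivatives",
    "cleanup",
]


def error_number_threshold(rs_frequency: int) -> int:
    """Allowed error count ``n`` for members of the integration set.

    Bands: 2-400 -> 3, 401-1000 -> 4, >1000 -> 5.  Chosen so that RS-derived
    errors remain Poisson-plausible at the RS's abundance.
    """
    if rs_frequency < 2:
        raise ValueError("RS frequency must be >= 2 (iteration stops at 1)")
    if rs_frequency <= 400:
        return 3
    if rs_frequency <= 1000:
        return 4
    return 5


def independence_threshold(num_changes: int) -> float:
    """Frequency-ratio threshold ``r`` above which a variant is independent.

    8% / 3% / 1% / 0.2% for 1 / 2 / 3 / >=4 base changes; set above the
    plausible error rate so that real minor variants are not absorbed.
    """
    if num_changes < 1:
        raise ValueError("num_changes must be >= 1")
    return {1: 0.08, 2: 0.03, 3: 0.01}.get(num_changes, 0.002)


@dataclass
class IntegrationMember:
    sequence: str
    frequency: int
    diffs: frozenset[tuple[int, str]]  # (position, member base) vs the RS


@dataclass
class IntegrationSet:
    rs: str
    rs_frequency: int
    members: list[IntegrationMember]  # excludes the RS itself
    independent: list[IntegrationMember] = field(default_factory=list)
    derivative: list[IntegrationMember] = field(default_factory=list)


def _diff_pattern(rs: str, seq: str) -> frozenset[tuple[int, str]]:
    return frozenset((i, b) for i, (a, b) in enumerate(zip(rs, seq)) if a != b)


def build_integration_set(table: pd.DataFrame, rs: str) -> IntegrationSet:
    """Collect equal-length sequences within Hamming distance ``n`` of the RS."""
    freq = dict(zip(table["sequence"], table["frequency"]))
    rs_freq = int(freq[rs])
    n = error_number_threshold(rs_freq)
    members = []
    for seq, f in freq.items():
        if seq == rs or len(seq) != len(rs):
            continue
        diffs = _diff_pattern(rs, seq)
        if 1 <= len(diffs) <= n:
            members.append(IntegrationMember(seq, int(f), diffs))
    return IntegrationSet(rs, rs_freq, members)


def mark_independent_and_derivatives(ds: IntegrationSet) -> IntegrationSet:
    """Remove independent variants and their derivatives from the set.

    A member whose frequency ratio to the RS strictly exceeds
    ``independence_threshold(#changes)`` is independent.  A member whose diff
    pattern contains an independent member's full diff pattern is a
    derivative of that variant rather than of the RS.  Both classes leave the
    integration set but stay in the main table for later iterations.
    """
    independent, rest = [], []
    for m in ds.members:
        if m.frequency / ds.rs_frequency > independence_threshold(len(m.diffs)):
            independent.append(m)
        else:
            rest.append(m)
    derivative, keep = [], []
    patterns = [m.diffs for m in independent]
    for m in rest:
        if any(m.diffs >= p for p in patterns):
            derivative.append(m)
        else:
            keep.append(m)
    return IntegrationSet(ds.rs, ds.rs_frequency, keep, independent, derivative)


@dataclass
class AbsorptionEvent:
    parent: str
    child: str
    distance: int
    parent_frequency: int
    child_frequency: int


class _LengthGroup:
    """Equal-length sequences as a byte matrix for vectorized Hamming scans."""

    def __init__(self, seqs: list[str], freqs: list[int]):
        self.seqs = seqs
        self.freqs = np.asarray(freqs, dtype=np.int64)
        self.enc = np.frombuffer(
            "".join(seqs).encode(), dtype=np.uint8
        ).reshape(len(seqs), -1) if seqs else np.empty((0, 0), np.uint8)
        self.active = np.ones(len(seqs), dtype=bool)

    def distances_to(self, idx: int) -> np.ndarray:
        return (self.enc != self.enc[idx]).sum(axis=1)


def cleanup(
    table: pd.DataFrame,
    derivative_mode: str = "superset",
    report: list[AbsorptionEvent] | None = None,
) -> pd.DataFrame:
    """Run the full iterative error cleanup on one sample table.

    Parameters
    ----------
    table
        Columns ``sequence`` and ``frequency``; sequences unique.
    derivative_mode
        ``"superset"`` (default): a member is a derivative when its diff
        pattern contains an independent member's pattern.  ``"exact"``
        requires equality, which cannot occur between distinct sequences and
        is provided only to expose the alternative reading.
    report
        Optional list receiving one :class:`AbsorptionEvent` per absorption.

    Returns the cleaned table (integrated frequencies), sorted by descending
    frequency then sequence.  Total frequency is conserved exactly.
    """
    if derivative_mode not in ("superset", "exact"):
        raise ValueError("derivative_mode must be 'superset' or 'exact'")
    if table.empty:
        return table.copy()
    if table["sequence"].duplicated().any():
        raise ValueError("input sequences must be unique")

    groups: dict[int, _LengthGroup] = {}
    for length, sub in table.groupby(table["sequence"].str.len()):
        groups[int(length)] = _LengthGroup(
            list(sub["sequence"]), list(sub["frequency"])
        )

    out_seqs: list[str] = []
    out_freqs: list[int] = []

    while True:
        # current RS: highest active frequency, ties to lexicographic smallest
        best: tuple[int, str, int, _LengthGroup] | None = None
        for g in groups.values():
            act = np.flatnonzero(g.active)
            if act.size == 0:
                continue
            top = int(g.freqs[act].max())
            cands = act[g.freqs[act] == top]
            idx = int(min(cands, key=lambda i: g.seqs[i]))
            if (
                best is None
                or top > best[2]
                or (top == best[2] and g.seqs[idx] < best[1])
            ):
                best = (idx, g.seqs[idx], top, g)
        if best is None:
            break
        idx, rs, rs_freq, g = best
        if rs_freq <= 1:
            break

        n = error_number_threshold(rs_freq)
        dists = g.distances_to(idx)
        cand = np.flatnonzero(g.active & (dists >= 1) & (dists <= n))

        members = [
            IntegrationMember(
                g.seqs[i], int(g.freqs[i]), _diff_pattern(rs, g.seqs[i])
            )
            for i in cand
        ]
        ds = mark_independent_and_derivatives(
            IntegrationSet(rs, rs_freq, members)
        )
        if derivative_mode == "exact":
            # equality of diff patterns implies sequence identity: re-admit
            ds.members.extend(ds.derivative)
            ds.derivative = []

        integrated = rs_freq
        absorbed_idx = []
        member_pos = {m.sequence: m for m in ds.members}
        for i in cand:
            m = member_pos.get(g.seqs[i])
            if m is None:
                continue
            integrated += m.frequency
            absorbed_idx.append(i)
            if report is not None:
                report.append(
                    AbsorptionEvent(
                        rs, m.sequence, len(m.diffs), rs_freq, m.frequency
                    )
                )
        g.active[idx] = False
        for i in absorbed_idx:
            g.active[i] = False
        out_seqs.append(rs)
        out_freqs.append(integrated)

    # pass through whatever remains active (singletons at loop exit)
    for g in groups.values():
        for i in np.flatnonzero(g.active):
            out_seqs.append(g.seqs[i])
            out_freqs.append(int(g.freqs[i]))

    out = pd.DataFrame({"sequence": out_seqs, "frequency": out_freqs})
    out = out.sort_values(
        ["frequency", "sequence"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out
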