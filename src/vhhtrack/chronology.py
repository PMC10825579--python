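"""Chronological sequence-frequency tables.

Per-week cleaned tables of one isotype are full-joined into a single matrix
(unique sequence x week), the per-row maximum frequency is computed, and
sequence IDs are assigned in descending maximum-frequency order: ``S1, S2,
...`` for the short-hinge isotype (IgG2) and ``L1, L2, ...`` for the
long-hinge isotype (IgG3).  The two isotype tables are then stacked; the same
nucleotide sequence may legitimately appear once per isotype.
"""

from __future__ import annotations

import re

import pandas as pd

ID_PREFIX = {"IgG2": "S", "IgG3": "L"}

_WEEK_RE = re.compile(r"^freq_(\d+)$")


def week_columns(ct: pd.DataFrame) -> list[str]:
    cols = [c for c in ct.columns if _WEEK_RE.match(c)]
    return sorted(cols, key=lambda c: int(c.split("_")[1]))


def weeks_of(ct: pd.DataFrame) -> list[int]:
    return [int(c.split("_")[1]) for c in week_columns(ct)]


def full_join_weeks(tables: dict[int, pd.DataFrame]) -> pd.DataFrame:
    """Outer-join per-week tables on sequence; absent (sequence, week) -> 0."""
    if len(tables) == 0:
        raise ValueError("no per-week tables supplied")
    weeks = sorted(tables)
    if len(weeks) != len(set(weeks)):
        raise ValueError("duplicate week")
    out: pd.DataFrame | None = None
    for w in weeks:
        t = tables[w][["sequence", "frequency"]].rename(
            columns={"frequency": f"freq_{w}"}
        )
        out = t if out is None else out.merge(t, on="sequence", how="outer")
    assert out is not None
    wcols = [f"freq_{w}" for w in weeks]
    out[wcols] = out[wcols].fillna(0).astype(int)
    out["max_freq"] = out[wcols].max(axis=1)
    return out


def first_week(row: pd.Series, wcols: list[str]) -> int:
    for c in wcols:
        if row[c] > 0:
            return int(c.split("_")[1])
    raise ValueError("row has no nonzero week")


def assign_ids(ct: pd.DataFrame, isotype: str) -> pd.DataFrame:
    """Sort by descending max frequency and assign S#/L# IDs.

    Ties are broken by earlier first-appearance week, then by sequence, so the
    numbering is invariant to input row order.
    """
    prefix = ID_PREFIX[isotype]
    wcols = week_columns(ct)
    ct = ct.copy()
    ct["_first"] = [first_week(r, wcols) for _, r in ct.iterrows()]
    ct = ct.sort_values(
        ["max_freq", "_first", "sequence"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    ct.insert(0, "sequence_id", [f"{prefix}{i + 1}" for i in range(len(ct))])
    ct.insert(1, "isotype", isotype)
    return ct.drop(columns="_first")


def build_isotype_table(tables: dict[int, pd.DataFrame], isotype: str) -> pd.DataFrame:
    return assign_ids(full_join_weeks(tables), isotype)


def stack_isotypes(igg2: pd.DataFrame, igg3: pd.DataFrame) -> pd.DataFrame:
    """Vertically combine the two isotype tables into the chronological table."""
    if len(igg2) == 0:
        return igg3.reset_index(drop=True)
    if len(igg3) == 0:
        return igg2.reset_index(drop=True)
    if weeks_of(igg2) != weeks_of(igg3):
        raise ValueError("isotype tables cover different week sets")
    return pd.concat([igg2, igg3], ignore_index=True)


def write_chronological_tsv(ct: pd.DataFrame, path) -> None:
    ct.to_csv(path, sep="\t", index=False)


def read_chronological_tsv(path) -> pd.DataFrame:
    ct = pd.read_csv(path, sep="\t", dtype={"sequence": str})
    for c in week_columns(ct) + ["max_freq"]:
        ct[c] = ct[c].astype(int)
    return ct
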