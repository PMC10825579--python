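"""Paired-end amplicon read processing.

Turns raw MiSeq-style mate pairs into per-sample sequence-frequency tables:
quality trimming (modified-Mott), overlap merging with a quality-aware
consensus, removal of the isotype-specific constant-region tail, and VHH
validity filtering (no ambiguous calls, in-frame, stop-free).

Pre-merged input (FASTA, or ``sequence<TAB>frequency`` TSV) may bypass this
module entirely; the downstream analysis only needs the tables.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import Seq

ISOTYPES = ("IgG2", "IgG3")

#: number of 3' constant-region bases carried by the amplicon, per isotype
CONSTANT_TAIL = {"IgG2": 21, "IgG3": 24}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadPair:
    """One mate pair with per-base Phred qualities and its sample key."""

    forward: str
    forward_qual: Sequence[int]
    reverse: str
    reverse_qual: Sequence[int]
    week: int = 0
    isotype: str = "IgG2"

    def __post_init__(self) -> None:
        if len(self.forward) != len(self.forward_qual):
            raise ValueError("forward sequence/quality length mismatch")
        if len(self.reverse) != len(self.reverse_qual):
            raise ValueError("reverse sequence/quality length mismatch")


@dataclass
class MergedRead:
    sequence: str
    week: int
    isotype: str


# ---------------------------------------------------------------------------
# quality trimming (modified-Mott)
# ---------------------------------------------------------------------------

def phred_error_probs(quals: Sequence[int]) -> np.ndarray:
    return 10.0 ** (-np.asarray(quals, dtype=float) / 10.0)


def mott_segment(quals: Sequence[int], limit: float) -> tuple[int, int]:
    """Best retained segment ``[start, end)`` under the modified-Mott rule.

    Each base contributes ``limit - p_err``; the retained segment is the
    contiguous run maximizing the cumulative contribution (Kadane scan, ties
    resolved to the earliest such segment).  Returns ``(0, 0)`` when every
    segment scores <= 0, i.e. the read is fully trimmed.
    """
    if not 0.0 < limit < 1.0:
        raise ValueError("limit must lie in (0, 1)")
    gains = limit - phred_error_probs(quals)
    best_sum = 0.0
    best = (0, 0)
    run_sum = 0.0
    run_start = 0
    for i, g in enumerate(gains):
        if run_sum <= 0.0:
            run_sum = g
            run_start = i
        else:
            run_sum += g
        if run_sum > best_sum:
            best_sum = run_sum
            best = (run_start, i + 1)
    return best


def quality_trim(pair: ReadPair, limit: float = 0.01) -> ReadPair | None:
    """Trim both mates; returns ``None`` when either mate trims away fully."""
    fs, fe = mott_segment(pair.forward_qual, limit)
    rs, re_ = mott_segment(pair.reverse_qual, limit)
    if fe == fs or re_ == rs:
        return None
    return replace(
        pair,
        forward=pair.forward[fs:fe],
        forward_qual=list(pair.forward_qual[fs:fe]),
        reverse=pair.reverse[rs:re_],
        reverse_qual=list(pair.reverse_qual[rs:re_]),
    )


# ---------------------------------------------------------------------------
# overlap merging
# ---------------------------------------------------------------------------

def _gapless_overlap(
    fwd: str, rc: str, mismatch_cost: int
) -> tuple[int, int]:
    """Best suffix(fwd)/prefix(rc) gapless overlap.

    Returns ``(score, overlap_len)`` maximizing
    ``matches - mismatch_cost * mismatches``; ties prefer the longer overlap.
    """
    best_score, best_len = -(10**9), 0
    max_l = min(len(fwd), len(rc))
    fa = np.frombuffer(fwd.encode(), dtype=np.uint8)
    ra = np.frombuffer(rc.encode(), dtype=np.uint8)
    for L in range(1, max_l + 1):
        mism = int((fa[-L:] != ra[:L]).sum())
        score = (L - mism) - mismatch_cost * mism
        if score > best_score or (score == best_score and L > best_len):
            best_score, best_len = score, L
    return best_score, best_len


def _overlap_aligner(mismatch_cost: int, gap_cost: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -mismatch_cost
    aligner.open_gap_score = -gap_cost
    aligner.extend_gap_score = -gap_cost
    # free end gaps (attribute names changed across biopython releases)
    try:
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner


def merge_pair(
    pair: ReadPair,
    mismatch_cost: int = 2,
    gap_cost: int = 3,
    min_score: int = 8,
) -> MergedRead | None:
    """Merge a mate pair across its overlap, or ``None`` on failure.

    The reverse mate is reverse-complemented, the suffix/prefix overlap
    maximizing ``matches - mismatch_cost*mismatches - gap_cost*gap_columns``
    is located (gapless scan first, affine-free gapped fallback), and the
    consensus is emitted when the best score reaches ``min_score``.  At
    overlap mismatches the higher-Phred base wins; ties keep the forward base.
    """
    fwd, rc = pair.forward, reverse_complement(pair.reverse)
    fq = list(pair.forward_qual)
    rq = list(pair.reverse_qual)[::-1]

    score, L = _gapless_overlap(fwd, rc, mismatch_cost)
    if score >= min_score:
        head = fwd[: len(fwd) - L]
        tail = rc[L:]
        mid = []
        for i in range(L):
            fi = len(fwd) - L + i
            if fwd[fi] == rc[i] or fq[fi] >= rq[i]:
                mid.append(fwd[fi])
            else:
                mid.append(rc[i])
        return MergedRead(head + "".join(mid) + tail, pair.week, pair.isotype)

    # gapped fallback: overlap (free end gap) alignment
    aligner = _overlap_aligner(mismatch_cost, gap_cost)
    try:
        aln = aligner.align(fwd, rc)[0]
    except (ValueError, IndexError, OverflowError):
        return None
    if aln.score < min_score:
        return None
    f_idx, r_idx = aln.aligned
    if len(f_idx) == 0:
        return None
    f_start, f_end = int(f_idx[0][0]), int(f_idx[-1][1])
    r_start, r_end = int(r_idx[0][0]), int(r_idx[-1][1])
    if f_start < r_start:  # geometry inverted: rc precedes fwd
        return None
    mid = []
    fi, ri = f_start, r_start
    for (fb, fe), (rb, re_) in zip(f_idx, r_idx):
        # gap columns before this aligned block: keep whichever mate has bases
        mid.append(fwd[fi:fb])
        mid.append(rc[ri:rb])
        for k in range(fe - fb):
            a, b = fwd[fb + k], rc[rb + k]
            if a == b or fq[fb + k] >= rq[rb + k]:
                mid.append(a)
            else:
                mid.append(b)
        fi, ri = fe, re_
    merged = fwd[:f_start] + "".join(mid) + rc[r_end:]
    return MergedRead(merged, pair.week, pair.isotype)


# ---------------------------------------------------------------------------
# trimming and validity
# ---------------------------------------------------------------------------

def trim_constant_region(read: MergedRead) -> MergedRead | None:
    """Drop the isotype-specific 3' constant-region tail (21 nt IgG2, 24 nt IgG3)."""
    tail = CONSTANT_TAIL[read.isotype]
    if len(read.sequence) <= tail:
        return None
    return MergedRead(read.sequence[:-tail], read.week, read.isotype)


def filter_valid_vhh(sequence: str) -> bool:
    """A sequence passes iff it is unambiguous, in frame, and stop-free.

    Frame 1 is used: the amplification primers anchor the reading frame at a
    codon boundary, so a VHH-coding merged read translates cleanly.
    """
    if not sequence or set(sequence) - set("ACGT"):
        return False
    if len(sequence) % 3 != 0:
        return False
    return "*" not in str(Seq(sequence).translate())


def tabulate(reads: Iterable[MergedRead | str]) -> pd.DataFrame:
    """Collapse reads into a sequence-frequency table.

    Rows are sorted by descending frequency then sequence, one row per
    distinct sequence, with ``sum(frequency)`` equal to the input count.
    """
    counts = Counter(
        r.sequence if isinstance(r, MergedRead) else r for r in reads
    )
    df = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["sequence", "frequency"],
    )
    return df


# ---------------------------------------------------------------------------
# sample-level driver and I/O
# ---------------------------------------------------------------------------

@dataclass
class SampleQC:
    week: int
    isotype: str
    reads_in: int = 0
    trim_discarded: int = 0
    merge_failed: int = 0
    tail_discarded: int = 0
    validity_failed: int = 0
    merged: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def process_pairs(
    pairs: Iterable[ReadPair],
    limit: float = 0.01,
    mismatch_cost: int = 2,
    gap_cost: int = 3,
    min_score: int = 8,
) -> tuple[pd.DataFrame, SampleQC]:
    """Full per-sample read path: trim, merge, de-tail, validate, tabulate."""
    qc: SampleQC | None = None
    kept: list[str] = []
    for pair in pairs:
        if qc is None:
            qc = SampleQC(pair.week, pair.isotype)
        qc.reads_in += 1
        trimmed = quality_trim(pair, limit)
        if trimmed is None:
            qc.trim_discarded += 1
            continue
        merged = merge_pair(trimmed, mismatch_cost, gap_cost, min_score)
        if merged is None:
            qc.merge_failed += 1
            continue
        detailed = trim_constant_region(merged)
        if detailed is None:
            qc.tail_discarded += 1
            continue
        if not filter_valid_vhh(detailed.sequence):
            qc.validity_failed += 1
            continue
        qc.merged += 1
        kept.append(detailed.sequence)
    if qc is None:
        qc = SampleQC(0, "IgG2")
    return tabulate(kept), qc


def _open_maybe_gz(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq_pairs(
    r1: str | Path, r2: str | Path, week: int, isotype: str
) -> Iterator[ReadPair]:
    with _open_maybe_gz(r1) as h1, _open_maybe_gz(r2) as h2:
        for rec1, rec2 in zip(
            SeqIO.parse(h1, "fastq"), SeqIO.parse(h2, "fastq")
        ):
            yield ReadPair(
                str(rec1.seq).upper(),
                rec1.letter_annotations["phred_quality"],
                str(rec2.seq).upper(),
                rec2.letter_annotations["phred_quality"],
                week,
                isotype,
            )


def read_table_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str})
    if not {"sequence", "frequency"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'sequence' and 'frequency'")
    df["frequency"] = df["frequency"].astype(int)
    return df[["sequence", "frequency"]]


def write_table_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_manifest(path: str | Path) -> list[dict]:
    """Run manifest: list of ``{"week": int, "isotype": str, ...file keys}``.

    File keys per entry are either ``r1``/``r2`` (paired FASTQ), ``fasta``
    (pre-merged reads) or ``table`` (sequence/frequency TSV).
    """
    entries = json.loads(Path(path).read_text())
    if not isinstance(entries, list):
        raise ValueError("manifest must be a JSON list")
    seen = set()
    for e in entries:
        key = (e["week"], e["isotype"])
        if e["isotype"] not in ISOTYPES:
            raise ValueError(f"unknown isotype {e['isotype']!r}")
        if key in seen:
            raise ValueError(f"duplicate sample {key} in manifest")
        seen.add(key)
    return entries


def load_sample(entry: dict, base: Path | None = None, **merge_kw) -> tuple[pd.DataFrame, dict]:
    """Materialize one manifest entry into a sequence-frequency table."""
    def _p(name: str) -> Path:
        p = Path(entry[name])
        return p if base is None or p.is_absolute() else base / p

    week, isotype = int(entry["week"]), entry["isotype"]
    if "table" in entry:
        df = read_table_tsv(_p("table"))
        return df, {"week": week, "isotype": isotype, "reads_in": int(df["frequency"].sum())}
    if "fasta" in entry:
        seqs = [
            str(rec.seq).upper() for rec in SeqIO.parse(str(_p("fasta")), "fasta")
        ]
        kept = [s for s in seqs if filter_valid_vhh(s)]
        df = tabulate(kept)
        return df, {
            "week": week,
            "isotype": isotype,
            "reads_in": len(seqs),
            "validity_failed": len(seqs) - len(kept),
        }
    pairs = iter_fastq_pairs(_p("r1"), _p("r2"), week, isotype)
    df, qc = process_pairs(pairs, **merge_kw)
    return df, qc.as_dict()
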