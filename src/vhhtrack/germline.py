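"""Germline V/J assignment by local alignment.

Each unique VHH nucleotide sequence is aligned (Smith-Waterman, affine gaps)
against a germline database of IGHV and IGHJ nucleotide sequences; the
highest-scoring gene of each class is the assigned origin.  Similarity is
reported as the Karlin-Altschul bit score ``(lambda*raw - ln K) / ln 2``,
which decreases as somatic hypermutation carries a sequence away from its
germline — the quantity tracked over the immunization time course.

Default nucleotide scoring is match +2 / mismatch -3 with gap open 5 /
extend 2 and (lambda=0.625, K=0.41), the conventional constants for that
scheme.  Absolute bit-score thresholds downstream (e.g. the 380-bit intercept
cut) are interpreted on this scale and are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Data import CodonTable

__all__ = [
    "ScoringScheme",
    "GermlineDB",
    "GermlineAssignment",
    "local_align",
    "bit_score",
    "assign_vj",
    "assign_table",
    "mutation_bitscore_calibration",
    "nonsynonymous_mutate",
]


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5   # BLAST-style: gap of length k costs open + k*extend
    gap_extend: int = 2
    lam: float = 0.625
    k: float = 0.41

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        # biopython charges open_gap_score for the first gap position and
        # extend_gap_score for each further one; BLAST charges open + extend
        # for a length-1 gap.
        a.open_gap_score = -(self.gap_open + self.gap_extend)
        a.extend_gap_score = -self.gap_extend
        return a


DEFAULT_SCORING = ScoringScheme()


@dataclass
class GermlineDB:
    v_genes: dict[str, str]
    j_genes: dict[str, str]

    def __post_init__(self) -> None:
        if not self.v_genes or not self.j_genes:
            raise ValueError("germline database must contain V and J genes")

    @classmethod
    def from_fasta(cls, v_path: str | Path, j_path: str | Path) -> "GermlineDB":
        def load(p):
            return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(p), "fasta")}

        return cls(load(v_path), load(j_path))

    def to_fasta(self, v_path: str | Path, j_path: str | Path) -> None:
        for path, genes in ((v_path, self.v_genes), (j_path, self.j_genes)):
            with open(path, "w") as fh:
                for gid, seq in genes.items():
                    fh.write(f">{gid}\n{seq}\n")


@dataclass
class GermlineAssignment:
    sequence_id: str | None
    v_gene: str | None
    j_gene: str | None
    v_raw_score: int
    v_bit_score: float
    j_bit_score: float

    @property
    def assigned(self) -> bool:
        return self.v_gene is not None and self.j_gene is not None


def local_align(query: str, subject: str, scoring: ScoringScheme = DEFAULT_SCORING) -> int:
    """Optimal Smith-Waterman score of query vs subject (affine gaps)."""
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    return int(scoring.aligner().score(query, subject))


def bit_score(raw_score: float, lam: float = DEFAULT_SCORING.lam, k: float = DEFAULT_SCORING.k) -> float:
    """Karlin-Altschul normalization: ``(lambda * raw - ln K) / ln 2``."""
    if lam <= 0 or k <= 0:
        raise ValueError("lambda and K must be positive")
    return (lam * raw_score - math.log(k)) / math.log(2)


def _best_hit(query: str, genes: dict[str, str], scoring: ScoringScheme) -> tuple[str, int]:
    best_id, best_raw = None, -1
    for gid in sorted(genes):
        raw = local_align(query, genes[gid], scoring)
        if raw > best_raw:
            best_id, best_raw = gid, raw
    return best_id, best_raw


def assign_vj(
    sequence: str,
    db: GermlineDB,
    scoring: ScoringScheme = DEFAULT_SCORING,
    j_window: int = 60,
    floor_raw: int = 20,
    sequence_id: str | None = None,
) -> GermlineAssignment:
    """Best-scoring V and J gene for one sequence.

    Ranking by bit score is equivalent to ranking by e-value for a fixed
    query against a fixed database partition.  The J search is restricted to
    the query's 3' ``j_window`` nucleotides, where the J segment lies.  Hits
    below ``floor_raw`` leave the sequence unassigned (excluded downstream).
    """
    v_id, v_raw = _best_hit(sequence, db.v_genes, scoring)
    j_query = sequence[-j_window:]
    j_id, j_raw = _best_hit(j_query, db.j_genes, scoring)
    if v_raw < floor_raw or j_raw < floor_raw:
        return GermlineAssignment(sequence_id, None, None, v_raw,
                                  bit_score(v_raw, scoring.lam, scoring.k),
                                  bit_score(j_raw, scoring.lam, scoring.k))
    return GermlineAssignment(
        sequence_id,
        v_id,
        j_id,
        v_raw,
        bit_score(v_raw, scoring.lam, scoring.k),
        bit_score(j_raw, scoring.lam, scoring.k),
    )


def assign_table(
    ct: pd.DataFrame,
    db: GermlineDB,
    scoring: ScoringScheme = DEFAULT_SCORING,
    j_window: int = 60,
    floor_raw: int = 20,
) -> pd.DataFrame:
    """Assign V/J for every row of a chronological table.

    Identical nucleotide sequences (e.g. the same clone seen in both
    isotypes) are aligned once and share the assignment.  Returns a frame
    with one row per ``sequence_id``; unassigned rows carry NaN gene ids.
    """
    cache: dict[str, GermlineAssignment] = {}
    rows = []
    for sid, seq in zip(ct["sequence_id"], ct["sequence"]):
        asg = cache.get(seq)
        if asg is None:
            asg = assign_vj(seq, db, scoring, j_window, floor_raw)
            cache[seq] = asg
        rows.append(
            {
                "sequence_id": sid,
                "v_gene": asg.v_gene,
                "j_gene": asg.j_gene,
                "v_raw_score": asg.v_raw_score,
                "v_bitscore": asg.v_bit_score,
                "j_bitscore": asg.j_bit_score,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nonsynonymous mutagenesis and the mutation <-> bit score calibration
# ---------------------------------------------------------------------------

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_TABLE.forward_table)
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_CODON_TO_AA.items()):
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
NONSTOP_CODONS = sorted(_CODON_TO_AA)


def nonsynonymous_mutate(sequence: str, n_mutations: int, rng: np.random.Generator) -> str:
    """Apply ``n_mutations`` amino-acid-changing codon substitutions.

    Each mutated codon is replaced by a random codon of a different amino
    acid (never a stop), so one amino-acid mutation changes 1-3 nucleotides.
    Codon positions are sampled without replacement.
    """
    if len(sequence) % 3 != 0:
        raise ValueError("sequence length must be a multiple of 3")
    codons = [sequence[i : i + 3] for i in range(0, len(sequence), 3)]
    if n_mutations > len(codons):
        raise ValueError("more mutations than codons")
    positions = rng.choice(len(codons), size=n_mutations, replace=False)
    for pos in positions:
        old_aa = _CODON_TO_AA.get(codons[pos])
        choices = [c for c in NONSTOP_CODONS if _CODON_TO_AA[c] != old_aa]
        codons[pos] = choices[rng.integers(len(choices))]
    return "".join(codons)


def mutation_bitscore_calibration(
    db: GermlineDB,
    scoring: ScoringScheme = DEFAULT_SCORING,
    max_mut: int = 20,
    replicates: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean self-alignment bit score vs number of amino-acid mutations.

    Each replicate follows one cumulative mutation trajectory on the first V
    gene: codon positions are drawn without replacement and mutated one at a
    time (each to a random codon of a different amino acid), re-aligning
    against the germline after every step.  Scoring the same trajectory at
    every mutation count pairs the samples across m, so the mean curve
    decreases without the noise an independent draw per m would add.  The
    curve is the ruler for reading mutation loads off bit-score
    trajectories.
    """
    rng = np.random.default_rng(seed)
    v_id = sorted(db.v_genes)[0]
    v_seq = db.v_genes[v_id]
    n_codons = len(v_seq) // 3
    if max_mut > n_codons:
        raise ValueError("more mutations than codons")
    scores = np.empty((replicates, max_mut + 1))
    for r in range(replicates):
        order = rng.permutation(n_codons)[:max_mut]
        codons = [v_seq[i : i + 3] for i in range(0, len(v_seq), 3)]
        scores[r, 0] = bit_score(
            local_align(v_seq, v_seq, scoring), scoring.lam, scoring.k
        )
        for m, pos in enumerate(order, start=1):
            old_aa = _CODON_TO_AA.get(codons[pos])
            choices = [c for c in NONSTOP_CODONS if _CODON_TO_AA[c] != old_aa]
            codons[pos] = choices[rng.integers(len(choices))]
            mutated = "".join(codons)
            scores[r, m] = bit_score(
                local_align(mutated, v_seq, scoring), scoring.lam, scoring.k
            )
    return pd.DataFrame(
        {
            "n_aa_mutations": np.arange(max_mut + 1),
            "mean_bit_score": scores.mean(axis=0),
        }
    )
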