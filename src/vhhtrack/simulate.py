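"""Synthetic immunization time courses with known ground truth.

The generator emulates the dynamics the analysis is built to detect:

* **responding** lineages start within a couple of amino-acid changes of
  their germline V gene, accumulate nonsynonymous mutations week by week
  (affinity maturation), and keep replacing their dominant clone with a
  newly arisen one (sequence turnover);
* **static** lineages enter the repertoire already heavily matured (a fixed
  pre-maturation mutation load), keep an unchanging clone set, and are
  dominated by the same founder every week;
* **preimmune** lineages behave like static ones but are already present in
  the week-0 (pre-immunization) sample, so the clustering stage must discard
  them.

Clone counts are drawn multinomially to a fixed per-sample depth, and
sequencing noise is injected per read copy: each copy is an errored copy
with probability ``seq_error_rate``, carrying 1-3 random substitutions.
Every emitted sequence is tracked back to its lineage so each pipeline stage
has an oracle.  Evolution is substitution-only, so lineages conserve length
(the clustering stage groups by exact length).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .germline import GermlineDB, NONSTOP_CODONS, _CODON_TO_AA
from .reads import CONSTANT_TAIL

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_germline_db",
    "simulate_repertoire",
    "simulate_denoise_table",
    "emit_fixtures",
    "evaluate_predictions",
]

LABELS = ("responding", "static", "preimmune")


@dataclass
class SimulationConfig:
    seed: int = 0
    weeks: tuple[int, ...] = tuple(range(15))
    n_v_genes: int = 5
    n_j_genes: int = 2
    n_responding: int = 15
    n_static: int = 15
    n_preimmune: int = 5
    mutation_rate: float = 1.0      # aa-changing substitutions per week
    founder_mutations: int = 2      # max aa distance of a responding founder
    pre_maturation: int = 25        # aa mutations on static/preimmune founders
    turnover_prob: float = 0.6      # weekly dominant-replacement probability
    depth: int = 10_000             # reads per (week, isotype)
    seq_error_rate: float = 0.003   # per-copy probability of an errored read
    v_len: int = 300
    j_len: int = 48
    cdr3_lengths: tuple[int, ...] = (15, 18, 21, 24, 27, 30, 33, 36)
    isotype_share_prob: float = 0.5  # lineage expressed in both isotypes

    def __post_init__(self) -> None:
        if list(self.weeks) != sorted(set(self.weeks)) or self.weeks[0] != 0:
            raise ValueError("weeks must be strictly increasing, starting at 0")
        for r in (self.mutation_rate / 10, self.turnover_prob, self.seq_error_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class LineageTruth:
    lineage_id: int
    label: str
    v_gene: str
    j_gene: str
    isotypes: tuple[str, ...]
    first_week: int
    founder: str


@dataclass
class GroundTruth:
    lineages: list[LineageTruth]
    seq_lineage: dict[str, int]                       # every true clone
    true_counts: dict[tuple[int, str], dict[str, int]]  # pre-error counts
    error_children: list[dict] = field(default_factory=list)

    def label_of(self, lineage_id: int) -> str:
        return self.lineages[lineage_id].label


def _random_orf(n_codons: int, rng: np.random.Generator) -> str:
    idx = rng.integers(len(NONSTOP_CODONS), size=n_codons)
    return "".join(NONSTOP_CODONS[i] for i in idx)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def simulate_germline_db(config: SimulationConfig, rng: np.random.Generator | None = None) -> GermlineDB:
    """Random stop-free germline V (~300 nt) and J (~48 nt) genes.

    V genes are resampled until pairwise Hamming distance exceeds 60, so
    assignment margins are unambiguous.
    """
    rng = rng or np.random.default_rng(config.seed)
    v_genes: dict[str, str] = {}
    while len(v_genes) < config.n_v_genes:
        cand = _random_orf(config.v_len // 3, rng)
        if all(_hamming(cand, v) > 60 for v in v_genes.values()):
            v_genes[f"IGHV3S{len(v_genes) + 1:02d}"] = cand
    j_genes = {
        f"IGHJ{i + 1}": _random_orf(config.j_len // 3, rng)
        for i in range(config.n_j_genes)
    }
    return GermlineDB(v_genes, j_genes)


# ---------------------------------------------------------------------------
# lineage dynamics
# ---------------------------------------------------------------------------

def _mutate_variable_region(seq: str, n_aa: int, j_len: int, rng: np.random.Generator) -> str:
    """Nonsynonymous mutations confined to the V+CDR3 region (J untouched).

    Mutations are biased into three CDR-like codon windows to mimic
    hypermutation hotspots; length is conserved.
    """
    var, j = seq[: len(seq) - j_len], seq[len(seq) - j_len :]
    n_codons = len(var) // 3
    hotspots = [
        w
        for lo, hi in ((25, 36), (50, 60), (n_codons - 12, n_codons))
        for w in range(max(lo, 0), min(hi, n_codons))
    ]
    codons = [var[i : i + 3] for i in range(0, len(var), 3)]
    chosen: set[int] = set()
    while len(chosen) < min(n_aa, n_codons):
        if hotspots and rng.random() < 0.6:
            pos = hotspots[rng.integers(len(hotspots))]
        else:
            pos = int(rng.integers(n_codons))
        chosen.add(pos)
    for pos in chosen:
        old_aa = _CODON_TO_AA.get(codons[pos])
        choices = [c for c in NONSTOP_CODONS if _CODON_TO_AA[c] != old_aa]
        codons[pos] = choices[rng.integers(len(choices))]
    return "".join(codons) + j


@dataclass
class _Lineage:
    lineage_id: int
    label: str
    v_gene: str
    j_gene: str
    isotypes: tuple[str, ...]
    first_week: int
    founder: str
    weekly_clones: dict[int, dict[str, float]]  # week -> clone -> weight


def _static_clone_set(
    founder: str, j_len: int, rng: np.random.Generator, n_satellites: int = 11
) -> dict[str, float]:
    clones = {founder: 0.45}
    raw = [0.85 ** (i + 1) for i in range(n_satellites)]
    norm = 0.55 / sum(raw)
    for i in range(n_satellites):
        sat = _mutate_variable_region(founder, int(rng.integers(2, 4)), j_len, rng)
        clones[sat] = clones.get(sat, 0.0) + raw[i] * norm
    return clones


def _build_lineage(
    lineage_id: int,
    label: str,
    db: GermlineDB,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> _Lineage:
    v_id = sorted(db.v_genes)[rng.integers(len(db.v_genes))]
    j_id = sorted(db.j_genes)[rng.integers(len(db.j_genes))]
    cdr3 = _random_orf(
        int(rng.choice(config.cdr3_lengths)) // 3, rng
    )
    germ_seq = db.v_genes[v_id] + cdr3 + db.j_genes[j_id]
    if label == "responding":
        n0 = int(rng.integers(0, config.founder_mutations + 1))
    else:
        n0 = config.pre_maturation
    founder = (
        _mutate_variable_region(germ_seq, n0, config.j_len, rng)
        if n0
        else germ_seq
    )

    if rng.random() < config.isotype_share_prob:
        isotypes: tuple[str, ...] = ("IgG2", "IgG3")
    else:
        isotypes = (("IgG2",), ("IgG3",))[rng.integers(2)]

    weeks = list(config.weeks)
    if label == "preimmune":
        first = weeks[0]
    elif label == "static":
        first = weeks[1]
    else:
        first = weeks[1 + int(rng.integers(min(2, len(weeks) - 1)))]
    active = [w for w in weeks if w >= first]

    weekly: dict[int, dict[str, float]] = {}
    if label in ("static", "preimmune"):
        clones = _static_clone_set(founder, config.j_len, rng)
        satellites = [s for s in clones if s != founder]
        for w in active:
            # founder dominates every week; minor satellites drift in and
            # out of detectability, so first-appearance weeks vary while the
            # clone set itself never evolves
            present = {founder: clones[founder]}
            for s in satellites:
                if rng.random() < 0.7:
                    present[s] = clones[s]
            total = sum(present.values())
            weekly[w] = {s: v / total for s, v in present.items()}
    else:
        dominant, prev_dom, new_clone = founder, None, None
        sats_prev: list[str] = []
        last_w = active[0]
        evolving = config.mutation_rate > 0
        for w in active:
            if w != active[0] and evolving:
                delta = w - last_w
                n_aa = max(1, int(rng.poisson(config.mutation_rate * delta)))
                new_clone = _mutate_variable_region(
                    dominant, n_aa, config.j_len, rng
                )
                if rng.random() < 1 - (1 - config.turnover_prob) ** delta:
                    prev_dom, dominant = dominant, new_clone
                    new_clone = None
            sats = (
                [
                    _mutate_variable_region(dominant, 2, config.j_len, rng)
                    for _ in range(2)
                ]
                if evolving
                else []
            )
            weights: dict[str, float] = {dominant: 0.5}
            if prev_dom is not None and prev_dom != dominant:
                weights[prev_dom] = weights.get(prev_dom, 0.0) + 0.15
            if new_clone is not None and new_clone != dominant:
                weights[new_clone] = weights.get(new_clone, 0.0) + 0.12
            for s in sats:
                weights[s] = weights.get(s, 0.0) + 0.06
            for s in sats_prev:
                weights[s] = weights.get(s, 0.0) + 0.03
            total = sum(weights.values())
            weekly[w] = {s: v / total for s, v in weights.items()}
            sats_prev = sats
            last_w = w
    return _Lineage(
        lineage_id, label, v_id, j_id, isotypes, first, founder, weekly
    )


# ---------------------------------------------------------------------------
# sampling and error injection
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def _inject_errors(
    counts: dict[str, int],
    error_rate: float,
    rng: np.random.Generator,
    truth: GroundTruth | None = None,
    week: int | None = None,
    isotype: str | None = None,
) -> dict[str, int]:
    """Per-copy substitution errors: each errored copy gains 1-3 changes."""
    out = dict(counts)
    for seq, c in counts.items():
        n_err = int(rng.binomial(c, error_rate))
        if n_err == 0:
            continue
        out[seq] -= n_err
        for _ in range(n_err):
            k = int(rng.choice([1, 2, 3], p=[0.85, 0.12, 0.03]))
            pos = rng.choice(len(seq), size=k, replace=False)
            chars = list(seq)
            for p in pos:
                chars[p] = rng.choice(
                    [b for b in _BASES if b != chars[p]]
                )
            child = "".join(chars)
            out[child] = out.get(child, 0) + 1
            if truth is not None:
                truth.error_children.append(
                    {
                        "week": week,
                        "isotype": isotype,
                        "parent": seq,
                        "child": child,
                        "n_subs": k,
                    }
                )
        if out[seq] == 0:
            del out[seq]
    return out


def simulate_repertoire(
    config: SimulationConfig, db: GermlineDB | None = None
) -> tuple[dict[tuple[int, str], pd.DataFrame], GroundTruth]:
    """Generate per-(week, isotype) sequence-frequency tables plus truth."""
    rng = np.random.default_rng(config.seed)
    if db is None:
        db = simulate_germline_db(config, rng)

    labels = (
        ["responding"] * config.n_responding
        + ["static"] * config.n_static
        + ["preimmune"] * config.n_preimmune
    )
    lineages = [
        _build_lineage(i, lab, db, config, rng) for i, lab in enumerate(labels)
    ]

    truth = GroundTruth(
        lineages=[
            LineageTruth(
                l.lineage_id, l.label, l.v_gene, l.j_gene, l.isotypes,
                l.first_week, l.founder,
            )
            for l in lineages
        ],
        seq_lineage={},
        true_counts={},
    )
    for l in lineages:
        for clones in l.weekly_clones.values():
            for s in clones:
                truth.seq_lineage.setdefault(s, l.lineage_id)

    tables: dict[tuple[int, str], pd.DataFrame] = {}
    for week in config.weeks:
        for isotype in ("IgG2", "IgG3"):
            active = [
                l
                for l in lineages
                if isotype in l.isotypes and week in l.weekly_clones
            ]
            if not active:
                tables[(week, isotype)] = pd.DataFrame(
                    {"sequence": [], "frequency": []}
                )
                truth.true_counts[(week, isotype)] = {}
                continue
            probs: dict[str, float] = {}
            share = 1.0 / len(active)
            for l in active:
                for s, wgt in l.weekly_clones[week].items():
                    probs[s] = probs.get(s, 0.0) + share * wgt
            seqs = sorted(probs)
            p = np.array([probs[s] for s in seqs])
            p = p / p.sum()
            draws = rng.multinomial(config.depth, p)
            counts = {
                s: int(c) for s, c in zip(seqs, draws) if c > 0
            }
            truth.true_counts[(week, isotype)] = dict(counts)
            observed = _inject_errors(
                counts, config.seq_error_rate, rng, truth, week, isotype
            )
            df = pd.DataFrame(
                sorted(observed.items(), key=lambda kv: (-kv[1], kv[0])),
                columns=["sequence", "frequency"],
            )
            df["frequency"] = df["frequency"].astype(int)
            tables[(week, isotype)] = df
    return tables, truth


def simulate_denoise_table(
    n_true: int = 20,
    length: int = 300,
    freq_range: tuple[int, int] = (50, 5000),
    error_rate: float = 0.003,
    min_separation: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """A single error-contaminated table with well-separated true sequences.

    True sequences are pairwise Hamming >= ``min_separation`` apart so that
    the cleanup's integration radius can never bridge two of them; the
    returned truth maps each true sequence to its total (clean + errored)
    read count.  This is the denoiser's dedicated oracle fixture.
    """
    rng = np.random.default_rng(seed)
    true_seqs: list[str] = []
    while len(true_seqs) < n_true:
        cand = "".join(rng.choice(list(_BASES), size=length))
        if all(_hamming(cand, s) >= min_separation for s in true_seqs):
            true_seqs.append(cand)
    counts = {
        s: int(rng.integers(freq_range[0], freq_range[1] + 1))
        for s in true_seqs
    }
    totals = dict(counts)
    observed = _inject_errors(counts, error_rate, rng)
    df = pd.DataFrame(
        sorted(observed.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["sequence", "frequency"],
    )
    return df, totals


# ---------------------------------------------------------------------------
# fixture emission (plain-text files) and optional FASTQ rendering
# ---------------------------------------------------------------------------

_CONST_SEQ = {
    "IgG2": "GGGGTCTTCGCTGTGGTGCGA"[:21],
    "IgG3": "TTGTGGTTTTGGTGTCTTGGGTTC"[:24],
}


def emit_fixtures(
    config: SimulationConfig,
    outdir: str | Path,
    emit_fastq: bool = False,
    read_length: int = 280,
) -> dict:
    """Write manifest, per-sample tables, germline FASTA and truth JSON.

    With ``emit_fastq`` each observed read copy is rendered as a mate pair:
    the template is the sequence plus its isotype's constant-region tail,
    R1/R2 are the template's first/last ``read_length`` bases (R2 reverse
    complemented) at uniform Q30.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    db = simulate_germline_db(config, rng)
    tables, truth = simulate_repertoire(config, db)

    db.to_fasta(outdir / "IGHV.fasta", outdir / "IGHJ.fasta")
    manifest = []
    comp = str.maketrans("ACGT", "TGCA")
    for (week, isotype), df in sorted(tables.items()):
        stem = f"w{week}_{isotype}"
        df.to_csv(outdir / f"{stem}.tsv", sep="\t", index=False)
        entry = {"week": week, "isotype": isotype, "table": f"{stem}.tsv"}
        if emit_fastq:
            tail = _CONST_SEQ[isotype]
            with open(outdir / f"{stem}_R1.fastq", "w") as h1, open(
                outdir / f"{stem}_R2.fastq", "w"
            ) as h2:
                rid = 0
                for seq, freq in zip(df["sequence"], df["frequency"]):
                    template = seq + tail
                    r1 = template[:read_length]
                    r2 = template[-read_length:].translate(comp)[::-1]
                    q1 = "?" * len(r1)  # Q30
                    q2 = "?" * len(r2)
                    for _ in range(int(freq)):
                        rid += 1
                        h1.write(f"@{stem}_{rid}/1\n{r1}\n+\n{q1}\n")
                        h2.write(f"@{stem}_{rid}/2\n{r2}\n+\n{q2}\n")
            entry.update(r1=f"{stem}_R1.fastq", r2=f"{stem}_R2.fastq")
        manifest.append(entry)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    truth_payload = {
        "config": asdict(config),
        "lineages": [asdict(l) for l in truth.lineages],
        "seq_lineage": truth.seq_lineage,
        "n_error_children": len(truth.error_children),
    }
    (outdir / "truth.json").write_text(json.dumps(truth_payload))
    return {"manifest": manifest, "n_lineages": len(truth.lineages)}


# ---------------------------------------------------------------------------
# ground-truth label recovery
# ---------------------------------------------------------------------------

def majority_lineage(cluster, truth: GroundTruth) -> int | None:
    """Lineage contributing the most of a cluster's unique sequences."""
    votes: dict[int, int] = {}
    for s in cluster.sequences:
        lid = truth.seq_lineage.get(s)
        if lid is None:  # error child: attribute through its parent if known
            continue
        votes[lid] = votes.get(lid, 0) + 1
    if not votes:
        return None
    return max(sorted(votes), key=lambda k: votes[k])


def evaluate_predictions(
    kept_clusters,
    discarded_clusters,
    predictions: pd.DataFrame,
    truth: GroundTruth,
) -> dict:
    """Compare hit calls against simulator labels.

    A responding/static lineage is called a hit when any cluster whose
    majority lineage it is was predicted a hit; a lineage with no surviving
    cluster is called a miss.  Returns sensitivity, specificity, balanced
    accuracy and preimmune-discard accounting.
    """
    pred_by_cluster = dict(
        zip(predictions["cluster_id"], predictions["predicted_hit"])
    )
    lineage_hit: dict[int, bool] = {}
    kept_labels = []
    for cl in kept_clusters:
        lid = majority_lineage(cl, truth)
        if lid is None:
            continue
        kept_labels.append(truth.label_of(lid))
        hit = bool(pred_by_cluster.get(cl.cluster_id, False))
        lineage_hit[lid] = lineage_hit.get(lid, False) or hit

    responding = [
        l.lineage_id for l in truth.lineages if l.label == "responding"
    ]
    static = [l.lineage_id for l in truth.lineages if l.label == "static"]
    sens = (
        float(np.mean([lineage_hit.get(l, False) for l in responding]))
        if responding
        else float("nan")
    )
    spec = (
        float(np.mean([not lineage_hit.get(l, False) for l in static]))
        if static
        else float("nan")
    )
    n_pre_discarded = sum(
        1
        for cl in discarded_clusters
        if (lid := majority_lineage(cl, truth)) is not None
        and truth.label_of(lid) == "preimmune"
    )
    preimmune_survivors = sum(1 for lab in kept_labels if lab == "preimmune")
    return {
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": (sens + spec) / 2.0,
        "n_preimmune_clusters_discarded": n_pre_discarded,
        "n_preimmune_clusters_surviving": preimmune_survivors,
    }
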