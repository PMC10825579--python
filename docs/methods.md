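# Methods

## Model and assumptions

The pipeline treats an antibody repertoire time course as a collection of
clonal lineages evolving under antigen selection. Its central assumptions:

* A lineage responding de novo to the immunized antigen starts close to its
  germline V gene (high V-region bit score), accumulates nonsynonymous
  mutations over weeks (falling bit score), and shows *sequence turnover*:
  the weekly dominant clone keeps being displaced by newly appeared clones.
* A lineage that matured before the experiment (responding to earlier
  antigens or adjuvant) enters already far from germline (low bit score),
  stays put (flat slope), and keeps a stable dominant clone.
* Members of one lineage conserve sequence length (substitution-dominated
  hypermutation), so grouping by exact length plus V/J assignment is a safe
  pre-partition, and Jukes–Cantor (JC69) distances can be computed from
  positional mismatches without alignment.

Prediction is the conjunction of three criteria on each cluster: negative
bit-score slope, initial bit score (OLS intercept at week 0) above a
threshold, and turnover (positive Spearman correlation between week and the
weekly dominant's first-appearance week, with at least three distinct
dominants). A cluster observed in a single week has an undefined slope and
fails by convention.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| quality limit | 0.01 | modified-Mott error-probability threshold per base |
| merge costs | mismatch 2, gap 3, min score 8 | overlap-merging score: matches − 2·mismatches − 3·gaps ≥ 8 |
| constant tail | 21 nt (IgG2) / 24 nt (IgG3) | 3′ constant-region bases removed after merging |
| integration radius *n* | 3 / 4 / 5 | for RS frequency 2–400 / 401–1000 / >1000 |
| independence ratio *r* | 8% / 3% / 1% / 0.2% | for 1 / 2 / 3 / ≥4 base changes vs the RS |
| U40 filter | < 10 excluded | neighbours of equal length within 40 bp |
| group / cluster minimum | 8 unique sequences | smaller groups and components are dropped |
| distance threshold | 0.04 (JC69) | edges kept at d ≤ 0.04 (boundary inclusive) |
| intercept threshold | 380 bits | criterion (2), on the default scoring scale |
| nucleotide scoring | +2/−3, gap 5/2, λ=0.625, K=0.41 | Smith–Waterman and Karlin–Altschul constants |

The alignment constants are the conventional ones for the +2/−3 scheme. All
absolute bit-score thresholds are calibration-dependent: with a different
scoring scheme the 380-bit cut must be rescaled (it is exposed as
`intercept_threshold`, and a data-driven midpoint between labelled hit and
miss clusters can replace it when labels exist).

The mutation/bit-score calibration uses cumulative mutation trajectories:
each replicate draws codon positions without replacement and scores the
same trajectory at every mutation count. Pairing the samples across counts
removes the between-draw noise that independent sampling per count would
add, so the mean curve is cleanly monotone at modest replicate numbers.
One amino-acid mutation is a codon replacement to a random codon of a
different amino acid (1–3 nucleotide changes, ≈1.9 expected), giving ≈9
bits per mutation under the default scoring — consistent with reading
5/10/15/20 mutations at roughly 500/450/400/350 bits.

## What the simulator emulates — and what it does not

`simulate_repertoire` draws lineages of three kinds. *Responding* lineages
start 0–2 amino-acid mutations from germline, appear in week 1–2, gain
`mutation_rate` (default 1.0) nonsynonymous mutations per week along a
dominant-clone chain, replace their dominant with probability
`turnover_prob` (default 0.6) per week, and emit minor satellite clones.
*Static* lineages start with `pre_maturation` (default 25) amino-acid
mutations, keep a fixed founder-dominated clone set whose minor satellites
drift in and out of detectability. *Preimmune* lineages are static lineages
already present at week 0. Mutations are biased into three CDR-like codon
windows. Counts are multinomial at `depth` reads per (week, isotype)
sample; a lineage is expressed in both isotypes with probability 0.5.

Sequencing noise is injected per read copy: a copy is an errored copy with
probability `seq_error_rate` (default 0.3%), carrying 1–3 substitutions
(85/12/3%). This per-copy model, rather than a per-base error rate, keeps
every error child within the cleanup's integration radius and far below the
independence ratio of its parent, which is what makes exact-recovery
testing of the denoiser well-posed; it emulates the residual error load
after upstream base-calling and overlap-consensus correction rather than
raw per-base miscall rates.

Features of real data the simulator does **not** model: indels (evolution
is substitution-only, matching the length-conserving group assumption),
chimeric reads, PCR amplification bias, primer artifacts, depth variation
across samples, and biophysical selection (affinity is not modelled — the
"responding" label is purely behavioural). Passing tests therefore show
that the implementation detects the behavioural signature it targets, not
that the signature is complete for any particular real repertoire.

## Numerical choices

* **Determinism.** Every tie is broken explicitly: RS selection by
  lexicographically smallest sequence; sequence IDs by earlier first week
  then sequence; overlap merging prefers longer overlaps at equal score and
  the forward base at equal quality; cluster IDs by earlier peak week then
  smallest member ID; V/J assignment by gene ID order. Reruns are
  byte-identical.
* **Derivative rule.** A member of the integration set is a derivative when
  its diff pattern (positions + bases vs the RS) is a superset of an
  independent member's pattern. The exact-equality reading is vacuous — a
  diff pattern determines the sequence, and table sequences are unique — so
  the `derivative_mode="exact"` flag exists only to expose that
  alternative.
* **Threshold comparisons.** Independence is strict (ratio > r); the
  cluster edge is inclusive (d ≤ 0.04); U40 counts distances 1–39.
* **Degenerate inputs.** Empty tables pass through; saturated JC69
  (p ≥ 0.75) distances become +∞ (never an edge); clusters with fewer than
  three sequences get star trees; queries below a raw-score floor (20) are
  left unassigned and excluded downstream.
* **"Distance values surpassing the threshold set to zero"** is implemented
  as edge deletion in the threshold graph — the zeroing in the original
  recipe encodes disconnection for its component extractor, and literal
  zeroing would instead merge distant sequences.
* **Regression** is unweighted, one point per member row (IgG2 and IgG3
  rows of the same nucleotide sequence are separate points); a
  frequency-weighted variant exists for sensitivity analysis.
* **Percentage appearance** sums the per-isotype percentages (ceiling
  200%); a pooled mode (ceiling 100%) is available.

## Problem sizes used in tests and the acceptance script

The test suite validates components against independent oracles (brute
force, closed forms, transitive closure, an O(nm) Gotoh DP) at small sizes,
and runs 20 full-scale simulated time courses (15+15+5 lineages, 15 weeks,
depth 10,000 per sample) for end-to-end label recovery.
`scripts/acceptance.py` uses 6 such time courses, 30 denoiser simulations
and 200 conservation tables; these sizes give stable estimates (lineage
outcomes are pooled across seeds) while keeping a single run well under an
hour on one core.

## Known limitations

* Absolute bit scores are meaningful only relative to the configured
  scoring; cross-study comparison requires the same constants.
* The turnover criterion needs the cluster observed in ≥3 weeks; sparse
  sampling schedules (e.g. 4 time points) weaken it and the package
  reports the raw dominant timeline so users can apply their own rule.
* Indel-bearing lineages change length and are split across groups; an MSA
  pre-step would be needed to recover them (out of scope here).
* The denoiser is frequency-only (no quality or UMI information) and will
  absorb a genuine variant rarer than the independence ratio of a
  same-length neighbour within the integration radius.
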