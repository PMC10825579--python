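# vhhtrack

Tracks the evolution of a camelid heavy-chain antibody (VHH) repertoire
across an immunization time course and predicts — purely in silico — which
sequence clusters contain antigen-responsive antibodies.

## Who this is for

Groups that immunize camelids and sequence the VHH repertoire (per week, per
isotype: IgG2 short-hinge and IgG3 long-hinge amplicons) and want candidate
binders without phage display or other wet-lab screening. The method finds
lineages that behave like a de novo immune response: they start near a
germline V gene, accumulate somatic hypermutation week after week, and keep
replacing their dominant clone with newly arisen ones.

## The method

1. **Read processing** — mate pairs are quality-trimmed (modified-Mott,
   limit 0.01), merged across their overlap (match +1, mismatch −2, gap −3,
   minimum score 8), stripped of the 3′ constant-region tail (21 nt IgG2 /
   24 nt IgG3), and filtered to unambiguous, in-frame, stop-free sequences.
   Each sample becomes a *sequence–frequency table* of unique sequences and
   read counts.
2. **Error cleanup** — iterative frequency integration. The most frequent
   sequence (the reference sequence, RS) absorbs equal-length neighbours
   within a Hamming radius *n* that widens with RS frequency (*n* = 3 for
   2–400, 4 for 401–1000, 5 above 1000). A neighbour whose frequency ratio
   to the RS exceeds *r* (8%, 3%, 1%, 0.2% for 1, 2, 3, ≥4 changes) is an
   independent variant and is spared, along with its derivatives; everyone
   else is summed into the RS. Repeats until the top frequency is 1. Total
   reads are conserved exactly.
3. **Chronology** — per-isotype full join across weeks, with a
   maximum-frequency column and IDs S1, S2, … (IgG2) / L1, L2, … (IgG3) in
   descending maximum frequency.
4. **Germline assignment** — Smith–Waterman (match +2, mismatch −3, gap
   open 5 / extend 2) against an IGHV/IGHJ FASTA; the best hit per class is
   the origin, reported as the bit score (λ·raw − ln K)/ln 2 with λ = 0.625,
   K = 0.41. Lower V bit score = more somatic mutation.
5. **Clustering** — rows with maximum frequency 1 (unless protected) and
   "lonely" rows (U40 < 10, where U40 counts equal-length sequences within
   40 bp) are dropped; the rest are grouped by (length, V, J), and connected
   components at Jukes–Cantor distance ≤ 0.04 with more than seven unique
   sequences become clusters. Clusters containing any week-0 sequence are
   discarded as pre-immune. Neighbor-joining trees are written per cluster.
6. **Prediction** — each cluster's members are plotted as (week of first
   appearance, V bit score); an OLS line gives the mutation-accumulation
   slope and the *initial bit score* (intercept at week 0). A cluster is
   called a **hit** when the slope is negative, the intercept exceeds 380
   bits, and the weekly dominant clone keeps turning over (positive Spearman
   rank correlation between week and the dominant's first-appearance week,
   with ≥3 distinct dominants).

A built-in simulator (`vhhtrack.simulate`) generates complete time courses
with known ground truth — responding, static (pre-matured), and pre-immune
lineages — so every stage can be validated without sequencing data.

## Worked example

```python
import vhhtrack as v

cfg = v.SimulationConfig(seed=3)                      # 15 weeks, 35 lineages
db = v.simulate.simulate_germline_db(cfg)
tables, truth = v.simulate.simulate_repertoire(cfg, db)
res = v.analyze_tables(tables, db)

print(len(res.clusters), "clusters,", len(res.discarded), "discarded as pre-immune")
print(res.predictions.head(4)[["cluster_id", "slope", "intercept",
                               "n_dominants", "predicted_hit"]])
```

prints

```
30 clusters, 5 discarded as pre-immune
  cluster_id     slope   intercept  n_dominants  predicted_hit
0        C-1 -1.958832  323.809486            1          False
1        C-2  4.021512  334.819364            1          False
2        C-3 -1.893537  333.286500            1          False
3        C-4 -7.877353  548.070367           12           True
```

C-4 is a responding lineage: bit score falling ~7.9 bits/week from an
initial 548 bits (germline-like), with 12 distinct weekly dominants. C-1 to
C-3 are pre-matured bystander lineages — intercepts around 320–335 bits
(≈25 amino-acid mutations at the ~9 bits/mutation calibration), no
turnover — and are correctly rejected.

The same pipeline runs from the shell over FASTQ/FASTA/TSV inputs:

```sh
vhhtrack simulate --config sim.json --out fixtures/
vhhtrack run --config pipeline.json      # merge → … → predictions.tsv
```

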