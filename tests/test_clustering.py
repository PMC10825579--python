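"""Cluster isolation: U40, prefilters, JC69 graph components, NJ trees."""

import math

import numpy as np
import pandas as pd
import pytest

from vhhtrack.chronology import build_isotype_table, stack_isotypes
from vhhtrack.clustering import (
    Cluster,
    assign_cluster_ids,
    build_nj_tree,
    discard_preimmune,
    group_sequences,
    isolate_clusters,
    jc69_distance,
    pairwise_jc69,
    prefilter,
    u40_counts,
)


def _mutant(seq, positions, base_map="ACGT"):
    chars = list(seq)
    for p in positions:
        chars[p] = base_map[(base_map.index(chars[p]) + 1) % 4]
    return "".join(chars)


def _ct_from(seq_freqs, isotype="IgG2", weeks=(0, 1)):
    tables = {
        w: pd.DataFrame(
            {
                "sequence": list(seq_freqs),
                "frequency": [f[i] for f in seq_freqs.values()],
            }
        )
        for i, w in enumerate(weeks)
    }
    for w in list(tables):
        t = tables[w]
        tables[w] = t[t["frequency"] > 0].reset_index(drop=True)
    return build_isotype_table(tables, isotype)


class TestU40:
    def test_lone_reference_counts_zero(self):
        ct = _ct_from({"A" * 60: (3, 4)})
        assert u40_counts(ct).tolist() == [0]

    def test_distance_boundaries_respected(self):
        ref = "A" * 120
        near = _mutant(ref, range(1))       # d = 1 -> counts
        edge = _mutant(ref, range(39))      # d = 39 -> counts
        far = _mutant(ref, range(40))       # d = 40 -> excluded
        ct = _ct_from({ref: (5, 5), near: (2, 2), edge: (1, 1), far: (9, 9)})
        vals = dict(zip(ct["sequence"], u40_counts(ct)))
        assert vals[ref] == 2

    def test_matches_all_pairs_hamming_oracle(self, rng):
        seqs = set()
        founders = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(4)]
        while len(seqs) < 80:
            f = founders[rng.integers(4)]
            k = int(rng.integers(0, 50))
            seqs.add(_mutant(f, rng.choice(60, size=k, replace=False)))
        seqs = sorted(seqs)
        ct = _ct_from({s: (1, 2) for s in seqs})
        got = dict(zip(ct["sequence"], u40_counts(ct)))
        for s in seqs:
            expected = sum(
                1
                for t in seqs
                if t != s
                and len(t) == len(s)
                and 1 <= sum(a != b for a, b in zip(s, t)) < 40
            )
            assert got[s] == expected


class TestPrefilter:
    def test_minor_unprotected_rows_dropped(self):
        ref = "A" * 60
        ct = _ct_from({ref: (1, 0), _mutant(ref, [3]): (5, 5)})
        out, att = prefilter(ct, min_u40=0)
        assert ref not in set(out["sequence"])
        assert att["dropped_max_freq_1"] == 1
        assert att["input"] == att["kept"] + att["dropped_max_freq_1"] + att["dropped_low_u40"]

    def test_protected_phage_display_clone_survives(self):
        ref = "A" * 60
        ct = _ct_from({ref: (1, 0), _mutant(ref, [3]): (5, 5)})
        out, _ = prefilter(ct, protected={ref}, min_u40=0)
        assert ref in set(out["sequence"])

    def test_u40_boundary_at_ten(self):
        base = "C" * 90
        crowd = {base: (4, 4)}
        for i in range(10):
            crowd[_mutant(base, [i])] = (3, 3)
        lonely = "T" * 90  # 90 diffs from the crowd: U40 = 0
        crowd[lonely] = (7, 7)
        ct = _ct_from(crowd)
        out, att = prefilter(ct, min_u40=10)
        kept = set(out["sequence"])
        assert lonely not in kept          # U40 0 < 10
        assert base in kept                # U40 10 passes
        assert att["dropped_low_u40"] == 1


class TestGrouping:
    def _germ(self, ct, v="V1", j="J1"):
        return pd.DataFrame(
            {
                "sequence_id": ct["sequence_id"],
                "v_gene": v,
                "j_gene": j,
                "v_bitscore": 500.0,
                "j_bitscore": 90.0,
            }
        )

    def test_group_size_boundary(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=60))
        seqs7 = {base: (2, 2)}
        for i in range(6):
            seqs7[_mutant(base, [i])] = (2, 2)
        ct7 = _ct_from(seqs7)
        assert group_sequences(ct7, self._germ(ct7)) == {}

        seqs8 = dict(seqs7)
        seqs8[_mutant(base, [10])] = (2, 2)
        ct8 = _ct_from(seqs8)
        groups = group_sequences(ct8, self._germ(ct8))
        assert list(groups) == [(60, "V1", "J1")]

    def test_mixed_lengths_split_groups(self, rng):
        short = {"".join(rng.choice(list("ACGT"), size=30)): (2, 2) for _ in range(9)}
        while len(short) < 8:
            short["".join(rng.choice(list("ACGT"), size=30))] = (2, 2)
        long_ = {s + "ACG": f for s, f in short.items()}
        ct = stack_isotypes(
            _ct_from(short, "IgG2"), _ct_from(long_, "IgG3")
        )
        groups = group_sequences(ct, self._germ(ct))
        assert set(groups) == {(30, "V1", "J1"), (33, "V1", "J1")}


class TestJC69:
    def test_zero_iff_identical(self):
        assert jc69_distance("ACGT", "ACGT") == 0.0
        assert jc69_distance("ACGT", "ACGA") > 0.0

    def test_closed_form_value(self):
        # 3 diffs over 300 nt: p = 0.01
        a = "A" * 300
        b = _mutant(a, [0, 1, 2])
        expected = -0.75 * math.log(1 - 4 * 0.01 / 3)
        assert jc69_distance(a, b) == pytest.approx(expected, abs=1e-9)

    def test_saturation_returns_infinity(self):
        assert jc69_distance("AAAA", "CCCC") == math.inf

    def test_strictly_increasing_in_hamming_distance(self):
        a = "A" * 100
        prev = -1.0
        for k in range(0, 60, 5):
            d = jc69_distance(a, _mutant(a, range(k)))
            assert d > prev
            prev = d

    def test_symmetric_matrix(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(6)]
        dm = pairwise_jc69(seqs)
        assert np.allclose(dm, dm.T)
        assert np.all(np.diag(dm) == 0)


class TestIsolateClusters:
    def _group_df(self, seqs):
        return pd.DataFrame(
            {
                "sequence_id": [f"S{i+1}" for i in range(len(seqs))],
                "sequence": seqs,
                "isotype": "IgG2",
            }
        )

    def test_chain_connects_transitively(self):
        # adjacent pairs ~0.03 apart, chain ends far beyond the threshold
        base = "A" * 300
        seqs = [base]
        for i in range(7):
            seqs.append(_mutant(seqs[-1], range(9 * i, 9 * (i + 1))))
        assert jc69_distance(seqs[0], seqs[-1]) > 0.2
        clusters = isolate_clusters(self._group_df(seqs), (300, "V1", "J1"))
        assert len(clusters) == 1 and clusters[0].size == 8

    def test_two_distant_cliques_split(self):
        a = "A" * 300
        b = _mutant(a, range(60))
        seqs = [_mutant(a, [i]) for i in range(8)] + [
            _mutant(b, [100 + i]) for i in range(8)
        ]
        clusters = isolate_clusters(self._group_df(seqs), (300, "V1", "J1"))
        assert len(clusters) == 2
        assert sorted(c.size for c in clusters) == [8, 8]

    def test_component_of_seven_is_discarded(self):
        a = "C" * 300
        seqs = [_mutant(a, [i]) for i in range(7)]
        assert isolate_clusters(self._group_df(seqs), (300, "V1", "J1")) == []

    def test_threshold_boundary_is_inclusive(self):
        # 333 nt, 12 diffs -> d = 0.0369 <= 0.04 edge; 13 diffs -> 0.0401 no edge
        a = "A" * 333
        near = _mutant(a, range(12))
        far = _mutant(a, range(13))
        assert jc69_distance(a, near) <= 0.04 < jc69_distance(a, far)


class TestDiscardAndIds:
    def _setup(self):
        base = "G" * 60
        crowd = {}
        for i in range(9):
            crowd[_mutant(base, [i])] = (0, 3)
        ct = _ct_from(crowd, weeks=(0, 1))
        cl = Cluster(None, (60, "V1", "J1"), sorted(crowd),
                     sorted(ct["sequence_id"]))
        return ct, cl

    def test_week0_member_condemns_cluster(self):
        ct, cl = self._setup()
        ct.loc[0, "freq_0"] = 3  # one member seen pre-immunization
        kept, dropped = discard_preimmune([cl], ct)
        assert kept == [] and dropped == [cl]
        assert cl.contains_preimmune

    def test_clean_cluster_is_kept(self):
        ct, cl = self._setup()
        kept, dropped = discard_preimmune([cl], ct)
        assert kept == [cl] and dropped == []

    def test_ids_rank_by_peak_weekly_total(self):
        ct, cl = self._setup()
        small = Cluster(None, (60, "V1", "J1"),
                        [ct.loc[0, "sequence"]], [ct.loc[0, "sequence_id"]])
        big = Cluster(None, (60, "V1", "J1"),
                      sorted(ct["sequence"]), sorted(ct["sequence_id"]))
        ordered = assign_cluster_ids([small, big], ct, prefix="Ig")
        assert ordered[0] is big and big.cluster_id == "Ig-1"
        assert small.cluster_id == "Ig-2"
        assert big.weekly_totals[1] == 27

    def test_added_singleton_never_changes_clusters(self, rng):
        """A brand-new unprotected max-frequency-1 row is filtered out."""
        base = "".join(rng.choice(list("ACGT"), size=60))
        crowd = {_mutant(base, [i]): (0, 3) for i in range(12)}
        ct1 = _ct_from(crowd)
        crowd2 = dict(crowd)
        crowd2["T" * 60] = (0, 1)
        ct2 = _ct_from(crowd2)
        out1, _ = prefilter(ct1, min_u40=10)
        out2, _ = prefilter(ct2, min_u40=10)
        assert sorted(out1["sequence"]) == sorted(out2["sequence"])


class TestNJTree:
    def test_three_equidistant_taxa(self):
        a = "A" * 90
        cl = Cluster(None, (90, "V", "J"),
                     [a, _mutant(a, [0]), _mutant(a, [1])],
                     ["S1", "S2", "S3"],
                     seq_ids={a: ["S1"], _mutant(a, [0]): ["S2"],
                              _mutant(a, [1]): ["S3"]})
        nwk = build_nj_tree(cl)
        assert nwk.endswith(";")
        for tip in ("S1", "S2", "S3"):
            assert tip in nwk

    def test_nj_recovers_additive_quartet_topology(self):
        """On additive distances NJ splits the true cherry pairs."""
        import io
        from skbio import TreeNode

        a = "A" * 300
        # quartet ((s1,s2),(s3,s4)): within-pair distance small, across large
        s1 = a
        s2 = _mutant(a, [0])
        s3 = _mutant(a, range(50, 80))
        s4 = _mutant(a, list(range(50, 80)) + [99])
        seqs = [s1, s2, s3, s4]
        cl = Cluster(None, (300, "V", "J"), seqs,
                     [f"S{i+1}" for i in range(4)],
                     seq_ids={s: [f"S{i+1}"] for i, s in enumerate(seqs)})
        tree = TreeNode.read(io.StringIO(build_nj_tree(cl)))
        # in the unrooted quartet, s1-s2 tip-to-tip path avoids s3/s4 branches
        d12 = tree.find("S1").distance(tree.find("S2"))
        d13 = tree.find("S1").distance(tree.find("S3"))
        assert d12 < d13
        assert {t.name for t in tree.tips()} == {"S1", "S2", "S3", "S4"}

    def test_star_tree_below_three_members(self):
        a = "T" * 30
        cl = Cluster(None, (30, "V", "J"), [a, _mutant(a, [0])], ["S1", "S2"],
                     seq_ids={a: ["S1"], _mutant(a, [0]): ["S2"]})
        assert build_nj_tree(cl) == "(S1,S2);"
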