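"""Trajectory construction, regression, turnover, percentage appearance."""

import numpy as np
import pandas as pd
import pytest

from vhhtrack.chronology import build_isotype_table, stack_isotypes
from vhhtrack.clustering import Cluster
from vhhtrack.predict import (
    fit_bitscore_line,
    max_percentage_appearance,
    percentage_appearance,
    predict_hits,
    trajectory,
    turnover_index,
)


def _ct(seq_week_freqs, isotype="IgG2", weeks=(0, 1, 2, 3)):
    tables = {}
    for i, w in enumerate(weeks):
        rows = {
            s: fs[i] for s, fs in seq_week_freqs.items() if fs[i] > 0
        }
        tables[w] = pd.DataFrame(
            {"sequence": list(rows), "frequency": list(rows.values())}
        )
    return build_isotype_table(tables, isotype)


def _cluster_for(ct, seqs=None):
    rows = ct if seqs is None else ct[ct["sequence"].isin(seqs)]
    return Cluster(
        "C-1",
        (len(ct.loc[0, "sequence"]), "V1", "J1"),
        sorted(rows["sequence"].unique()),
        sorted(rows["sequence_id"]),
    )


def _germ(ct, scores):
    return pd.DataFrame(
        {
            "sequence_id": ct["sequence_id"],
            "v_gene": "V1",
            "j_gene": "J1",
            "v_bitscore": [scores[s] for s in ct["sequence"]],
            "j_bitscore": 90.0,
        }
    )


class TestTrajectory:
    def test_first_week_is_earliest_nonzero(self):
        ct = _ct({"AAA": (0, 0, 4, 6), "CCC": (0, 2, 2, 2)})
        germ = _germ(ct, {"AAA": 500.0, "CCC": 480.0})
        pts = trajectory(_cluster_for(ct), ct, germ)
        first = dict(zip(
            ct.set_index("sequence_id").loc[pts["sequence_id"], "sequence"],
            pts["first_week"],
        ))
        assert first == {"AAA": 2, "CCC": 1}

    def test_sequence_in_both_isotypes_yields_two_points(self):
        g2 = _ct({"AAA": (0, 3, 3, 3)}, "IgG2")
        g3 = _ct({"AAA": (0, 0, 5, 5)}, "IgG3")
        ct = stack_isotypes(g2, g3)
        germ = _germ(ct, {"AAA": 500.0})
        cl = Cluster("C-1", (3, "V1", "J1"), ["AAA"],
                     sorted(ct["sequence_id"]))
        pts = trajectory(cl, ct, germ)
        assert len(pts) == 2
        assert set(pts["isotype"]) == {"IgG2", "IgG3"}
        assert set(pts["first_week"]) == {1, 2}

    def test_weekly_shares_sum_to_one_across_isotype(self):
        ct = _ct({"AAA": (0, 3, 1, 0), "CCC": (0, 1, 3, 4)})
        germ = _germ(ct, {"AAA": 500.0, "CCC": 480.0})
        pts = trajectory(_cluster_for(ct), ct, germ)
        for w in (1, 2, 3):
            assert pts[f"share_{w}"].sum() == pytest.approx(1.0)


class TestFitLine:
    def test_collinear_points_recovered_exactly(self):
        pts = pd.DataFrame(
            {"first_week": [0, 5, 10], "v_bitscore": [500.0, 450.0, 400.0]}
        )
        slope, intercept = fit_bitscore_line(pts)
        assert slope == pytest.approx(-10.0, abs=1e-12)
        assert intercept == pytest.approx(500.0, abs=1e-9)

    def test_matches_normal_equation_oracle(self, rng):
        for _ in range(30):
            x = rng.integers(0, 15, size=12).astype(float)
            if len(np.unique(x)) < 2:
                continue
            y = rng.normal(400, 60, size=12)
            pts = pd.DataFrame({"first_week": x, "v_bitscore": y})
            slope, intercept = fit_bitscore_line(pts)
            X = np.column_stack([x, np.ones_like(x)])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert slope == pytest.approx(beta[0], abs=1e-9)
            assert intercept == pytest.approx(beta[1], abs=1e-9)

    def test_single_week_cluster_is_flagged_undefined(self):
        pts = pd.DataFrame(
            {"first_week": [3, 3, 3], "v_bitscore": [400.0, 410.0, 390.0]}
        )
        slope, intercept = fit_bitscore_line(pts)
        assert np.isnan(slope) and np.isnan(intercept)


class TestTurnover:
    def test_weekly_replacement_gives_perfect_index(self):
        # a new clone dominates each week
        ct = _ct({
            "AAAAAA": (0, 9, 1, 1),
            "CCCCCC": (0, 0, 9, 1),
            "GGGGGG": (0, 0, 0, 9),
        })
        idx, n_dom, ok = turnover_index(_cluster_for(ct), ct)
        assert idx == pytest.approx(1.0)
        assert n_dom == 3 and ok

    def test_static_dominant_fails(self):
        ct = _ct({
            "AAAAAA": (0, 9, 9, 9),
            "CCCCCC": (0, 2, 2, 2),
        })
        idx, n_dom, ok = turnover_index(_cluster_for(ct), ct)
        assert n_dom == 1 and not ok

    def test_cluster_present_under_three_weeks_fails(self):
        ct = _ct({"AAAAAA": (0, 9, 0, 0), "CCCCCC": (0, 2, 0, 0)})
        _, _, ok = turnover_index(_cluster_for(ct), ct)
        assert not ok


class TestPercentageAppearance:
    def _two_isotype_ct(self):
        g2 = _ct({"AAA": (0, 8, 0, 0), "CCC": (0, 2, 10, 10)}, "IgG2")
        g3 = _ct({"TTT": (0, 5, 5, 5)}, "IgG3")
        return stack_isotypes(g2, g3)

    def test_sum_mode_can_reach_two_hundred(self):
        ct = self._two_isotype_ct()
        cl = Cluster("C-1", (3, "V", "J"), ["AAA", "CCC", "TTT"],
                     sorted(ct["sequence_id"]))
        # week 1: cluster holds all IgG2 and all IgG3 reads
        assert percentage_appearance(cl, ct, 1) == pytest.approx(200.0)
        assert percentage_appearance(cl, ct, 1, mode="pooled") == pytest.approx(100.0)

    def test_absent_week_contributes_zero(self):
        ct = self._two_isotype_ct()
        cl = Cluster("C-1", (3, "V", "J"), ["AAA"],
                     sorted(ct.loc[ct["sequence"] == "AAA", "sequence_id"]))
        assert percentage_appearance(cl, ct, 2) == 0.0

    def test_max_over_post_immunization_weeks(self):
        ct = self._two_isotype_ct()
        cl = Cluster("C-1", (3, "V", "J"), ["AAA"],
                     sorted(ct.loc[ct["sequence"] == "AAA", "sequence_id"]))
        # week1 share: 8/10 IgG2 = 80%; weeks 2,3: 0
        assert max_percentage_appearance(cl, ct) == pytest.approx(80.0)


class TestPredictHits:
    def _prediction_for(self, scores_by_week, turnover=True):
        """Build a 3-member cluster whose bit scores follow scores_by_week."""
        seqs = ["AAAAAA", "CCCCCC", "GGGGGG"]
        if turnover:
            freqs = {
                seqs[0]: (0, 9, 1, 1),
                seqs[1]: (0, 0, 9, 1),
                seqs[2]: (0, 0, 0, 9),
            }
        else:
            freqs = {
                seqs[0]: (0, 9, 9, 9),
                seqs[1]: (0, 1, 1, 1),
                seqs[2]: (0, 0, 1, 1),
            }
        ct = _ct(freqs)
        germ = _germ(ct, dict(zip(seqs, scores_by_week)))
        cl = _cluster_for(ct)
        return predict_hits([cl], ct, germ).iloc[0]

    def test_responding_profile_is_called_hit(self):
        row = self._prediction_for([470.0, 450.0, 430.0], turnover=True)
        assert row["slope"] < 0
        assert row["intercept"] > 380
        assert bool(row["predicted_hit"])

    def test_positive_slope_low_intercept_is_miss(self):
        row = self._prediction_for([310.0, 320.0, 330.0], turnover=False)
        assert row["slope"] > 0 and not bool(row["predicted_hit"])

    def test_criterion_conjunction_requires_intercept(self):
        # negative slope and turnover, but starts far from germline
        row = self._prediction_for([360.0, 350.0, 340.0], turnover=True)
        assert row["slope"] < 0 and bool(row["turnover_pass"])
        assert not bool(row["predicted_hit"])

    def test_invariant_to_uniform_depth_scaling(self):
        seqs = ["AAAAAA", "CCCCCC", "GGGGGG"]
        freqs = {
            seqs[0]: (0, 9, 1, 1),
            seqs[1]: (0, 0, 9, 1),
            seqs[2]: (0, 0, 0, 9),
        }
        scaled = {s: tuple(10 * f for f in fs) for s, fs in freqs.items()}
        ct1, ct2 = _ct(freqs), _ct(scaled)
        scores = {s: v for s, v in zip(seqs, [470.0, 450.0, 430.0])}
        p1 = predict_hits([_cluster_for(ct1)], ct1, _germ(ct1, scores))
        p2 = predict_hits([_cluster_for(ct2)], ct2, _germ(ct2, scores))
        for col in ("slope", "intercept", "turnover_idx", "max_pct_appearance"):
            assert p1.loc[0, col] == pytest.approx(p2.loc[0, col])
        assert bool(p1.loc[0, "predicted_hit"]) == bool(p2.loc[0, "predicted_hit"])
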