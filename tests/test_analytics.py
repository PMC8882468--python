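import math

import numpy as np
import pandas as pd
import pytest

from grscreen import analytics
from grscreen.analytics import ClinicalCourse, ScreenMatrix


def matrix_from(d: dict) -> ScreenMatrix:
    return ScreenMatrix(pd.DataFrame(d).T)  # rows = models


class TestRanking:
    def test_models_sorted_by_graoc(self):
        m = matrix_from({"A": {"d": 1.5}, "B": {"d": 0.2}, "C": {"d": 0.9}})
        order = analytics.rank_models_by_drug(m, "d")
        assert list(order.index) == ["A", "C", "B"]

    def test_ties_break_lexicographically(self):
        m = matrix_from({"B": {"d": 1.0}, "A": {"d": 1.0}, "C": {"d": 1.0}})
        assert list(analytics.rank_models_by_drug(m, "d").index) == ["A", "B", "C"]

    def test_unknown_drug_rejected(self):
        with pytest.raises(KeyError):
            analytics.rank_models_by_drug(matrix_from({"A": {"d": 1.0}}), "nope")

    def test_drug_ranks_within_model(self):
        m = matrix_from({"A": {"d1": 2.0, "d2": 1.0, "d3": 0.0}})
        ranks = analytics.rank_drugs_within_model(m, "A")
        assert ranks.to_dict() == {"d1": 1.0, "d2": 2.0, "d3": 3.0}

    def test_tied_drugs_get_average_rank(self):
        m = matrix_from({"A": {"d1": 1.0, "d2": 1.0, "d3": 0.0}})
        ranks = analytics.rank_drugs_within_model(m, "A")
        assert ranks["d1"] == ranks["d2"] == 1.5

    def test_ranking_is_a_permutation(self):
        rng = np.random.default_rng(0)
        m = matrix_from({f"m{i}": {f"d{j}": rng.normal() for j in range(7)}
                         for i in range(5)})
        ranks = analytics.rank_drugs_within_model(m, "m0")
        assert sorted(ranks) == list(range(1, 8))
        order = analytics.rank_models_by_drug(m, "d0")
        assert sorted(order.index) == sorted(m.graoc.index)


class TestGroupComparison:
    def test_identical_groups_null(self):
        m = matrix_from({"A": {"d": 1.0}, "B": {"d": 2.0},
                         "C": {"d": 1.0}, "D": {"d": 2.0}})
        r = analytics.group_compare_graoc(m, ["A", "B"], ["C", "D"])
        assert r.p_value == pytest.approx(1.0)
        assert r.hl_shift == 0.0

    def test_pooled_values_shift(self):
        m = matrix_from({"A": {"d1": 1.0, "d2": 2.0}, "B": {"d1": 3.0, "d2": 4.0},
                         "C": {"d1": 5.0, "d2": 6.0}, "D": {"d1": 7.0, "d2": 8.0}})
        r = analytics.group_compare_graoc(m, ["A", "B"], ["C", "D"])
        assert r.p_value == pytest.approx(2 / 70)
        assert r.hl_shift == -4.0

    def test_class_rank_compare_extreme(self):
        # class drugs occupy ranks 1-3 in group A models and 10-12 in group B
        rng = np.random.default_rng(1)
        rows = {}
        for grp, base in (("a", 12.0), ("b", 0.0)):
            for i in range(2):
                vals = {f"class{j}": base + 3 - j for j in range(3)}
                vals.update({f"other{j}": 11.0 - j - (base / 12.0) * 10.0
                             for j in range(9)})
                rows[f"{grp}{i}"] = vals
        m = ScreenMatrix(pd.DataFrame(rows).T)
        r = analytics.class_rank_compare(m, [f"class{j}" for j in range(3)],
                                         ["a0", "a1"], ["b0", "b1"])
        assert r.hl_shift == -9.0

    def test_empty_class_rejected(self):
        m = matrix_from({"A": {"d": 1.0}, "B": {"d": 0.0}})
        with pytest.raises(ValueError):
            analytics.class_rank_compare(m, [], ["A"], ["B"])


class TestConcordance:
    def test_perfect_agreement(self):
        rng = np.random.default_rng(2)
        gr50 = 10.0 ** rng.uniform(-2, 1, 12)
        metrics = pd.DataFrame({
            "model_id": [f"m{i % 4}" for i in range(12)],
            "drug_id": [f"d{i // 4}" for i in range(12)],
            "GR50": gr50, "GI50": gr50,
        })
        dt = pd.Series({f"m{i}": 3.0 + i for i in range(4)})
        res = analytics.gr_gi_concordance(metrics, dt)
        assert res.pearson_r == pytest.approx(1.0)
        assert np.allclose(res.residuals["residual"], 0.0, atol=1e-12)

    def test_too_few_pairs_rejected(self):
        metrics = pd.DataFrame({"model_id": ["a", "b"], "drug_id": ["d", "d"],
                                "GR50": [0.1, math.nan], "GI50": [0.1, 0.2]})
        with pytest.raises(ValueError):
            analytics.gr_gi_concordance(metrics, pd.Series({"a": 3.0, "b": 5.0}))


class TestClustering:
    def test_block_matrix_leaves_contiguous(self):
        rng = np.random.default_rng(3)
        block = np.vstack([
            np.hstack([np.full((4, 5), 1.5), np.full((4, 5), 0.1)]),
            np.hstack([np.full((4, 5), 0.1), np.full((4, 5), 1.5)]),
        ]) + rng.normal(0, 0.01, (8, 10))
        models = [f"g1_{i}" for i in range(4)] + [f"g2_{i}" for i in range(4)]
        m = ScreenMatrix(pd.DataFrame(block, index=models,
                                      columns=[f"d{j}" for j in range(10)]))
        res = analytics.cluster_screen(m)
        groups = ["".join(sorted(set(x.split("_")[0] for x in res.row_order[:4]))),
                  "".join(sorted(set(x.split("_")[0] for x in res.row_order[4:])))]
        assert sorted(groups) == ["g1", "g2"]

    def test_single_row_matrix(self):
        m = matrix_from({"A": {"d1": 1.0, "d2": 0.0, "d3": 2.0, "d4": 1.0}})
        res = analytics.cluster_screen(m)
        assert res.row_order == ["A"]

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(4)
        frame = pd.DataFrame(rng.normal(size=(6, 8)),
                             index=[f"m{i}" for i in range(6)],
                             columns=[f"d{j}" for j in range(8)])
        res1 = analytics.cluster_screen(ScreenMatrix(frame))
        shuffled = frame.sample(frac=1.0, random_state=9)
        res2 = analytics.cluster_screen(ScreenMatrix(shuffled))
        assert res1.row_order == res2.row_order
        assert res1.col_order == res2.col_order

    def test_na_rejected(self):
        m = matrix_from({"A": {"d1": 1.0, "d2": math.nan}, "B": {"d1": 0.0, "d2": 1.0}})
        with pytest.raises(ValueError, match="NA"):
            analytics.cluster_screen(m)


class TestReproducibility:
    def test_identical_replicates(self):
        rng = np.random.default_rng(5)
        base = pd.DataFrame({
            "model_id": [f"m{i % 3}" for i in range(9)],
            "drug_id": [f"d{i // 3}" for i in range(9)],
            "GR_aoc": rng.uniform(0, 2, 9),
        })
        reps = pd.concat([base.assign(bio_rep=b) for b in (1, 2, 3)])
        res = analytics.replicate_reproducibility(reps)
        assert np.allclose(res.pairwise_correlations["pearson_r"], 1.0)
        assert np.allclose(res.cv_table["cv"], 0.0)

    def test_single_replicate_rejected(self):
        base = pd.DataFrame({"model_id": ["m"], "drug_id": ["d"],
                             "GR_aoc": [1.0], "bio_rep": [1]})
        with pytest.raises(ValueError):
            analytics.replicate_reproducibility(base)


class TestClinicalBenefit:
    def test_reported_case_ratios(self):
        new = ClinicalCourse("matched", pfs_days=138.0, ttnt_days=197.0)
        prior = ClinicalCourse("prior", pfs_days=41.0, ttnt_days=41.0)
        res = analytics.clinical_benefit_ratio(new, prior)
        assert res["ttnt_ratio"] == 4.8
        assert res["pfs_ratio"] == 3.4
        assert res["meets_benchmark"] is True

    def test_equal_courses_fail_benchmark(self):
        c = ClinicalCourse("x", 41.0, 41.0)
        res = analytics.clinical_benefit_ratio(c, c)
        assert res["pfs_ratio"] == 1.0
        assert res["meets_benchmark"] is False

    def test_invalid_durations(self):
        with pytest.raises(ValueError):
            ClinicalCourse("x", -1.0)
        with pytest.raises(ValueError):
            ClinicalCourse("x", 50.0, 40.0)  # TTNT before PFS
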