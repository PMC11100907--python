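import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from dcistme.cohort import (
    assemble_features,
    association_matrix,
    characterize_clusters,
    combine_biomarkers,
    consensus_cluster,
    dichotomize_median,
    km_logrank,
    pairwise_complete_distances,
    select_k_cdf,
    survival_endpoint,
    wilcoxon_rank_sum,
)
from dcistme.errors import ConfigError, QCWarning, ValidationError
from dcistme.io_model import ClinicalRecord
from dcistme.synthetic import simulate_planted_matrix
from oracles import bh_adjust, logrank_brute


def record(sid, followup, event, **kw):
    base = dict(age=50.0, grade=2, hr="pos", her2="neg", comedo=False,
                palpable=False, path_mass=False)
    base.update(kw)
    return ClinicalRecord(sample_id=sid, followup_time=followup, event=event, **base)


class TestAssemble:
    def test_union_of_sources(self):
        pop = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0], "c": [0.0, 1.0]},
                           index=["S1", "S2"])
        spa = pd.DataFrame({"d": [5.0], "e": [6.0]}, index=["S1"])
        m = assemble_features(pop, spa)
        assert m.shape == (2, 5)
        assert np.isnan(m.loc["S2", "d"])  # absent spatial value stays missing

    def test_duplicate_feature_name_rejected(self):
        a = pd.DataFrame({"f": [1.0]}, index=["S1"])
        with pytest.raises(ValidationError, match="duplicate"):
            assemble_features(a, a)


class TestDichotomize:
    def test_even_split(self):
        g = dichotomize_median(pd.Series([1, 2, 3, 4], dtype=float))
        assert g.tolist() == ["low", "low", "high", "high"]

    def test_ties_go_low(self):
        g = dichotomize_median(pd.Series([5, 5, 5, 9], dtype=float))
        assert g.tolist() == ["low", "low", "low", "high"]

    def test_constant_vector_degenerate(self):
        with pytest.warns(QCWarning, match="degenerate"):
            g = dichotomize_median(pd.Series([2.0, 2.0, 2.0]))
        assert g.tolist() == ["low"] * 3

    def test_missing_preserved_and_all_missing_rejected(self):
        g = dichotomize_median(pd.Series([1.0, np.nan, 3.0]))
        assert pd.isna(g.iloc[1])
        with pytest.raises(ValidationError):
            dichotomize_median(pd.Series([np.nan, np.nan]))


class TestCombine:
    def test_truth_table(self):
        g1 = pd.Series(["low", "low", "high", "high"], index=list("abcd"))
        g2 = pd.Series(["high", "low", "high", "low"], index=list("abcd"))
        out = combine_biomarkers(g1, g2, "low AND high")
        assert out.tolist() == [1, 0, 0, 0]

    def test_low_and_low_on_same_grouping_is_low_group(self):
        g = pd.Series(["low", "high", "low"], index=list("abc"))
        out = combine_biomarkers(g, g, "low AND low")
        assert out.tolist() == [1, 0, 1]

    def test_missing_marker_excludes_sample(self):
        g1 = pd.Series(["low", np.nan], index=list("ab"))
        g2 = pd.Series(["high", "high"], index=list("ab"))
        out = combine_biomarkers(g1, g2, "low AND high")
        assert list(out.index) == ["a"]

    def test_empty_intersection_rejected(self):
        g1 = pd.Series(["low"], index=["a"])
        g2 = pd.Series(["high"], index=["b"])
        with pytest.raises(ValidationError):
            combine_biomarkers(g1, g2)


class TestAssociations:
    def test_extreme_separation_exact_p(self):
        # 3 vs 3 with complete separation: the most extreme of the C(6,3)=20
        # equally likely rank splits in both directions → p = 2/20
        _, p = wilcoxon_rank_sum([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)

    def test_identical_distributions_near_null(self):
        _, p = wilcoxon_rank_sum([1, 2, 3, 4], [1.5, 2.5, 0.5, 3.5])
        assert p > 0.5

    def test_association_matrix_directions_and_tests(self):
        clinical = [
            record(f"S{i}", 5.0, "none",
                   hr="pos" if i < 5 else "neg",
                   grade=(i % 3) + 1)
            for i in range(10)
        ]
        feats = pd.DataFrame(
            {"marker": [10.0 + i if i < 5 else float(i) for i in range(10)]},
            index=[f"S{i}" for i in range(10)],
        )
        out = association_matrix(feats, clinical)
        hr_row = out[(out.clinical_variable == "HR")].iloc[0]
        assert hr_row.test == "wilcoxon"
        assert hr_row.direction == "pos"  # HR-positive samples have higher values
        assert hr_row.p_value < 0.05
        grade_row = out[(out.clinical_variable == "grade")].iloc[0]
        assert grade_row.test == "kruskal_wallis"
        assert 0.0 <= grade_row.p_value <= 1.0

    def test_kruskal_on_identical_groups_is_zero(self):
        from scipy.stats import kruskal

        clinical = [record(f"S{i}", 5.0, "none", grade=(i % 3) + 1) for i in range(9)]
        feats = pd.DataFrame({"flat": [7.0] * 9}, index=[f"S{i}" for i in range(9)])
        out = association_matrix(feats, clinical)
        grade_row = out[out.clinical_variable == "grade"].iloc[0]
        assert grade_row.statistic == 0.0 and grade_row.p_value == 1.0


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        time = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        event = pd.Series([True, True, False] * 2)
        group = pd.Series(["a"] * 3 + ["b"] * 3)
        res = km_logrank(time, event, group)
        assert res.logrank_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_toy_case_matches_risk_table(self):
        ta, ea = [1.0, 2.0, 3.0, 4.0], [True] * 4
        tb, eb = [5.0, 6.0, 7.0, 8.0], [False] * 4
        res = km_logrank(
            pd.Series(ta + tb), pd.Series(ea + eb),
            pd.Series(["A"] * 4 + ["B"] * 4),
        )
        assert res.logrank_statistic == pytest.approx(logrank_brute(ta, ea, tb, eb), abs=1e-9)

    def test_permutation_invariance(self, rng):
        n = 20
        time = pd.Series(rng.exponential(5, n))
        event = pd.Series(rng.uniform(size=n) < 0.6)
        group = pd.Series(np.where(rng.uniform(size=n) < 0.5, "a", "b"))
        res1 = km_logrank(time, event, group)
        perm = rng.permutation(n)
        res2 = km_logrank(time.iloc[perm], event.iloc[perm], group.iloc[perm])
        assert res1.logrank_statistic == pytest.approx(res2.logrank_statistic, abs=1e-12)

    def test_single_group_rejected_and_zero_events_flagged(self):
        time = pd.Series([1.0, 2.0])
        with pytest.raises(ValidationError):
            km_logrank(time, pd.Series([True, True]), pd.Series(["a", "a"]))
        res = km_logrank(
            pd.Series([1.0, 2.0, 3.0, 4.0]),
            pd.Series([False] * 4),
            pd.Series(["a", "a", "b", "b"]),
        )
        assert res.flagged and np.isnan(res.p_value)

    def test_invasive_endpoint_censors_dcis_recurrences(self):
        clinical = [
            record("S1", 2.0, "DCIS"),
            record("S2", 3.0, "invasive"),
            record("S3", 8.0, "none"),
        ]
        any_ep = survival_endpoint(clinical, "any_recurrence")
        inv_ep = survival_endpoint(clinical, "invasive_recurrence")
        assert any_ep["event"].tolist() == [True, True, False]
        assert inv_ep["event"].tolist() == [False, True, False]
        # DCIS recurrence censored at its event time, not at follow-up end
        assert inv_ep.loc["S1", "time"] == 2.0


class TestConsensus:
    def test_matrix_symmetric_unit_diagonal(self):
        X, _ = simulate_planted_matrix((6, 6), 6, 3.0, seed=0)
        res = consensus_cluster(X, k_range=(2, 3), iterations=30, seed=1)
        for k in (2, 3):
            M = res.matrices[k]
            assert np.allclose(M, M.T)
            assert np.allclose(np.diag(M), 1.0)
            assert M.min() >= 0.0 and M.max() <= 1.0

    def test_seed_reproducibility(self):
        X, _ = simulate_planted_matrix((6, 6), 6, 3.0, seed=0)
        a = consensus_cluster(X, k_range=(2, 3), iterations=30, seed=5)
        b = consensus_cluster(X, k_range=(2, 3), iterations=30, seed=5)
        assert np.array_equal(a.matrices[2], b.matrices[2])
        assert a.labels.equals(b.labels)

    def test_two_cluster_recovery(self):
        X, truth = simulate_planted_matrix((15, 15), 10, 6.0, seed=2)
        res = consensus_cluster(X, k_range=(2, 3, 4), iterations=50, seed=2)
        assert adjusted_rand_score(truth, res.labels_per_k[2]) == 1.0

    def test_no_structure_keeps_consensus_diffuse(self):
        X, _ = simulate_planted_matrix((12, 12), 8, 0.0, seed=3)
        res = consensus_cluster(X, k_range=(2,), iterations=100, seed=3)
        off = res.matrices[2][np.triu_indices(len(X), 1)]
        # without structure, pairs co-cluster ambiguously rather than crisply
        assert 0.05 < off.mean() < 0.95
        assert ((off > 0.02) & (off < 0.98)).mean() > 0.2

    def test_pair_with_no_shared_features_named_in_error(self):
        X = pd.DataFrame(
            {"f1": [1.0, np.nan, 2.0, 1.5, 0.5, 1.2, 0.1, 2.2],
             "f2": [np.nan, 1.0, 2.0, 1.1, 0.2, 0.8, 1.9, 0.3]},
            index=[f"S{i}" for i in range(8)],
        )
        with pytest.raises(ValidationError, match="S0.*S1"):
            consensus_cluster(X, k_range=(2,), iterations=5, seed=0)

    def test_pairwise_complete_matches_full_euclidean_without_missing(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 5)))
        from scipy.spatial.distance import pdist, squareform

        want = squareform(pdist(X.to_numpy()))
        got = pairwise_complete_distances(X)
        np.testing.assert_allclose(got, want, atol=1e-12)


@pytest.fixture(scope="module")
def planted3():
    X, truth = simulate_planted_matrix((20, 20, 20), 12, 6.0,
                                       missing_rate=0.1, seed=4)
    with pytest.warns(QCWarning):
        res = consensus_cluster(X, k_range=(2, 3, 4, 5), iterations=100, seed=4)
    return res, truth


class TestSelectK:

    def test_recovers_planted_k(self, planted3):
        res, truth = planted3
        assert res.selected_k == 3
        assert adjusted_rand_score(truth, res.labels) >= 0.9

    def test_delta_small_beyond_true_k(self, planted3):
        res, _ = planted3
        # perfect blocks at the true k: further splits add little CDF area
        assert res.delta_areas[3] > 0.2
        assert res.delta_areas[4] < 0.2 and res.delta_areas[5] < 0.2

    def test_threshold_zero_selects_max_k(self, planted3):
        res, _ = planted3
        assert select_k_cdf(res, threshold=0.0) == max(res.k_range)


class TestCharacterize:
    def test_flat_feature_p_one_and_bh_matches_stepup(self, rng):
        X, truth = simulate_planted_matrix((8, 8), 6, 4.0, seed=6)
        X["flat"] = 1.0
        labels = pd.Series(truth + 1, index=X.index)
        out = characterize_clusters(X, labels)
        flat = out[out.feature == "flat"]
        assert (flat.p_raw == 1.0).all()
        np.testing.assert_allclose(
            out["p_adjusted"].to_numpy(), bh_adjust(out["p_raw"].to_numpy()), atol=1e-12
        )

    def test_singleton_cluster_excluded(self):
        X, truth = simulate_planted_matrix((6, 6), 5, 4.0, seed=7)
        labels = pd.Series(truth + 1, index=X.index)
        labels.iloc[-1] = 99  # make a singleton
        with pytest.warns(QCWarning, match="singleton"):
            out = characterize_clusters(X, labels)
        assert 99 not in set(out.cluster)

    def test_all_singletons_rejected(self):
        X, _ = simulate_planted_matrix((2, 2), 4, 1.0, seed=8)
        labels = pd.Series(range(len(X)), index=X.index)
        with pytest.raises(ValidationError):
            characterize_clusters(X, labels)
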