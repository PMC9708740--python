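import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import lncemt as L
from helpers import random_expr


def _expr_from(values: np.ndarray, biotype="lncRNA") -> L.ExpressionMatrix:
    df = pd.DataFrame(
        values,
        index=[f"l{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )
    return L.ExpressionMatrix(df, pd.Series(biotype, index=df.index))


class TestScreen:
    def test_score_itself_gives_r_one(self):
        score = pd.Series([1.0, 2.0, 3.0, 4.0], index=[f"s{j}" for j in range(4)])
        expr = _expr_from(score.to_numpy()[None, :])
        res = L.emt_correlation_screen(expr, score)
        assert res.table.loc["l0", "r"] == pytest.approx(1.0)
        assert bool(res.table.loc["l0", "pass"])

    def test_hand_computed_product_moment(self):
        # r([1,2,3,4],[1,3,2,4]) = 0.8 by direct product-moment computation
        expr = _expr_from(np.array([[1.0, 2.0, 3.0, 4.0]]))
        score = pd.Series([1.0, 3.0, 2.0, 4.0], index=expr.sample_ids)
        res = L.emt_correlation_screen(expr, score)
        assert res.table.loc["l0", "r"] == pytest.approx(0.8, abs=1e-12)

    def test_constant_lncrna_flagged_undefined(self):
        expr = _expr_from(np.array([[2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0]]))
        score = pd.Series([1.0, 2.0, 3.0, 4.0], index=expr.sample_ids)
        res = L.emt_correlation_screen(expr, score)
        assert np.isnan(res.table.loc["l0", "r"])
        assert not bool(res.table.loc["l0", "pass"])

    def test_p_value_matches_scipy(self):
        rng = np.random.default_rng(0)
        expr = _expr_from(rng.normal(size=(5, 30)))
        score = pd.Series(rng.normal(size=30), index=expr.sample_ids)
        res = L.emt_correlation_screen(expr, score)
        for i, lnc in enumerate(expr.feature_ids):
            r_ref, p_ref = stats.pearsonr(
                expr.values.loc[lnc].to_numpy(), score.to_numpy()
            )
            assert res.table.loc[lnc, "r"] == pytest.approx(r_ref, abs=1e-12)
            assert res.table.loc[lnc, "p"] == pytest.approx(p_ref, rel=1e-9)

    def test_sample_mismatch_rejected(self):
        expr = _expr_from(np.ones((1, 4)) * np.arange(4))
        score = pd.Series([1.0, 2.0, 3.0, 4.0], index=["x1", "x2", "x3", "x4"])
        with pytest.raises(ValueError, match="sample ids"):
            L.emt_correlation_screen(expr, score)


class TestIntersect:
    def _screen(self, rows: dict) -> L.ScreenResult:
        table = pd.DataFrame(rows).T
        table.columns = ["r", "p", "pass", "sign"]
        return L.ScreenResult(table=table, r_thresh=0.25, p_thresh=0.05)

    def test_sign_consistency_required(self):
        a = self._screen({"x": [0.5, 0.01, True, 1], "y": [-0.5, 0.01, True, -1]})
        b = self._screen({"x": [0.6, 0.01, True, 1], "y": [0.5, 0.01, True, 1]})
        assert L.intersect_screens([a, b]) == ["x"]

    def test_identical_results_identity(self):
        a = self._screen({"x": [0.5, 0.01, True, 1], "y": [-0.5, 0.01, True, -1]})
        assert L.intersect_screens([a, a]) == ["x", "y"]

    def test_partial_pass_excluded_from_three_cohorts(self):
        a = self._screen({"x": [0.5, 0.01, True, 1]})
        b = self._screen({"x": [0.5, 0.01, True, 1]})
        c = self._screen({"x": [0.1, 0.5, False, 1]})
        assert L.intersect_screens([a, b, c]) == []

    def test_sign_check_can_be_disabled(self):
        a = self._screen({"x": [0.5, 0.01, True, 1]})
        b = self._screen({"x": [-0.5, 0.01, True, -1]})
        assert L.intersect_screens([a, b]) == []
        assert L.intersect_screens([a, b], require_sign=False) == ["x"]


def _blobs(rng, n_per, centers, sd=1.0):
    X = np.vstack(
        [rng.normal(c, sd, size=(n_per, len(centers[0]))) for c in centers]
    )
    labels = np.repeat(np.arange(len(centers)), n_per)
    df = pd.DataFrame(X, index=[f"s{i}" for i in range(len(X))])
    return df, labels


class TestConsensus:
    def test_separable_blobs_recovered_perfectly(self):
        rng = np.random.default_rng(0)
        X, truth = _blobs(rng, 30, [(0.0, 0.0), (10.0, 10.0)])
        res = L.consensus_cluster(X, seed=1, k_min=2, k_max=4, n_boot=100)
        assert res.chosen_k == 2
        m = res.consensus[2].to_numpy()
        same = truth[:, None] == truth[None, :]
        iu = np.triu_indices_from(m, k=1)
        assert np.all(m[iu][same[iu]] == 1.0)
        assert np.all(m[iu][~same[iu]] == 0.0)
        assert adjusted_rand_score(truth, res.labels.to_numpy()) == 1.0

    def test_noise_has_higher_pac_than_structure(self):
        rng = np.random.default_rng(1)
        Xs, _ = _blobs(rng, 30, [(0.0, 0.0), (10.0, 10.0)])
        Xn = pd.DataFrame(
            rng.normal(size=(60, 2)), index=[f"s{i}" for i in range(60)]
        )
        res_s = L.consensus_cluster(Xs, seed=2, k_min=2, k_max=2, n_boot=100)
        res_n = L.consensus_cluster(Xn, seed=2, k_min=2, k_max=2, n_boot=100)
        assert res_n.pac[2] > res_s.pac[2] + 0.2

    def test_duplicated_samples_always_co_cluster(self):
        rng = np.random.default_rng(2)
        X, _ = _blobs(rng, 12, [(0.0, 0.0), (6.0, 6.0)])
        X2 = pd.concat([X, X.set_axis([f"d{i}" for i in range(len(X))])])
        res = L.consensus_cluster(X2, seed=3, k_min=2, k_max=2, n_boot=100)
        m = res.consensus[2]
        for i in range(len(X)):
            assert m.loc[f"s{i}", f"d{i}"] == 1.0

    def test_sample_order_permutation_invariance(self):
        rng = np.random.default_rng(3)
        X, _ = _blobs(rng, 20, [(0.0, 0.0), (4.0, 4.0)])
        res1 = L.consensus_cluster(X, seed=4, k_min=2, k_max=2, n_boot=200)
        perm = rng.permutation(len(X))
        Xp = X.iloc[perm]
        res2 = L.consensus_cluster(Xp, seed=4, k_min=2, k_max=2, n_boot=200)
        m1 = res1.consensus[2].loc[X.index, X.index].to_numpy()
        m2 = res2.consensus[2].loc[X.index, X.index].to_numpy()
        assert np.abs(m1 - m2).mean() < 0.05

    def test_cdf_exposed_and_monotone(self):
        rng = np.random.default_rng(4)
        X, _ = _blobs(rng, 15, [(0.0, 0.0), (5.0, 5.0)])
        res = L.consensus_cluster(X, seed=5, k_min=2, k_max=3, n_boot=60)
        grid, cdf = res.cdf(2)
        assert np.all(np.diff(cdf) >= 0)
        assert cdf[-1] == 1.0

    def test_too_few_samples_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError, match="more samples"):
            L.consensus_cluster(X, seed=0, k_min=2, k_max=6, n_boot=50)


def _clin(times, events):
    idx = [f"s{i}" for i in range(len(times))]
    return L.ClinicalTable(
        pd.DataFrame({"os_time": times, "os_event": events}, index=idx)
    )


class TestLabelSubtypes:
    def test_better_survival_cluster_named_c1(self):
        clin = _clin([1, 1, 10, 10], [1, 1, 0, 0])
        labels = pd.Series([1, 1, 2, 2], index=clin.sample_ids)
        out = L.label_subtypes(labels, clin)
        assert (out[["s2", "s3"]] == "C1").all()
        assert (out[["s0", "s1"]] == "C2").all()

    def test_tie_broken_by_cluster_size(self):
        clin = _clin([5, 5, 5, 5, 5], [1, 1, 1, 1, 1])
        labels = pd.Series([1, 1, 2, 2, 2], index=clin.sample_ids)
        out = L.label_subtypes(labels, clin)
        assert (out[labels == 2] == "C1").all()

    def test_invariant_to_arbitrary_label_codes(self):
        clin = _clin([1, 1, 9, 9, 9], [1, 1, 1, 1, 1])
        labels_a = pd.Series([7, 7, 3, 3, 3], index=clin.sample_ids)
        labels_b = pd.Series([0, 0, 9, 9, 9], index=clin.sample_ids)
        assert L.label_subtypes(labels_a, clin).equals(L.label_subtypes(labels_b, clin))

    def test_more_than_two_clusters_ordered(self):
        clin = _clin([1, 1, 5, 5, 20, 20], [1, 1, 1, 1, 1, 1])
        labels = pd.Series([1, 1, 2, 2, 3, 3], index=clin.sample_ids)
        out = L.label_subtypes(labels, clin)
        assert (out[labels == 3] == "C1").all()
        assert (out[labels == 1] == "C3").all()


class TestCompareGroups:
    def test_rank_sum_exact_enumeration_case(self):
        # [1,2,3] vs [4,5,6]: most extreme of the C(6,3)=20 assignments,
        # two-sided p = 2/20 = 0.1
        values = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], index=["f"])
        values.columns = [f"s{i}" for i in range(6)]
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=values.columns)
        res = L.compare_groups(values, labels, test="wilcoxon")
        assert res.table.loc["f", "p"] == pytest.approx(0.1, abs=1e-12)

    def test_fisher_cross_table(self):
        # [[2,0],[0,2]]: p = 2/6 by hypergeometric enumeration
        values = pd.DataFrame([[1, 1, 0, 0]], index=["g"], columns=[f"s{i}" for i in range(4)])
        labels = pd.Series(["a", "a", "b", "b"], index=values.columns)
        res = L.compare_groups(values.astype(float), labels, test="fisher")
        assert res.table.loc["g", "p"] == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_groups_fisher_p_one(self):
        values = pd.DataFrame([[1, 0, 1, 0]], index=["g"], columns=[f"s{i}" for i in range(4)])
        labels = pd.Series(["a", "a", "b", "b"], index=values.columns)
        res = L.compare_groups(values.astype(float), labels, test="fisher")
        assert res.table.loc["g", "p"] == 1.0

    def test_welch_t_matches_scipy(self):
        rng = np.random.default_rng(5)
        values = pd.DataFrame(rng.normal(size=(3, 20)), index=list("abc"))
        values.columns = [f"s{i}" for i in range(20)]
        labels = pd.Series(["x"] * 10 + ["y"] * 10, index=values.columns)
        res = L.compare_groups(values, labels, test="student_t")
        ref = stats.ttest_ind(
            values.iloc[0, :10], values.iloc[0, 10:], equal_var=False
        )
        assert res.table.loc["a", "p"] == pytest.approx(ref.pvalue, rel=1e-12)

    def test_empty_group_rejected(self):
        values = pd.DataFrame([[1.0, 2.0]], index=["f"], columns=["s0", "s1"])
        labels = pd.Series(["a", "a"], index=values.columns)
        with pytest.raises(ValueError):
            L.compare_groups(values, labels, test="wilcoxon")
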