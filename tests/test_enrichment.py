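from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lncemt as L
from helpers import random_expr


def ssgsea_oracle(values: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Brute-force running sum, gene by gene, written independently."""
    n = len(values)
    m = int(in_set.sum())
    order = sorted(range(n), key=lambda i: (-values[i], i))
    # rank from bottom with average ties
    rank_bottom = stats.rankdata(values, method="average")
    total_w = sum(rank_bottom[j] ** alpha for j in range(n) if in_set[j])
    es = 0.0
    for i in range(1, n + 1):
        top = order[:i]
        p_in = sum(rank_bottom[j] ** alpha for j in top if in_set[j]) / total_w
        p_out = sum(1 for j in top if not in_set[j]) / (n - m)
        es += p_in - p_out
    return es


class TestSsgsea:
    def test_worked_single_gene_example(self):
        # 4 features, the set gene ranked first, alpha=0:
        # ES = (1-0) + (1-1/3) + (1-2/3) + (1-1) = 2
        values = pd.DataFrame(
            {"s1": [4.0, 3.0, 2.0, 1.0]}, index=["g1", "g2", "g3", "g4"]
        )
        expr = L.ExpressionMatrix(values, pd.Series("other", index=values.index))
        es = L.ssgsea_score(expr, ["g1"], L.SsgseaParams(alpha=0))
        assert es["s1"] == pytest.approx(2.0, abs=1e-12)

    def test_first_last_antisymmetry_unweighted(self):
        rng = np.random.default_rng(0)
        expr = random_expr(rng, 10, 1)
        vals = expr.values.copy()
        top = vals["s0"].nlargest(3).index
        bottom = vals["s0"].nsmallest(3).index
        es_top = L.ssgsea_score(expr, list(top), L.SsgseaParams(alpha=0))
        es_bottom = L.ssgsea_score(expr, list(bottom), L.SsgseaParams(alpha=0))
        assert es_top["s0"] == pytest.approx(-es_bottom["s0"], abs=1e-12)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        expr = random_expr(rng, 20, 3)
        genes = list(expr.feature_ids[:5])
        base = L.ssgsea_score(expr, genes)
        vals = expr.values.copy()
        vals["s1"] = np.exp(vals["s1"] * 2)  # strictly increasing
        expr2 = L.ExpressionMatrix(vals, expr.biotype)
        assert L.ssgsea_score(expr2, genes)["s1"] == pytest.approx(base["s1"], abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 1.0])
    def test_matches_brute_force_oracle(self, alpha):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(34):
            n = int(rng.integers(5, 51))
            m = int(rng.integers(1, min(11, n)))
            expr = random_expr(rng, n, 2)
            genes = list(rng.choice(expr.feature_ids, size=m, replace=False))
            got = L.ssgsea_score(expr, genes, L.SsgseaParams(alpha=alpha))
            in_set = np.asarray(expr.feature_ids.isin(genes))
            for s in expr.sample_ids:
                exp = ssgsea_oracle(expr.values[s].to_numpy(), in_set, alpha)
                worst = max(worst, abs(got[s] - exp))
        assert worst < 1e-9

    def test_alpha0_depends_only_on_set_positions(self):
        # permuting out-of-set genes among themselves leaves ES unchanged
        rng = np.random.default_rng(3)
        expr = random_expr(rng, 15, 1)
        genes = list(expr.feature_ids[:4])
        base = L.ssgsea_score(expr, genes, L.SsgseaParams(alpha=0))["s0"]
        vals = expr.values.copy()
        out = [g for g in expr.feature_ids if g not in genes]
        perm = rng.permutation(vals.loc[out, "s0"].to_numpy())
        # permute out-of-set VALUES among out-of-set genes: set positions fixed
        order_out = np.argsort(-vals.loc[out, "s0"].to_numpy())
        sorted_vals = np.sort(perm)[::-1]
        new = vals.copy()
        new.loc[np.array(out)[order_out], "s0"] = sorted_vals
        expr2 = L.ExpressionMatrix(new, expr.biotype)
        assert L.ssgsea_score(expr2, genes, L.SsgseaParams(alpha=0))["s0"] == pytest.approx(
            base, abs=1e-9
        )

    def test_set_equal_universe_rejected(self, tiny_expr):
        with pytest.raises(ValueError, match="universe"):
            L.ssgsea_score(tiny_expr, ["g1", "g2", "g3", "g4"])

    def test_absent_set_rejected(self, tiny_expr):
        with pytest.raises(ValueError, match="zz"):
            L.ssgsea_score(tiny_expr, ["zz"])

    def test_normalized_scores_in_unit_interval(self):
        rng = np.random.default_rng(4)
        expr = random_expr(rng, 30, 8)
        s = L.ssgsea_score(expr, list(expr.feature_ids[:6]),
                           L.SsgseaParams(normalize=True))
        assert s.min() == 0.0 and s.max() == 1.0


class TestSignatureScores:
    def test_top_ranked_signature_is_cohort_maximum(self):
        rng = np.random.default_rng(5)
        expr = random_expr(rng, 30, 10)
        stromal = list(expr.feature_ids[:5])
        immune = list(expr.feature_ids[5:10])
        vals = expr.values.copy()
        vals.loc[stromal, "s0"] = vals["s0"].max() + np.arange(1, 6)
        expr2 = L.ExpressionMatrix(vals, expr.biotype)
        est = L.estimate_scores(expr2, stromal, immune)
        assert est.loc["stromal", "s0"] == est.loc["stromal"].max()

    def test_disjoint_shuffled_signatures_uncorrelated(self):
        # Monte-Carlo null: independent ranks -> near-zero score correlation
        rng = np.random.default_rng(6)
        expr = random_expr(rng, 40, 200)
        est = L.estimate_scores(
            expr, list(expr.feature_ids[:6]), list(expr.feature_ids[6:12])
        )
        r = np.corrcoef(est.loc["stromal"], est.loc["immune"])[0, 1]
        assert abs(r) < 0.15

    def test_duplicate_sample_gets_identical_scores(self):
        rng = np.random.default_rng(7)
        expr = random_expr(rng, 25, 3)
        vals = expr.values.copy()
        vals["dup"] = vals["s0"]
        expr2 = L.ExpressionMatrix(vals, expr.biotype)
        est = L.estimate_scores(
            expr2, list(expr2.feature_ids[:4]), list(expr2.feature_ids[4:8])
        )
        assert est["dup"].equals(est["s0"])

    def test_absent_immune_signature_named(self):
        rng = np.random.default_rng(8)
        expr = random_expr(rng, 10, 3)
        sigs = L.GeneSetCollection({"ok": list(expr.feature_ids[:3]), "ghost": ["no1", "no2"]})
        with pytest.raises(ValueError, match="ghost"):
            L.immune_infiltration(expr, sigs)


def gsea_oracle_es(metric: np.ndarray, in_set: np.ndarray) -> float:
    """Independent weighted-KS enrichment score (weight 1)."""
    order = sorted(range(len(metric)), key=lambda i: (-metric[i], i))
    nr = sum(abs(metric[i]) for i in order if in_set[i])
    n_miss = len(metric) - int(in_set.sum())
    run, best = 0.0, 0.0
    for i in order:
        if in_set[i]:
            run += abs(metric[i]) / nr
        else:
            run -= 1.0 / n_miss
        if abs(run) > abs(best):
            best = run
    return best


class TestTwoGroupGsea:
    def _toy(self, seed=0, n_feat=30, n1=3, n0=3):
        rng = np.random.default_rng(seed)
        expr = random_expr(rng, n_feat, n1 + n0)
        labels = pd.Series([1] * n1 + [0] * n0, index=expr.sample_ids)
        return expr, labels

    def test_top_metric_set_reaches_es_one(self):
        expr, labels = self._toy(seed=1)
        vals = expr.values.copy()
        top = list(expr.feature_ids[:5])
        vals.loc[top, labels == 1] += 50.0  # extreme positive signal-to-noise
        expr2 = L.ExpressionMatrix(vals, expr.biotype)
        res = L.gsea_two_group(
            expr2, labels, L.GeneSetCollection({"top": top}), n_perm=10, seed=0, weight=0.0
        )
        assert res.table.loc["top", "es"] == pytest.approx(1.0, abs=1e-12)

    def test_label_swap_negates_nes(self):
        expr, labels = self._toy(seed=2, n1=4, n0=4)
        sets = L.GeneSetCollection({"a": list(expr.feature_ids[:6])})
        res1 = L.gsea_two_group(expr, labels, sets, exhaustive=True)
        res2 = L.gsea_two_group(expr, 1 - labels, sets, exhaustive=True)
        assert res1.table.loc["a", "nes"] == pytest.approx(
            -res2.table.loc["a", "nes"], rel=1e-9
        )
        assert res1.table.loc["a", "direction"] != res2.table.loc["a", "direction"]

    def test_exhaustive_p_matches_enumeration_oracle(self):
        expr, labels = self._toy(seed=3, n_feat=25)
        sets = L.GeneSetCollection(
            {"x": list(expr.feature_ids[:5]), "y": list(expr.feature_ids[10:16])}
        )
        res = L.gsea_two_group(expr, labels, sets, exhaustive=True)
        X = expr.values.to_numpy()
        n = X.shape[1]
        for name in sets.names():
            in_set = np.asarray(expr.feature_ids.isin(sets[name]))

            def metric_for(mask):
                g1, g0 = X[:, mask], X[:, ~mask]
                mu1, mu0 = g1.mean(1), g0.mean(1)
                s1 = np.maximum(g1.std(1, ddof=1), 0.2 * np.abs(mu1) + 1e-8)
                s0 = np.maximum(g0.std(1, ddof=1), 0.2 * np.abs(mu0) + 1e-8)
                return (mu1 - mu0) / (s1 + s0)

            obs_mask = labels.to_numpy() == 1
            es_obs = gsea_oracle_es(metric_for(obs_mask), in_set)
            null = []
            for idx in combinations(range(n), int(obs_mask.sum())):
                mask = np.zeros(n, dtype=bool)
                mask[list(idx)] = True
                null.append(gsea_oracle_es(metric_for(mask), in_set))
            null = np.array(null)
            same = null >= 0 if es_obs >= 0 else null < 0
            p_exact = float(np.mean(np.abs(null[same]) >= abs(es_obs)))
            assert res.table.loc[name, "es"] == pytest.approx(es_obs, abs=1e-12)
            assert res.table.loc[name, "p"] == pytest.approx(p_exact, abs=1e-12)

    def test_null_labels_calibrated(self):
        # random labels: nominal p < 0.05 in about 5% of sets over replicates
        rng = np.random.default_rng(9)
        hits, total = 0, 0
        for rep in range(10):
            expr = random_expr(np.random.default_rng(100 + rep), 40, 12)
            labels = pd.Series(
                rng.permutation([1] * 6 + [0] * 6), index=expr.sample_ids
            )
            sets = L.GeneSetCollection(
                {f"s{i}": list(expr.feature_ids[i * 4 : i * 4 + 4]) for i in range(5)}
            )
            res = L.gsea_two_group(expr, labels, sets, n_perm=200, seed=rep)
            hits += int((res.table["p"] < 0.05).sum())
            total += len(sets)
        assert hits / total == pytest.approx(0.05, abs=0.08)

    def test_small_group_rejected(self):
        expr, labels = self._toy(n1=2, n0=4)
        with pytest.raises(ValueError, match=">= 3"):
            L.gsea_two_group(expr, labels, L.GeneSetCollection({"a": ["g0", "g1"]}))


class TestOra:
    def test_worked_hypergeometric_example(self):
        # C(5,4)*C(5,0)/C(10,4) = 5/210
        universe = [f"u{i}" for i in range(10)]
        gene_set = universe[:5]
        query = universe[:4]
        p = L.ora_hypergeometric(query, gene_set, universe)
        assert p == pytest.approx(5 / 210, rel=1e-12)

    def test_empty_query_p_one(self):
        universe = ["a", "b", "c"]
        assert L.ora_hypergeometric([], ["a"], universe) == 1.0

    def test_set_equal_universe_p_one(self):
        universe = ["a", "b", "c", "d"]
        assert L.ora_hypergeometric(["a", "b"], universe, universe) == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            L.ora_hypergeometric(["a"], ["a"], [])

    def test_collection_bh_adjustment_monotone(self):
        universe = [f"u{i}" for i in range(30)]
        sets = L.GeneSetCollection(
            {"hit": universe[:5], "miss": universe[20:25]}
        )
        out = L.ora_collection(universe[:5], sets, universe)
        assert out.loc["hit", "p"] < out.loc["miss", "p"]
        assert (out["q"] >= out["p"] - 1e-15).all()
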