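"""Statistical kernel checks against independent oracles: a brute-force
running-sum reimplementation for ssGSEA, exhaustive enumeration for the
permutation fit, O(n^2) pair counting for the ROC AUC, the closed-form
2x2 chi-square, and a hand-computed hypergeometric log-rank table."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triaxis import enrichment
from triaxis.containers import GeneSet, GeneSetCollection, TriaxisError
from conftest import make_expression


# ---------------------------------------------------------------------------
# independent oracles


def ssgsea_oracle(values: np.ndarray, set_mask: np.ndarray, alpha: float) -> float:
    """Direct transcription of the running-sum definition, O(N^2)."""
    n = len(values)
    ranks = stats.rankdata(values)  # ascending, average ties
    order = np.argsort(-ranks, kind="stable")
    denom_in = sum(ranks[g] ** alpha for g in range(n) if set_mask[g])
    n_out = n - set_mask.sum()
    score = 0.0
    for i in range(1, n + 1):
        seen = order[:i]
        p_in = sum(ranks[g] ** alpha for g in seen if set_mask[g]) / denom_in
        p_out = sum(1 for g in seen if not set_mask[g]) / n_out
        score += p_in - p_out
    return score


def auc_pair_oracle(score, label):
    """AUC by explicit pair counting with half credit for ties."""
    pos = [s for s, l in zip(score, label) if l == 1]
    neg = [s for s, l in zip(score, label) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# ssGSEA


class TestSsgsea:
    def test_four_gene_hand_example(self):
        m = make_expression({"s1": [4.0, 3.0, 2.0, 1.0]}, index=["g1", "g2", "g3", "g4"])
        sets = GeneSetCollection([GeneSet("S", "synthetic", ("g1", "g3"))])
        sm = enrichment.ssgsea_scores(m, sets, alpha=1.0, normalize=False)
        assert sm.scores.iloc[0, 0] == pytest.approx(4 / 3, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(0)
        values = rng.lognormal(2, 1, size=(200, 10))
        m = make_expression(
            {f"s{j}": values[:, j] for j in range(10)},
            niches=["CT"] * 10,
            index=[f"g{i}" for i in range(200)],
        )
        sets = GeneSetCollection(
            [
                GeneSet(f"S{k}", "synthetic", tuple(f"g{i}" for i in rng.choice(200, 15, replace=False)))
                for k in range(3)
            ]
        )
        sm = enrichment.ssgsea_scores(m, sets, alpha=0.25, normalize=False)
        for k, s in enumerate(sets):
            mask = np.array([g in s.gene_set for g in m.feature_ids])
            for j in range(10):
                expected = ssgsea_oracle(values[:, j], mask, 0.25)
                assert sm.scores.iloc[k, j] == pytest.approx(expected, abs=1e-9)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(0, 1, 50)
        m1 = make_expression({"s": vals}, index=[f"g{i}" for i in range(50)])
        m2 = make_expression({"s": vals**3 + 7}, index=[f"g{i}" for i in range(50)])
        sets = GeneSetCollection([GeneSet("S", "synthetic", ("g3", "g8", "g12", "g40"))])
        a = enrichment.ssgsea_scores(m1, sets, normalize=False).scores
        b = enrichment.ssgsea_scores(m2, sets, normalize=False).scores
        pd.testing.assert_frame_equal(a, b)

    def test_identical_columns_identical_scores(self, tiny_matrix):
        sets = GeneSetCollection([GeneSet("S", "synthetic", ("g1", "g3"))])
        sm = enrichment.ssgsea_scores(tiny_matrix, sets)
        assert sm.scores["s1"].equals(sm.scores["s3"])

    def test_normalization_is_single_global_scalar(self, tissue_scores):
        # ordering of entries is preserved under global range scaling
        raw = tissue_scores.scores.to_numpy()
        assert tissue_scores.normalized
        assert np.ptp(raw) == pytest.approx(1.0, abs=1e-9)

    def test_all_sets_too_small_rejected(self, tiny_matrix):
        sets = GeneSetCollection([GeneSet("S", "synthetic", ("g1",))])
        with pytest.raises(TriaxisError):
            with pytest.warns(UserWarning):
                enrichment.ssgsea_scores(tiny_matrix, sets)


# ---------------------------------------------------------------------------
# preranked GSEA


class TestGseaPreranked:
    def _stat(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(np.sort(rng.normal(0, 1, n))[::-1], index=[f"g{i}" for i in range(n)])

    def test_top_k_set_hits_p_floor(self):
        stat = self._stat()
        res = enrichment.gsea_preranked(stat, [f"g{i}" for i in range(15)], n_perm=200, seed=1)
        assert res["es"] > 0.9
        assert res["p"] == pytest.approx(1 / 201)

    def test_reversed_ranking_negates_es(self):
        stat = self._stat(seed=2)
        genes = [f"g{i}" for i in range(10)]
        a = enrichment.gsea_preranked(stat, genes, n_perm=100, seed=3)
        rev = pd.Series(-stat.to_numpy(), index=stat.index)
        b = enrichment.gsea_preranked(rev, genes, n_perm=100, seed=3)
        assert np.sign(a["es"]) == -np.sign(b["es"])

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(4)
        stat = self._stat(n=120, seed=4)
        ps = []
        for _ in range(500):
            genes = [f"g{i}" for i in rng.choice(120, 10, replace=False)]
            ps.append(enrichment.gsea_preranked(stat, genes, n_perm=100, seed=5)["p"])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


# ---------------------------------------------------------------------------
# permutation linear fit


class TestPermutedLinearFit:
    def test_exhaustive_four_point_example(self):
        res = enrichment.permuted_linear_fit([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.n_perm == 24
        assert res.p_value == pytest.approx(2 / 24)

    def test_sign_symmetry(self):
        a = enrichment.permuted_linear_fit([1, 2, 3, 4], [1, 2, 3, 4])
        b = enrichment.permuted_linear_fit([1, 2, 3, 4], [-1, -2, -3, -4])
        assert a.p_value == b.p_value and b.slope == -a.slope

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(6)
        rejections = 0
        trials = 1000
        for _ in range(trials):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0, 1, 8)
            res = enrichment.permuted_linear_fit(x, y, n_perm=199, seed=int(rng.integers(2**31)))
            rejections += res.p_value <= 0.05
        # 99% binomial band around 0.05
        lo, hi = stats.binom.ppf([0.005, 0.995], trials, 0.05) / trials
        assert lo <= rejections / trials <= hi

    def test_constant_y_gives_p_one(self):
        with pytest.warns(UserWarning):
            res = enrichment.permuted_linear_fit([1, 2, 3, 4], [5, 5, 5, 5])
        assert res.p_value == 1.0

    def test_constant_x_rejected(self):
        with pytest.raises(TriaxisError):
            enrichment.permuted_linear_fit([1, 1, 1, 1], [1, 2, 3, 4])


class TestRobustLinearFitIqr:
    def test_perfect_line_no_removals_tiny_p(self):
        x = np.arange(10.0)
        res = enrichment.robust_linear_fit_iqr(x, 3 * x - 2)
        assert res.n_used == 10
        assert res.p_value < 1e-6
        assert res.slope == pytest.approx(3.0)

    def test_gross_outlier_removed_and_slope_restored(self):
        rng = np.random.default_rng(7)
        x = np.linspace(0, 10, 30)
        y = 2 * x + rng.normal(0, 0.05, 30)
        y[4] += 50
        res = enrichment.robust_linear_fit_iqr(x, y)
        clean = np.delete(np.arange(30), 4)
        ref = np.polyfit(x[clean], y[clean], 1)[0]
        assert res.n_used <= 29
        assert res.slope == pytest.approx(ref, abs=1e-6)

    def test_null_rejection_rate_near_nominal(self):
        # IQR pruning plus heteroskedasticity-robust errors is mildly
        # anti-conservative under a clean Gaussian null (pruning tightens
        # residuals); the rejection rate at alpha=0.01 stays within a few
        # fold of nominal and far below the 5% level
        rng = np.random.default_rng(8)
        hits = sum(
            enrichment.robust_linear_fit_iqr(rng.normal(0, 1, 30), rng.normal(0, 1, 30)).p_value < 0.01
            for _ in range(500)
        )
        assert hits / 500 < 0.05


# ---------------------------------------------------------------------------
# ROC / Youden


class TestRocYouden:
    def test_perfect_separation(self):
        res = enrichment.roc_youden([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res == {"auc": 1.0, "cutoff": 0.8, "J": 1.0, "sens": 1.0, "spec": 1.0}

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(9)
        res = enrichment.roc_youden(rng.normal(0, 1, 4000), rng.integers(0, 2, 4000))
        assert abs(res["auc"] - 0.5) < 0.05

    def test_auc_matches_pair_counting_oracle_with_ties(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            n = int(rng.integers(6, 50))
            score = rng.integers(0, 6, n).astype(float)  # many ties
            label = rng.integers(0, 2, n)
            if label.sum() in (0, n):
                continue
            res = enrichment.roc_youden(score, label)
            assert res["auc"] == pytest.approx(auc_pair_oracle(score, label), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(TriaxisError):
            enrichment.roc_youden([1.0, 2.0], [1, 1])


# ---------------------------------------------------------------------------
# chi-square


class TestChi2Association:
    def test_balanced_table_is_null(self):
        res = enrichment.chi2_association([[10, 10], [10, 10]])
        assert res["chi2"] == 0.0 and res["p"] == 1.0

    def test_closed_form_example(self):
        res = enrichment.chi2_association([[20, 10], [10, 20]], correction=False)
        assert res["chi2"] == pytest.approx(20 / 3)

    def test_yates_correction_shrinks_statistic(self):
        raw = enrichment.chi2_association([[20, 10], [10, 20]], correction=False)
        cor = enrichment.chi2_association([[20, 10], [10, 20]], correction=True)
        assert cor["chi2"] < raw["chi2"]

    def test_zero_margin_rejected(self):
        with pytest.raises(TriaxisError):
            enrichment.chi2_association([[0, 0], [5, 5]])


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank


class TestKmLogrank:
    def test_identical_groups_give_zero_statistic(self):
        surv = pd.DataFrame({"time": [1, 2, 3, 1, 2, 3], "event": [1, 1, 0, 1, 1, 0]},
                            index=list("abcdef"))
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=surv.index)
        res = enrichment.km_logrank(surv, groups)
        assert res.logrank_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_hypergeometric_example(self):
        # A events at t=1,2; B events at t=3,4; O-E = 7/6, Var = 17/36
        surv = pd.DataFrame({"time": [1, 2, 3, 4], "event": [1, 1, 1, 1]}, index=list("abcd"))
        groups = pd.Series(["A", "A", "B", "B"], index=surv.index)
        res = enrichment.km_logrank(surv, groups)
        assert res.logrank_stat == pytest.approx((7 / 6) ** 2 / (17 / 36), rel=1e-9)

    def test_km_curve_starts_at_one_and_never_increases(self):
        rng = np.random.default_rng(11)
        surv = pd.DataFrame(
            {"time": rng.exponential(5, 40), "event": rng.integers(0, 2, 40)},
            index=[f"s{i}" for i in range(40)],
        )
        surv.loc[surv.index[0], "event"] = 1
        groups = pd.Series(["A"] * 20 + ["B"] * 20, index=surv.index)
        res = enrichment.km_logrank(surv, groups)
        for curve in res.curves.values():
            s = curve["survival"].to_numpy()
            assert s[0] == 1.0
            assert (np.diff(s) <= 1e-12).all()

    def test_empty_group_rejected(self):
        surv = pd.DataFrame({"time": [1, 2], "event": [1, 1]}, index=["a", "b"])
        groups = pd.Series(["A", "A"], index=surv.index)
        with pytest.raises(TriaxisError):
            enrichment.km_logrank(surv, groups)
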