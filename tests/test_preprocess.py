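import numpy as np
import pandas as pd
import pytest

from triaxis import preprocess, synthetic
from triaxis.containers import TriaxisError
from conftest import make_expression


class TestMergeTechnicalReplicates:
    def _pair_matrix(self, a, b):
        return make_expression(
            {"s1": a, "s2": b},
            niches=["CT", "CT"],
            modality="protein",
            index=[f"g{i}" for i in range(len(a))],
        )

    def test_mean_single_value_and_both_missing(self):
        m = self._pair_matrix([4.0, 5.0, 0.0], [6.0, 0.0, 0.0])
        # patient ids must match within a pair
        m.sample_meta["patient_id"] = "p1"
        merged = preprocess.merge_technical_replicates(m, [("s1", "s2")])
        assert merged.values["s1"].tolist() == [5.0, 5.0, 0.0]
        assert merged.missing_mask["s1"].tolist() == [False, False, True]

    def test_unknown_sample_in_pair_rejected(self):
        m = self._pair_matrix([1.0], [2.0])
        with pytest.raises(TriaxisError, match="unknown"):
            preprocess.merge_technical_replicates(m, [("s1", "nope")])

    def test_pair_across_niches_rejected(self):
        m = make_expression({"s1": [1.0], "s2": [2.0]}, niches=["CT", "PAN"], modality="protein")
        with pytest.raises(TriaxisError, match="patient/niche"):
            preprocess.merge_technical_replicates(m, [("s1", "s2")])


class TestPresenceFilter:
    def test_any_group_rule_keeps_60pct_in_one_group(self):
        df = {f"c{i}": [0.0, 0.0, 1.0] for i in range(5)} | {f"p{i}": [0.0, 0.0, 1.0] for i in range(5)}
        m = make_expression(df, niches=["CT"] * 5 + ["PAN"] * 5, modality="protein",
                            index=["gA", "gB", "gC"])
        m.values.loc["gA", ["c0", "c1", "c2"]] = 1.0
        m.missing_mask.loc["gA", ["c0", "c1", "c2"]] = False
        m.values.loc["gB", ["c0", "c1", "p0", "p1"]] = 1.0
        m.missing_mask.loc["gB", ["c0", "c1", "p0", "p1"]] = False
        out = preprocess.presence_filter(m, frac=0.6)
        assert list(out.feature_ids) == ["gA", "gC"]  # gA 3/5 CT kept, gB 2/5 dropped

    def test_idempotent(self, cohort_protein):
        m, _ = cohort_protein
        once = preprocess.presence_filter(m)
        twice = preprocess.presence_filter(once)
        assert list(once.feature_ids) == list(twice.feature_ids)

    def test_zero_fraction_rejected(self, cohort_protein):
        m, _ = cohort_protein
        with pytest.raises(TriaxisError):
            preprocess.presence_filter(m, frac=0.0)


class TestImputeMissing:
    def test_no_missing_equals_log2(self):
        m = make_expression({"s1": [1.0, 2.0, 4.0, 8.0], "s2": [2.0, 4.0, 8.0, 16.0]},
                            modality="protein", index=list("abcd"))
        out = preprocess.impute_missing(m, seed=0)
        np.testing.assert_allclose(out.values.to_numpy(), np.log2(m.values.to_numpy()))

    def test_same_seed_reproducible(self, cohort_protein):
        m, _ = cohort_protein
        f = preprocess.presence_filter(m)
        a = preprocess.impute_missing(f, seed=5)
        b = preprocess.impute_missing(f, seed=5)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_imputed_draws_match_downshifted_gaussian_moments(self):
        rng = np.random.default_rng(1)
        n = 20_000
        observed = 2.0 ** rng.normal(10, 2, size=n)
        col = np.concatenate([observed, np.zeros(n)])
        m = make_expression({"s1": col}, modality="protein",
                            index=[f"g{i}" for i in range(2 * n)])
        out = preprocess.impute_missing(m, downshift=0.3, width=1.8, seed=2)
        obs_log = np.log2(observed)
        mu, sigma = obs_log.mean(), obs_log.std(ddof=1)
        imputed = out.values["s1"].to_numpy()[n:]
        se = 1.8 * sigma / np.sqrt(n)
        assert abs(imputed.mean() - (mu - 0.3 * sigma)) < 3 * se
        assert abs(imputed.std(ddof=1) - 1.8 * sigma) < 0.05 * 1.8 * sigma

    def test_column_with_too_few_observations_rejected(self):
        m = make_expression({"s1": [1.0, 2.0, 0.0, 0.0]}, modality="protein", index=list("abcd"))
        with pytest.raises(TriaxisError, match="<3 observed"):
            preprocess.impute_missing(m, seed=0)


class TestCenterGeometric:
    @pytest.mark.parametrize(
        "col,target,expected",
        [
            ([1.0, 10.0, 100.0], 10.0, [1.0, 10.0, 100.0]),
            ([2.0, 20.0, 200.0], 10.0, [1.0, 10.0, 100.0]),
            ([2.5, 2.5], 2.5, [2.5, 2.5]),
        ],
    )
    def test_hand_examples(self, col, target, expected):
        m = make_expression({"s1": col}, index=[f"g{i}" for i in range(len(col))])
        out = preprocess.center_geometric(m, target)
        np.testing.assert_allclose(out.values["s1"].to_numpy(), expected)

    def test_all_columns_reach_target_and_zeros_preserved(self, cohort_protein):
        m, _ = cohort_protein
        out = preprocess.center_geometric(m, 1e7)
        vals = out.values.to_numpy()
        for j in range(vals.shape[1]):
            pos = vals[:, j] > 0
            gm = np.exp(np.mean(np.log(vals[pos, j])))
            assert abs(gm - 1e7) / 1e7 < 1e-9
        assert ((m.values.to_numpy() == 0) == (vals == 0)).all()

    def test_all_zero_column_rejected(self):
        m = make_expression({"s1": [0.0, 0.0]}, modality="protein", index=["a", "b"])
        with pytest.raises(TriaxisError):
            preprocess.center_geometric(m, 10.0)


class TestSelectLowZeroFeatures:
    def test_fully_observed_identity(self, tiny_matrix):
        out = preprocess.select_low_zero_features(tiny_matrix, n=4)
        assert list(out.feature_ids) == list(tiny_matrix.feature_ids)

    def test_orders_by_zero_count_then_abundance(self):
        df = {
            "s1": [1.0, 0.0, 0.0, 5.0],
            "s2": [1.0, 2.0, 0.0, 5.0],
            "s3": [1.0, 2.0, 3.0, 5.0],
        }
        # zeros: gA=0, gB=1, gC=2, gD=0; tie gA/gD broken by total abundance
        m = make_expression(df, niches=["CT"] * 3, index=["gA", "gB", "gC", "gD"])
        out = preprocess.select_low_zero_features(m, n=2)
        assert list(out.feature_ids) == ["gD", "gA"]

    def test_boundary_tie_resolved_by_abundance(self):
        df = {"s1": [0.0, 1.0, 9.0], "s2": [1.0, 1.0, 9.0]}
        m = make_expression(df, niches=["CT"] * 2, index=["gA", "gB", "gC"])
        out = preprocess.select_low_zero_features(m, n=2)
        # gB and gC both fully observed; both beat gA; among them order by abundance
        assert list(out.feature_ids) == ["gC", "gB"]


class TestFlagOutlierSamples:
    def test_collinear_points_not_flagged(self):
        x = np.arange(20.0)
        df = pd.DataFrame({"sample": [f"s{i}" for i in range(20)], "n_total": x, "n_msms": 2 * x + 1})
        flags = preprocess.flag_outlier_samples(df)
        assert not flags["flagged"].any()

    def test_single_gross_outlier_flagged(self):
        x = np.arange(20.0)
        y = 2 * x + 1
        y[7] = 200.0
        df = pd.DataFrame({"sample": [f"s{i}" for i in range(20)], "n_total": x, "n_msms": y})
        flags = preprocess.flag_outlier_samples(df)
        assert flags["flagged"].sum() == 1 and bool(flags.loc["s7", "flagged"])
        # Cook's distance via the closed form on the refit matches statsmodels
        assert flags.loc["s7", "cooks_d"] > 4 / 20

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame({"sample": list("abcd"), "n_total": [1.0, 2, 3, 4], "n_msms": [1.0, 2, 3, 4]})
        with pytest.raises(TriaxisError):
            preprocess.flag_outlier_samples(df)

    def test_constant_predictor_rejected(self):
        df = pd.DataFrame({"sample": list("abcde"), "n_total": [1.0] * 5, "n_msms": [1.0, 2, 3, 4, 5]})
        with pytest.raises(TriaxisError, match="constant"):
            preprocess.flag_outlier_samples(df)


class TestRegionMarkerMatrix:
    def _toy(self, pan_mean=10.0, mvp_boost=None):
        rng = np.random.default_rng(0)
        niches = ["LE"] * 4 + ["IT"] * 4 + ["CT"] * 4 + ["PAN"] * 4 + ["MVP"] * 4
        base = rng.normal(0, 0.1, size=(3, 20)) + 5.0
        base[0, 12:16] += pan_mean  # gene X high in PAN
        if mvp_boost is not None:
            base[0, 16:20] += mvp_boost
        df = {f"s{i}": base[:, i] for i in range(20)}
        return make_expression(df, niches=niches, index=["gX", "gY", "gZ"])

    def test_single_planted_marker_recovered(self):
        res = preprocess.region_marker_matrix(self._toy())
        table = res["table"]
        assert len(table) == 1
        assert table.iloc[0]["feature_id"] == "gX" and table.iloc[0]["niche"] == "PAN"
        assert res["counts"]["PAN"] == 1

    def test_null_matrix_yields_no_markers(self):
        res = preprocess.region_marker_matrix(self._toy(pan_mean=0.0))
        assert len(res["table"]) == 0

    def test_all_comparisons_rule_blocks_partial_winner(self):
        # gX higher in PAN than LE/IT/CT but even higher in MVP
        res = preprocess.region_marker_matrix(self._toy(mvp_boost=15.0))
        table = res["table"]
        assert not ((table["feature_id"] == "gX") & (table["niche"] == "PAN")).any()
        assert ((table["feature_id"] == "gX") & (table["niche"] == "MVP")).any()

    def test_niche_with_one_sample_rejected(self):
        niches = ["LE", "IT", "CT", "PAN", "MVP", "LE", "IT", "CT", "PAN"]
        df = {f"s{i}": [1.0, 2.0] for i in range(9)}
        m = make_expression(df, niches=niches, index=["a", "b"])
        with pytest.raises(TriaxisError):
            preprocess.region_marker_matrix(m)

    def test_recovers_planted_programs_on_synthetic_cohort(self):
        m, truth = synthetic.generate_regional_cohort(20, 1500, seed=13, modality="protein")
        tissue = m.subset_niches(["LE", "IT", "CT", "PAN", "MVP"])
        imp = preprocess.impute_missing(preprocess.presence_filter(tissue), seed=0)
        res = preprocess.region_marker_matrix(imp)
        table = res["table"]
        planted = {
            "LE_neuronal": "LE", "PAN_hypoxia": "PAN", "MVP_angio": "MVP",
            "CT_MYC": "CT", "CT_KRAS": "CT",
        }
        hits = total = 0
        program_genes = set()
        for prog, niche in planted.items():
            genes = set(truth.program_genes[prog])
            program_genes |= genes
            present = [g for g in genes if g in imp.feature_ids]
            total += len(present)
            hits += len(table[(table["niche"] == niche) & table["feature_id"].isin(genes)])
        assert hits / total >= 0.9
        # null genes exclude every planted program (the immune program is
        # genuinely elevated around MVP, so its genes are not null)
        all_program = {g for gs in truth.program_genes.values() for g in gs}
        null_calls = (~table["feature_id"].isin(all_program)).sum()
        n_null = imp.n_features - sum(g in imp.feature_ids for g in all_program)
        assert null_calls / n_null < 2 * 0.01
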