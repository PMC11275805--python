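"""Predictor machinery: subset enumeration, binning, splits, grouped
cross-validation, monotone constraints and model search."""

import numpy as np
import pandas as pd
import pytest

import dms_tki as dt
from dms_tki import mlmodel as ml


@pytest.fixture(scope="module")
def feature_table(library, conditions, effects):
    ft = dt.simulate_feature_table(library, conditions[1:], effects, seed=3)
    rng = np.random.default_rng(3)
    # ddG coefficient large enough that its component independent of llr
    # (the two are collinear through the control fitness) is identifiable
    ft["target"] = (2.0 * ft["llr"] - 1.5 * ft["ddG"]
                    + rng.normal(0, 0.1, len(ft)))
    return ft


@pytest.fixture(scope="module")
def splits(feature_table):
    return ml.make_splits(feature_table, ml.SplitSpec(
        heldout_inhibitors=("inhA1", "inhB1"), seed=0))


class TestEnumerate:
    @pytest.mark.parametrize("k,n", [(13, 8192), (0, 1), (3, 8)])
    def test_subset_counts(self, k, n):
        subs = ml.enumerate_feature_subsets(ml.OPTIONAL_FEATURES[:k])
        assert len(subs) == n
        assert len(set(subs)) == n            # all distinct

    def test_deterministic_binary_order(self):
        subs = ml.enumerate_feature_subsets(["a", "b"])
        assert subs == [(), ("a",), ("b",), ("a", "b")]

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ml.enumerate_feature_subsets(["a", "a"])


class TestBinning:
    def test_median_coding(self):
        df = pd.DataFrame({"position": [1] * 6, "wt_aa": "A", "mut_aa": "V",
                           "var_class": "missense", "inhibitor": "x",
                           "llr": 0.0,
                           "rf_score": [0.1, 0.2, 0.3, 1.5, 2.5, 3.5]})
        out = ml.bin_features(df, np.ones(6, bool),
                              breakpoints={"rf_score": [1, 2, 3]})
        # training values {0.1,0.2,0.3} share bin 0 -> all map to 0.2
        assert out["rf_score"].tolist()[:3] == [0.2, 0.2, 0.2]
        assert out["rf_score"].tolist()[3:] == [1.5, 2.5, 3.5]

    def test_monotone_features_pass_through(self, feature_table):
        out = ml.bin_features(feature_table, np.ones(len(feature_table), bool))
        for f in ml.NEVER_BINNED:
            pd.testing.assert_series_equal(out[f], feature_table[f])

    def test_constant_feature_degenerate(self):
        df = pd.DataFrame({"position": [1] * 4, "wt_aa": "A", "mut_aa": "V",
                           "var_class": "missense", "inhibitor": "x",
                           "llr": 0.0, "rf_score": [5.0] * 4})
        out = ml.bin_features(df, np.ones(4, bool))
        assert (out["rf_score"] == 5.0).all()

    def test_bin_count_bounded(self, feature_table):
        out = ml.bin_features(feature_table, np.ones(len(feature_table), bool),
                              n_bins=4)
        binned = [f for f in ml.OPTIONAL_FEATURES if f not in ml.NEVER_BINNED]
        for f in binned:
            assert out[f].nunique() <= 5

    def test_edge_values_fall_in_edge_bins(self):
        df = pd.DataFrame({"position": [1] * 5, "wt_aa": "A", "mut_aa": "V",
                           "var_class": "missense", "inhibitor": "x",
                           "llr": 0.0,
                           "rf_score": [1.0, 2.0, 3.0, -99.0, 99.0]})
        out = ml.bin_features(df, np.array([1, 1, 1, 0, 0], bool),
                              breakpoints={"rf_score": [1.5, 2.5]})
        assert out["rf_score"].iloc[3] == 1.0    # below lowest breakpoint
        assert out["rf_score"].iloc[4] == 3.0    # above highest


class TestSplits:
    def test_partition_exhaustive_disjoint(self, feature_table, splits):
        all_idx = set(splits.train) | set(splits.tune) | set(splits.test)
        assert all_idx == set(feature_table.index)
        assert not (set(splits.train) & set(splits.tune))
        assert not (set(splits.train) & set(splits.test))
        assert not (set(splits.tune) & set(splits.test))

    def test_heldout_inhibitor_rows_all_in_test(self, feature_table, splits):
        held = feature_table["inhibitor"].isin(["inhA1", "inhB1"])
        assert set(feature_table.index[held]) <= set(splits.test)

    def test_heldout_positions_and_aas_in_test(self, feature_table, splits):
        leak = feature_table.loc[list(splits.train) + list(splits.tune)]
        assert not leak["position"].isin(splits.heldout_positions).any()
        assert not leak["mut_aa"].isin(splits.heldout_amino_acids).any()

    def test_excluded_conditions_absent(self, feature_table):
        sp = ml.make_splits(feature_table, ml.SplitSpec(
            heldout_inhibitors=("inhA1", "inhB1"),
            excluded_conditions=frozenset({"inhA2"}), seed=0))
        covered = feature_table.loc[list(sp.train) + list(sp.tune) + list(sp.test)]
        assert "inhA2" not in set(covered["inhibitor"])

    def test_missing_heldout_inhibitor_errors(self, feature_table):
        with pytest.raises(ValueError, match="absent"):
            ml.make_splits(feature_table,
                           ml.SplitSpec(heldout_inhibitors=("nope", "inhB1")))

    def test_deterministic(self, feature_table):
        spec = ml.SplitSpec(heldout_inhibitors=("inhA1", "inhB1"), seed=4)
        a, b = ml.make_splits(feature_table, spec), ml.make_splits(feature_table, spec)
        assert list(a.train) == list(b.train) and list(a.test) == list(b.test)


class TestCVFolds:
    def test_positions_partitioned(self):
        folds = ml.make_cv_folds(range(230), list("ACDEFGHIKLMNPQRSTV"), k=10, seed=0)
        sizes = [len(p) for p, _ in folds]
        assert sizes == [23] * 10
        union = set().union(*(p for p, _ in folds))
        assert union == set(range(230))
        for i in range(10):
            for j in range(i + 1, 10):
                assert not (folds[i][0] & folds[j][0])

    def test_amino_acid_resampling(self):
        folds = ml.make_cv_folds(range(230), list("ACDEFGHIKLMNPQRSTV"), k=10, seed=0)
        assert all(len(a) == 2 for _, a in folds)

    def test_small_k(self):
        folds = ml.make_cv_folds([1, 2, 3, 4], list("AC"), k=2, seed=1)
        assert [len(p) for p, _ in folds] == [2, 2]

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            ml.make_cv_folds(range(10), list("AC"), k=1)


class TestFitModel:
    def test_llr_required(self, feature_table):
        with pytest.raises(ValueError, match="llr"):
            ml.fit_model(feature_table, ["ddG"], params={})

    def test_monotone_in_llr_and_ddg(self, feature_table):
        feats = ["llr", "ddG", "rf_score"]
        m, _, _ = ml.fit_model(feature_table, feats,
                               params={"max_iter": 80}, seed=0)
        rng = np.random.default_rng(0)
        base = feature_table[feats].sample(100, random_state=1).to_numpy()
        for col, direction in ((0, +1), (1, -1)):
            lo, hi = base.copy(), base.copy()
            hi[:, col] += np.abs(rng.normal(1.0, 0.5, 100))
            dp = m.predict(hi) - m.predict(lo)
            assert np.all(direction * dp >= -1e-9)

    def test_realizable_target_low_tune_mse(self, feature_table, splits):
        df = feature_table.copy()
        df["target"] = df["llr"]
        _, _, tune_mse = ml.fit_model(
            df.loc[splits.train], ["llr"], tune=df.loc[splits.tune],
            hp_budget=8, seed=0)
        assert tune_mse < 0.05

    def test_hyperparameter_search_deterministic(self, feature_table, splits):
        out = [ml.fit_model(feature_table.loc[splits.train], ["llr", "rf_score"],
                            tune=feature_table.loc[splits.tune],
                            hp_budget=5, seed=7)[1] for _ in range(2)]
        assert out[0] == out[1]


class TestModelSearch:
    def test_single_subset(self, feature_table, splits):
        res = ml.model_search(feature_table, splits, subsets=[("ddG",)],
                              hp_budget=2, k=3, seed=0)
        assert len(res) == 1
        assert res[0].features == ("llr", "ddG")
        assert res[0].test_pearson_per_inhibitor is not None
        # held-out inhibitors are fully in test; training inhibitors also
        # contribute test rows via held-out positions / amino acids
        assert {"inhA1", "inhB1"} <= set(res[0].test_pearson_per_inhibitor)

    def test_ranking_is_permutation(self, feature_table, splits):
        subsets = [(), ("ddG",), ("rf_score",), ("ddG", "rf_score")]
        res = ml.model_search(feature_table, splits, subsets=subsets,
                              hp_budget=2, k=3, seed=0)
        assert sorted(r.features for r in res) == sorted(
            (ml.LLR,) + s for s in subsets)
        cvs = [r.cv_pearson for r in res]
        assert cvs == sorted(cvs, reverse=True)

    def test_informative_feature_beats_llr_only(self, feature_table, splits):
        """Target depends on ddG beyond llr, so the two-feature model
        must out-predict the llr-only model on held-out data."""
        res = ml.model_search(feature_table, splits, subsets=[(), ("ddG",)],
                              hp_budget=4, k=5, seed=1)
        assert res[0].features == ("llr", "ddG")
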