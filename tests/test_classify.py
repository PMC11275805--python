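"""Resistance calling, GOF/LOF labels, hotspot aggregation and
cross-inhibitor differential analysis."""

import numpy as np
import pandas as pd
import pytest

import dms_tki as dt
from dms_tki.scoring import ScoreTable
from dms_tki.types import VARIANT_COLUMNS


def score_table(rows, name="inh", itype="I_a", se=0.05, df=np.inf):
    """Hand-built ScoreTable from (position, mut_aa, beta) triples."""
    from dms_tki.scoring import tail_probability
    df_ = pd.DataFrame(rows, columns=["position", "mut_aa", "beta"])
    df_["wt_aa"] = "A"
    df_["var_class"] = np.where(df_["mut_aa"] == "A", "synonymous",
                                np.where(df_["mut_aa"] == "*", "nonsense", "missense"))
    df_["se"] = se
    df_["df"] = df
    p_lt = tail_probability(df_["beta"].to_numpy(), df_["se"].to_numpy(),
                            df_["df"].to_numpy(), 0.0)
    df_["p_gt_wt"] = 1 - p_lt
    df_["p_lt_wt"] = p_lt
    df_["tail_prob_resist"] = tail_probability(
        df_["beta"].to_numpy(), df_["se"].to_numpy(), df_["df"].to_numpy(), 0.5)
    cols = VARIANT_COLUMNS + ["beta", "se", "df", "p_gt_wt", "p_lt_wt",
                              "tail_prob_resist"]
    return ScoreTable(df_[cols], dt.ConditionMeta(name, itype))


class TestCallResistance:
    def make_pair(self, inh_rows, dmso_rows, **kw):
        return dt.call_resistance(score_table(inh_rows),
                                  score_table(dmso_rows, "DMSO", "DMSO"), **kw)

    def test_clear_resistance_called(self):
        calls = self.make_pair([(1, "R", 1.2)], [(1, "R", -0.1)])
        assert calls["is_resistance"].iloc[0] == True  # noqa: E712

    def test_below_effect_threshold_not_called(self):
        calls = self.make_pair([(1, "R", 0.4)], [(1, "R", -0.1)])
        assert calls["is_resistance"].iloc[0] == False  # noqa: E712
        assert calls["tail_prob_resist"].iloc[0] > 0.5

    def test_dmso_advantage_disqualifies(self):
        calls = self.make_pair([(1, "R", 1.2)], [(1, "R", 0.3)])
        assert calls["is_resistance"].iloc[0] == False  # noqa: E712

    def test_synonymous_never_resistant(self):
        calls = self.make_pair([(1, "A", 1.2)], [(1, "A", 0.0)])
        assert calls["is_resistance"].iloc[0] == False  # noqa: E712

    def test_missing_dmso_gives_na(self):
        calls = self.make_pair([(1, "R", 1.2), (2, "K", 1.2)],
                               [(1, "R", -0.1)])
        assert pd.isna(calls.set_index("position")["is_resistance"][2])

    def test_planted_recovery(self, noisy_scores, effects, conditions):
        """Sensitivity and specificity on the simulated screen: planted
        resistance pairs are recovered, planted-neutral variants are not
        falsely called."""
        from conftest import RES_I
        calls = dt.call_resistance(noisy_scores["inhA1"], noisy_scores["DMSO"])
        idx = calls.set_index(["position", "mut_aa"])
        planted = idx.loc[list(RES_I), "is_resistance"]
        assert planted.mean() >= 0.9
        dmso_truth = effects[effects["condition"] == "DMSO"].set_index(
            ["position", "mut_aa"])["true_score"]
        inh_truth = effects[effects["condition"] == "inhA1"].set_index(
            ["position", "mut_aa"])["true_score"]
        neutral = idx.join(dmso_truth.rename("s0")).join(inh_truth.rename("s1"))
        neutral = neutral[(neutral["s1"] <= 0.0)]
        fpr = (neutral["is_resistance"] == True).mean()  # noqa: E712
        assert fpr <= 0.05


class TestGofLof:
    @pytest.mark.parametrize("gamma,expect", [
        (0.9, "GOF"), (-0.4, "LOF"), (0.3, "neutral"), (0.75, "neutral"), (0.0, "neutral")])
    def test_threshold_rule(self, gamma, expect):
        out = dt.classify_gof_lof(pd.Series([gamma]))
        assert out["category"].iloc[0] == expect
        assert not (out["gof"].iloc[0] and out["lof"].iloc[0])

    def test_na_propagates(self):
        out = dt.classify_gof_lof(pd.Series([np.nan]))
        assert pd.isna(out["gof"].iloc[0]) and pd.isna(out["category"].iloc[0])

    def test_within_condition_bimodal(self, noisy_scores):
        labels = dt.classify_within_condition(noisy_scores["DMSO"])
        assert set(labels.unique()) <= {"GOF", "LOF", "neutral"}
        # the control has a large deleterious component -> many LOF calls
        assert (labels == "LOF").mean() > 0.2


class TestResistancePositions:
    def test_set_semantics(self):
        calls = dt.call_resistance(
            score_table([(1, "R", 1.2), (1, "K", 1.3), (2, "M", 0.1)]),
            score_table([(1, "R", -0.1), (1, "K", -0.2), (2, "M", 0.0)],
                        "DMSO", "DMSO"))
        assert dt.resistance_positions(calls) == {1}

    def test_empty(self):
        calls = dt.call_resistance(
            score_table([(1, "R", 0.0)]), score_table([(1, "R", 0.0)], "DMSO", "DMSO"))
        assert dt.resistance_positions(calls) == set()


@pytest.fixture()
def toy_panel():
    """Four inhibitors over two major types with hand-set calls."""
    conds = [dt.ConditionMeta("DMSO", "DMSO"),
             dt.ConditionMeta("a1", "I_a"), dt.ConditionMeta("a2", "I_b"),
             dt.ConditionMeta("b1", "II"), dt.ConditionMeta("b2", "II")]
    dmso = score_table([(1, "R", -0.1), (1, "K", -0.2), (2, "M", -0.1),
                        (3, "W", -0.3)], "DMSO", "DMSO")
    betas = {
        # variant 1R resistant to both type I inhibitors and b1 (shared I+II)
        "a1": [(1, "R", 1.2), (1, "K", 1.1), (2, "M", 0.1), (3, "W", -1.0)],
        "a2": [(1, "R", 1.3), (1, "K", 0.2), (2, "M", 0.0), (3, "W", -1.2)],
        "b1": [(1, "R", 1.1), (1, "K", 0.1), (2, "M", 1.4), (3, "W", -0.9)],
        "b2": [(1, "R", 0.2), (1, "K", 0.0), (2, "M", 1.2), (3, "W", -1.1)],
    }
    calls = {n: dt.call_resistance(score_table(b, n), dmso)
             for n, b in betas.items()}
    return conds, calls


class TestHotspots:
    def test_hand_counts(self, toy_panel):
        conds, calls = toy_panel
        hs = dt.hotspot_counts(calls, conds)
        assert hs.count(1, "I") == 3     # 1R x2 inhibitors + 1K x1
        assert hs.count(1, "II") == 1    # 1R under b1
        assert hs.count(2, "II") == 2    # 2M under b1 and b2
        assert hs.count(2, "I") == 0 and hs.count(3, "I") == 0

    def test_totals_match_call_table(self, toy_panel):
        conds, calls = toy_panel
        hs = dt.hotspot_counts(calls, conds)
        meta = {c.name: c for c in conds}
        for t in ("I", "II"):
            total = sum((c["is_resistance"] == True).sum()  # noqa: E712
                        for n, c in calls.items() if meta[n].major_type == t)
            assert hs.counts.loc[hs.counts["inhibitor_type"] == t, "count"].sum() == total

    def test_shared_sets(self, toy_panel):
        conds, calls = toy_panel
        hs = dt.hotspot_counts(calls, conds)
        keys = {(v.position, v.mut_aa) for v in hs.shared_sets[("I", "II")]}
        assert keys == {(1, "R")}        # resistant under a type of each
        only_I = {(v.position, v.mut_aa) for v in hs.shared_sets[("I",)]}
        assert only_I == {(1, "K")}

    def test_no_calls_all_zero(self):
        conds = [dt.ConditionMeta("DMSO", "DMSO"), dt.ConditionMeta("a1", "I_a"),
                 dt.ConditionMeta("b1", "II")]
        dmso = score_table([(1, "R", 0.0)], "DMSO", "DMSO")
        calls = {n: dt.call_resistance(score_table([(1, "R", 0.0)], n), dmso)
                 for n in ("a1", "b1")}
        hs = dt.hotspot_counts(calls, conds)
        assert (hs.counts["count"] == 0).all()
        assert all(len(s) == 0 for s in hs.shared_sets.values())


class TestExclusiveSets:
    def test_brute_force_equivalence(self, toy_panel):
        conds, calls = toy_panel
        excl = dt.type_exclusive_resistance(calls, conds)
        meta = {c.name: c for c in conds}
        # independent enumeration over every variant and inhibitor
        res_by_type = {"I": set(), "II": set()}
        for n, c in calls.items():
            for _, row in c[c["is_resistance"] == True].iterrows():  # noqa: E712
                res_by_type[meta[n].major_type].add((row["position"], row["mut_aa"]))
        expect_I = res_by_type["I"] - res_by_type["II"]
        expect_II = res_by_type["II"] - res_by_type["I"]
        assert {(v.position, v.mut_aa) for v in excl["I"]} == expect_I
        assert {(v.position, v.mut_aa) for v in excl["II"]} == expect_II

    def test_disjoint_and_subset(self, toy_panel):
        conds, calls = toy_panel
        excl = dt.type_exclusive_resistance(calls, conds)
        assert not (excl["I"] & excl["II"])


class TestDifferentialPairs:
    def make_recentered(self, gammas, name):
        df = pd.DataFrame(gammas, columns=["position", "mut_aa", "gamma"])
        df["wt_aa"] = "A"
        df["var_class"] = "missense"
        df["beta_inh"] = df["gamma"]
        df["beta_dmso"] = 0.0
        return dt.RecenteredScores(df, name)

    def make_calls(self, rows, resistant):
        df = pd.DataFrame(rows, columns=["position", "mut_aa", "gamma"])
        df["wt_aa"] = "A"
        df["var_class"] = "missense"
        df["is_resistance"] = pd.array(
            [(p, m) in resistant for p, m, _ in rows], dtype="boolean")
        return df

    def test_hand_enumeration(self):
        rows_a = [(i, "R", g) for i, g in enumerate(
            [1.0, 1.0, 0.9, -0.5, 0.2, 1.2, -0.8, 0.0, 2.0, 0.76])]
        rows_b = [(i, "R", g) for i, g in enumerate(
            [-0.6, 0.2, -0.1, 1.0, -0.9, -0.2, 1.5, 0.0, 0.3, -0.01])]
        res_a = {(i, "R") for i in (0, 1, 2, 5, 9)}
        res_b = {(3, "R"), (6, "R")}
        a, b = dt.differential_pairs(
            self.make_recentered(rows_a, "a"), self.make_recentered(rows_b, "b"),
            self.make_calls(rows_a, res_a), self.make_calls(rows_b, res_b))
        # GOF in a (gamma>0.75, resistant) and LOF in b (gamma<0)
        assert {v.position for v in a} == {0, 2, 5, 9}
        assert {v.position for v in b} == {3, 6}

    def test_lax_mode_ignores_resistance_filter(self):
        rows_a = [(1, "R", 1.0)]
        rows_b = [(1, "R", -0.5)]
        a, _ = dt.differential_pairs(
            self.make_recentered(rows_a, "a"), self.make_recentered(rows_b, "b"),
            self.make_calls(rows_a, set()), self.make_calls(rows_b, set()),
            require_resistance=False)
        assert {v.position for v in a} == {1}
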