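"""Statistical engine: outlier screening, assumption checks, mixed-design
ANOVA against brute-force and pingouin oracles, Tukey-Kramer post-hocs and
the control-pooling planned contrasts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rewardops.stats import (
    AnovaSpec,
    check_assumptions,
    mixed_anova,
    planned_contrast_pooling,
    screen_outliers,
    sidak_adjust,
    tukey_posthoc,
)


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_mixed_1w(df, dv, subject, between, within):
    """Loop-based classical mixed ANOVA (1 between, 1 within) computed from
    definitional sums over cell means; independent of the vectorized path."""
    subs = sorted(df[subject].unique())
    wlevels = sorted(df[within].unique())
    k = len(wlevels)
    grp = {s: df.loc[df[subject] == s, between].iloc[0] for s in subs}
    y = {
        (s, w): df.loc[(df[subject] == s) & (df[within] == w), dv].mean()
        for s in subs
        for w in wlevels
    }
    gm = np.mean(list(y.values()))
    sub_mean = {s: np.mean([y[(s, w)] for w in wlevels]) for s in subs}
    glabels = sorted(set(grp.values()))
    g_sub = {g: [s for s in subs if grp[s] == g] for g in glabels}
    g_mean = {g: np.mean([sub_mean[s] for s in g_sub[g]]) for g in glabels}
    w_mean = {w: np.mean([y[(s, w)] for s in subs]) for w in wlevels}
    gw_mean = {
        (g, w): np.mean([y[(s, w)] for s in g_sub[g]])
        for g in glabels
        for w in wlevels
    }
    ss_group = k * sum(len(g_sub[g]) * (g_mean[g] - gm) ** 2 for g in glabels)
    ss_sub = k * sum((sub_mean[s] - g_mean[grp[s]]) ** 2 for s in subs)
    ss_w = len(subs) * sum((w_mean[w] - gm) ** 2 for w in wlevels)
    ss_gw = sum(
        len(g_sub[g]) * (gw_mean[(g, w)] - g_mean[g] - w_mean[w] + gm) ** 2
        for g in glabels
        for w in wlevels
    )
    ss_err = sum(
        (y[(s, w)] - sub_mean[s] - gw_mean[(grp[s], w)] + g_mean[grp[s]]) ** 2
        for s in subs
        for w in wlevels
    )
    n, g = len(subs), len(glabels)
    out = {
        "group": (ss_group, g - 1, ss_sub, n - g),
        "within": (ss_w, k - 1, ss_err, (n - g) * (k - 1)),
        "interaction": (ss_gw, (g - 1) * (k - 1), ss_err, (n - g) * (k - 1)),
    }
    return {
        name: {
            "SS": ss,
            "df1": df1,
            "df2": df2,
            "F": (ss / df1) / (ss_e / df2),
        }
        for name, (ss, df1, ss_e, df2) in out.items()
    }


def anova_2x2_fixture():
    data = {
        ("g1", "s1"): (3.0, 5.0), ("g1", "s2"): (4.0, 6.0),
        ("g1", "s3"): (5.0, 9.0), ("g1", "s4"): (6.0, 8.0),
        ("g2", "s5"): (7.0, 10.0), ("g2", "s6"): (8.0, 12.0),
        ("g2", "s7"): (9.0, 11.0), ("g2", "s8"): (10.0, 13.0),
    }
    rows = []
    for (g, s), (t1, t2) in data.items():
        rows.append({"mouse_id": s, "group": g, "test": 1, "dv": t1})
        rows.append({"mouse_id": s, "group": g, "test": 2, "dv": t2})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


class TestScreenOutliers:
    def test_gross_outlier_flagged(self):
        flags = screen_outliers([1.0, 2.0, 3.0, 4.0, 100.0])
        assert list(flags) == [False, False, False, False, True]

    def test_identical_values_unflagged(self):
        assert not screen_outliers(np.full(10, 2.0)).any()

    def test_small_group_skipped(self, caplog):
        with caplog.at_level("WARNING"):
            flags = screen_outliers([1.0, 2.0, 100.0])
        assert not flags.any()

    def test_clean_normal_flag_rate(self):
        """On clean normal samples the boxplot rule flags < 5% on average."""
        rng = np.random.default_rng(0)
        rates = [
            screen_outliers(rng.normal(size=20)).mean() for _ in range(500)
        ]
        assert np.mean(rates) < 0.05


class TestCheckAssumptions:
    def test_normal_sample_passes(self):
        rng = np.random.default_rng(1)
        rep = check_assumptions(rng.normal(size=100), ["a"] * 50 + ["b"] * 50)
        assert rep["shapiro"]["a"]["p"] > 0.05
        assert rep["levene"]["p"] > 0.05

    def test_constant_sample_degenerate(self):
        rep = check_assumptions(np.full(10, 3.0), ["a"] * 10)
        assert rep["shapiro"]["a"]["degenerate"]

    def test_variance_ratio_detected(self):
        rng = np.random.default_rng(2)
        v = np.concatenate([rng.normal(0, 1, 20), rng.normal(0, 10, 20)])
        rep = check_assumptions(v, ["a"] * 20 + ["b"] * 20)
        assert rep["levene"]["p"] < 0.05


class TestMixedAnova:
    def test_no_group_effect_gives_zero_f(self):
        rows = []
        for g, subs in (("a", "pq"), ("b", "rs")):
            for s in subs:
                for w, val in ((1, 1.0), (2, 3.0)):
                    rows.append({"mouse_id": g + s, "group": g, "test": w, "dv": val})
        table = mixed_anova(
            pd.DataFrame(rows),
            AnovaSpec(dv="dv", subject="mouse_id", between="group", within=("test",)),
        )
        assert table.set_index("effect").loc["group", "F"] == pytest.approx(0.0)

    def test_balanced_2x2_matches_brute_force(self):
        df = anova_2x2_fixture()
        spec = AnovaSpec(dv="dv", subject="mouse_id", between="group", within=("test",))
        mine = mixed_anova(df, spec).set_index("effect")
        oracle = brute_force_mixed_1w(df, "dv", "mouse_id", "group", "test")
        for eff, key in (("group", "group"), ("test", "within"), ("group:test", "interaction")):
            assert mine.loc[eff, "F"] == pytest.approx(oracle[key]["F"], rel=1e-8)
            assert mine.loc[eff, "SS"] == pytest.approx(oracle[key]["SS"], rel=1e-8)
            assert mine.loc[eff, "df1"] == oracle[key]["df1"]
            assert mine.loc[eff, "df2"] == oracle[key]["df2"]

    def test_unbalanced_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(0)
        rows = []
        for g, n in (("a", 5), ("b", 7)):
            for i in range(n):
                base = rng.normal()
                for w in range(3):
                    rows.append(
                        {"s": f"{g}{i}", "g": g, "w": w,
                         "y": base + 0.5 * w + (0.8 if g == "b" else 0) + rng.normal(0, 0.5)}
                    )
        df = pd.DataFrame(rows)
        mine = mixed_anova(
            df, AnovaSpec(dv="y", subject="s", between="g", within=("w",))
        ).set_index("effect")
        ref = pg.mixed_anova(df, dv="y", within="w", subject="s", between="g")
        ref = ref.set_index("Source")
        assert mine.loc["g", "F"] == pytest.approx(ref.loc["g", "F"], rel=1e-9)
        assert mine.loc["w", "F"] == pytest.approx(ref.loc["w", "F"], rel=1e-9)
        assert mine.loc["g:w", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9
        )

    def test_three_way_decomposition_sums_to_total(self):
        """On balanced data the component SS (including all error strata)
        partition the total SS exactly."""
        rng = np.random.default_rng(4)
        rows = []
        for g in ("a", "b"):
            for i in range(4):
                base = rng.normal()
                for t in (1, 3):
                    for b in range(5):
                        rows.append(
                            {"s": f"{g}{i}", "g": g, "t": t, "b": b,
                             "y": base + rng.normal()}
                        )
        df = pd.DataFrame(rows)
        spec = AnovaSpec(dv="y", subject="s", between="g", within=("t", "b"))
        table = mixed_anova(df, spec)
        y = df["y"].to_numpy()
        ss_total = np.sum((y - y.mean()) ** 2)
        # effect SS plus the four error strata (subjects; subjects x each
        # within combination) partition the total
        err_ss = (
            table.drop_duplicates("error_term")
            .apply(lambda r: r["MS_error"] * r["df2"], axis=1)
            .sum()
        )
        assert table["SS"].sum() + err_ss == pytest.approx(ss_total, rel=1e-9)

    def test_three_way_reduces_to_two_way_when_factor_constant(self):
        """Averaging out one within factor reproduces the remaining 1B x 1W
        analysis, and the 3-way within-factor F agrees with a loop oracle
        applied to the transposed design."""
        rng = np.random.default_rng(5)
        rows = []
        for g in ("a", "b"):
            for i in range(4):
                base = rng.normal()
                for t in (1, 2):
                    for b in (1, 2, 3):
                        rows.append(
                            {"s": f"{g}{i}", "g": g, "t": t, "b": b,
                             "y": base + 0.4 * t + 0.2 * b + rng.normal(0, 0.3)}
                        )
        df = pd.DataFrame(rows)
        three = mixed_anova(
            df, AnovaSpec(dv="y", subject="s", between="g", within=("t", "b"))
        ).set_index("effect")
        # collapse b: the (g, t) part of the 3-way equals the 2-way on means
        dfa = df.groupby(["s", "g", "t"], as_index=False)["y"].mean()
        two = mixed_anova(
            dfa, AnovaSpec(dv="y", subject="s", between="g", within=("t",))
        ).set_index("effect")
        oracle = brute_force_mixed_1w(dfa, "y", "s", "g", "t")
        assert three.loc["g", "F"] == pytest.approx(two.loc["g", "F"], rel=1e-9)
        assert three.loc["t", "F"] == pytest.approx(oracle["within"]["F"], rel=1e-9)
        assert three.loc["g:t", "F"] == pytest.approx(
            oracle["interaction"]["F"], rel=1e-9
        )

    def test_constant_dv_degenerate(self):
        df = anova_2x2_fixture().assign(dv=5.0)
        spec = AnovaSpec(dv="dv", subject="mouse_id", between="group", within=("test",))
        table = mixed_anova(df, spec)
        assert table.attrs["degenerate"]
        assert (table["F"] == 0.0).all()

    def test_incomplete_subjects_dropped_listwise(self):
        df = anova_2x2_fixture()
        df = df[~((df["mouse_id"] == "s1") & (df["test"] == 2))]
        spec = AnovaSpec(dv="dv", subject="mouse_id", between="group", within=("test",))
        table = mixed_anova(df, spec)
        assert table.attrs["n_dropped"] == 1
        assert table.attrs["n_subjects"] == 7

    def test_single_level_factor_rejected(self):
        df = anova_2x2_fixture()
        df["group"] = "g1"
        spec = AnovaSpec(dv="dv", subject="mouse_id", between="group", within=("test",))
        with pytest.raises(ValueError):
            mixed_anova(df, spec)


class TestTukey:
    def test_identical_means_p_one(self):
        tab = tukey_posthoc({"a": 2.0, "b": 2.0}, {"a": 5, "b": 5}, 1.0, 8.0)
        assert tab["p_adj"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_q_table_lookup(self):
        """k=3, df=12: the 5% critical studentized range is 3.77."""
        # place one pair exactly at the critical q
        se = np.sqrt(1.0 / 2.0 * (1 / 5 + 1 / 5))
        means = {"a": 0.0, "b": 3.77 * se, "c": 0.0}
        tab = tukey_posthoc(means, {k: 5 for k in means}, 1.0, 12.0)
        p = tab.set_index(["A", "B"]).loc[("a", "b"), "p_adj"]
        assert p == pytest.approx(0.05, abs=0.002)

    def test_separated_means_p_to_zero(self):
        tab = tukey_posthoc({"a": 0.0, "b": 50.0}, {"a": 5, "b": 5}, 0.01, 8.0)
        assert tab["p_adj"].iloc[0] < 1e-6

    def test_sidak(self):
        assert sidak_adjust([0.05])[0] == pytest.approx(0.05)
        assert sidak_adjust([0.02, 0.5])[0] == pytest.approx(1 - 0.98**2)


class TestPlannedContrasts:
    def test_pooling_when_controls_agree(self):
        rng = np.random.default_rng(6)
        v = np.concatenate(
            [rng.normal(0, 1, 10), rng.normal(0, 1, 10), rng.normal(2.0, 1, 10)]
        )
        g = ["c1"] * 10 + ["c2"] * 10 + ["exp"] * 10
        rep = planned_contrast_pooling(v, g, ("c1", "c2"), "exp")
        assert rep.pooled
        assert rep.final[0]["p"] < 0.05

    def test_all_identical_nothing_significant(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=30)
        g = ["c1"] * 10 + ["c2"] * 10 + ["exp"] * 10
        rep = planned_contrast_pooling(v, g, ("c1", "c2"), "exp")
        assert rep.pooled
        assert rep.final[0]["p"] > 0.05

    def test_pooling_refused_when_controls_differ(self):
        rng = np.random.default_rng(8)
        v = np.concatenate(
            [rng.normal(0, 0.5, 10), rng.normal(5, 0.5, 10), rng.normal(2.5, 0.5, 10)]
        )
        g = ["c1"] * 10 + ["c2"] * 10 + ["exp"] * 10
        rep = planned_contrast_pooling(v, g, ("c1", "c2"), "exp")
        assert not rep.pooled
        assert len(rep.final) == 2

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError):
            planned_contrast_pooling([1, 2], ["c1", "exp"], ("c1", "c2"), "exp")


class TestPermutationCrossCheck:
    def test_ttest_matches_label_permutation(self):
        """Two-group t-test p agrees with a 10,000-shuffle label-permutation
        p within Monte-Carlo error on fixture data."""
        rng = np.random.default_rng(9)
        a = rng.normal(0.0, 1.0, 12)
        b = rng.normal(1.0, 1.0, 12)
        t_obs, p_t = sps.ttest_ind(a, b)
        pooled = np.concatenate([a, b])
        n = len(a)
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            t, _ = sps.ttest_ind(perm[:n], perm[n:])
            count += abs(t) >= abs(t_obs)
        p_perm = (count + 1) / (n_perm + 1)
        mc_err = 3 * np.sqrt(p_t * (1 - p_t) / n_perm)
        assert abs(p_perm - p_t) < max(mc_err, 0.005)
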