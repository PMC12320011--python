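import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from eegfmri.groupstats import (
    consistency_report,
    fdr_correct,
    one_sample_t,
    posthoc_pairwise,
    rm_anova,
    shapiro_wilk,
)


def bh_stepup_oracle(p, q=0.05):
    """Benjamini-Hochberg by its definition: largest k with p_(k) <= k q / m."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    flags = np.zeros(m, bool)
    kmax = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            kmax = k
    flags[order[:kmax]] = True
    return flags


class TestOneSampleT:
    def test_symmetric_pair_gives_zero(self):
        t, p, df = one_sample_t([-1.0, 1.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert df == 1

    def test_hand_computed_example(self):
        t, p, df = one_sample_t([2.0, 4.0, 6.0])
        assert t == pytest.approx(2 * np.sqrt(3), rel=1e-12)
        assert df == 2

    def test_zero_sd_reported_missing(self):
        t, p, df = one_sample_t([3.0, 3.0, 3.0])
        assert np.isnan(t) and np.isnan(p)

    def test_null_rejection_rate_calibrated(self):
        # 2000 null families of n=23: rejection rate within the exact
        # binomial 95% CI around 0.05
        rng = np.random.default_rng(13)
        reps = 2000
        rejections = sum(one_sample_t(rng.standard_normal(23))[1] < 0.05
                         for _ in range(reps))
        lo, hi = sps.binom.interval(0.95, reps, 0.05)
        assert lo <= rejections <= hi

    def test_matches_scipy(self, rng):
        x = rng.standard_normal(15) + 0.3
        t, p, df = one_sample_t(x)
        ref = sps.ttest_1samp(x, 0.0)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)


class TestShapiroWilk:
    def test_normal_scores_high_w(self):
        q = sps.norm.ppf((np.arange(1, 21) - 0.5) / 20)
        w, p = shapiro_wilk(q)
        assert w > 0.95

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk(np.ones(10))

    def test_bimodal_sample_rejected_as_nonnormal(self):
        x = np.r_[np.full(10, -1.0), np.full(10, 1.0)]
        x += np.linspace(-1e-6, 1e-6, 20)   # break exact ties
        _, p = shapiro_wilk(x)
        assert p < 0.05


class TestFDR:
    def test_stepup_rule_by_hand(self):
        flags, thresh = fdr_correct(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
        assert flags.all()
        assert thresh == pytest.approx(0.04)

    def test_all_ones_none_significant(self):
        flags, thresh = fdr_correct(np.ones(10))
        assert not flags.any() and thresh == 0.0

    def test_single_p_reduces_to_raw_threshold(self):
        flags, _ = fdr_correct(np.array([0.04]), q=0.05)
        assert flags[0]

    def test_matches_stepup_oracle_on_random_families(self, rng):
        for _ in range(120):
            m = rng.integers(1, 30)
            p = rng.random(m) ** rng.uniform(0.5, 3.0)
            flags, _ = fdr_correct(p, q=0.05)
            np.testing.assert_array_equal(flags, bh_stepup_oracle(p, 0.05))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bh_monotonicity(self, seed):
        g = np.random.default_rng(seed)
        p = g.random(12)
        flags, _ = fdr_correct(p)
        lowered = p.copy()
        i = int(g.integers(0, 12))
        lowered[i] *= 0.5
        flags2, _ = fdr_correct(lowered)
        # lowering one p never removes a previously significant flag
        assert not np.any(flags & ~flags2)

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct(np.array([]))


class TestRMAnova:
    def test_two_level_factor_equals_squared_paired_t(self, rng):
        rows = []
        for s in range(9):
            base = rng.standard_normal()
            rows.append({"subject": s, "cond": "a", "y": base + rng.standard_normal()})
            rows.append({"subject": s, "cond": "b",
                         "y": base + 0.4 + rng.standard_normal()})
        df = pd.DataFrame(rows)
        table = rm_anova(df, dv="y", within=["cond"])
        piv = df.pivot(index="subject", columns="cond", values="y")
        t, _ = sps.ttest_rel(piv["a"], piv["b"])
        assert table["F"].iloc[0] == pytest.approx(t**2, abs=1e-8)

    def test_constant_response_all_f_zero(self):
        rows = [{"subject": s, "A": a, "B": b, "y": 2.5}
                for s in range(4) for a in "xy" for b in "uv"]
        table = rm_anova(pd.DataFrame(rows), dv="y", within=["A", "B"])
        assert np.allclose(table["F"], 0.0)

    def test_three_subject_2x2_matches_bruteforce_ss(self, rng):
        rows = []
        for s in range(3):
            for a in (0, 1):
                for b in (0, 1):
                    rows.append({"subject": s, "A": a, "B": b,
                                 "y": rng.standard_normal() + 0.7 * a + 0.3 * a * b})
        df = pd.DataFrame(rows)
        table = rm_anova(df, dv="y", within=["A", "B"]).set_index("effect")
        y = df.pivot_table(index="subject", columns=["A", "B"], values="y")
        grand = y.to_numpy().mean()
        # explicit sums-of-squares decomposition from cell means
        mean_a = y.T.groupby(level="A").mean().T.to_numpy()   # subj x A
        mean_b = y.T.groupby(level="B").mean().T.to_numpy()
        ss_a = 2 * 3 * ((mean_a.mean(axis=0) - grand) ** 2).sum()
        ss_b = 2 * 3 * ((mean_b.mean(axis=0) - grand) ** 2).sum()
        cell = y.to_numpy().reshape(3, 2, 2)
        cell_mean = cell.mean(axis=0)
        ss_ab = 3 * ((cell_mean - cell_mean.mean(axis=1, keepdims=True)
                      - cell_mean.mean(axis=0, keepdims=True) + grand) ** 2).sum()
        assert table.loc["A", "ss"] == pytest.approx(ss_a, abs=1e-10)
        assert table.loc["B", "ss"] == pytest.approx(ss_b, abs=1e-10)
        assert table.loc["A x B", "ss"] == pytest.approx(ss_ab, abs=1e-10)

    def test_matches_statsmodels_anovarm(self, rng):
        rows = [{"subject": f"s{s}", "A": f"a{a}", "B": f"b{b}",
                 "y": rng.standard_normal() + 0.5 * a}
                for s in range(6) for a in range(3) for b in range(2)]
        df = pd.DataFrame(rows)
        mine = rm_anova(df, dv="y", within=["A", "B"]).set_index("effect")
        from statsmodels.stats.anova import AnovaRM

        ref = AnovaRM(df, "y", "subject", within=["A", "B"]).fit().anova_table
        for eff, ref_name in [("A", "A"), ("B", "B"), ("A x B", "A:B")]:
            assert mine.loc[eff, "F"] == pytest.approx(
                ref.loc[ref_name, "F Value"], rel=1e-8)

    def test_mixed_design_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        rows = []
        for g in ("g1", "g2"):
            for s in range(5):
                for w in range(3):
                    rows.append({"subject": f"{g}{s}", "grp": g, "W": f"w{w}",
                                 "y": rng.standard_normal()
                                 + (0.8 + 0.3 * w) * (g == "g2")})
        df = pd.DataFrame(rows)
        mine = rm_anova(df, dv="y", within=["W"], between="grp").set_index("effect")
        ref = pg.mixed_anova(df, dv="y", within="W", subject="subject",
                             between="grp").set_index("Source")
        assert mine.loc["grp", "F"] == pytest.approx(ref.loc["grp", "F"], rel=1e-8)
        assert mine.loc["W", "F"] == pytest.approx(ref.loc["W", "F"], rel=1e-8)
        assert mine.loc["grp x W", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-8)

    def test_unbalanced_design_rejected_naming_cells(self):
        rows = [{"subject": s, "A": a, "y": 0.0}
                for s in range(3) for a in "xy"]
        rows.pop()          # remove one cell
        with pytest.raises(ValueError, match="crossing|balanced"):
            rm_anova(pd.DataFrame(rows), dv="y", within=["A"])


class TestPosthoc:
    @pytest.fixture()
    def crossing(self, rng):
        rows = []
        for d in ("d1", "d2", "d3"):
            for s in range(4):
                sid = f"{d}_{s}"
                for rsn in [f"R{i}" for i in range(7)]:
                    for band in [f"b{i}" for i in range(5)]:
                        rows.append({"subject": sid, "dataset": d, "rsn": rsn,
                                     "band": band,
                                     "y": rng.standard_normal() * 0.1})
        return pd.DataFrame(rows)

    def test_family_size_3x7x5_is_105(self, crossing):
        out = posthoc_pairwise(crossing, dv="y",
                               effect=["dataset", "rsn", "band"],
                               between="dataset")
        assert (out["family_size"] == 105).all()

    def test_small_raw_p_capped_at_one(self, crossing):
        out = posthoc_pairwise(crossing, dv="y",
                               effect=["dataset", "rsn", "band"],
                               between="dataset")
        raw = out["p_raw"]
        adj = out["p_adjusted"]
        np.testing.assert_allclose(adj, np.minimum(1.0, raw * 105))
        assert (adj[raw > 0.01] == 1.0).all()   # 0.01 x 105 > 1

    def test_family_of_one_keeps_raw_p(self, rng):
        rows = [{"subject": s, "c": "only", "y": rng.standard_normal()}
                for s in range(6)] + \
               [{"subject": s, "c": "two", "y": rng.standard_normal() + 1}
                for s in range(6)]
        df = pd.DataFrame(rows)
        out = posthoc_pairwise(df, dv="y", effect=["c"])
        assert out["family_size"].iloc[0] == 2
        # family = product of level counts; with a single factor of 2 levels
        np.testing.assert_allclose(out["p_adjusted"],
                                   np.minimum(1.0, out["p_raw"] * 2))

    def test_unknown_effect_rejected(self, crossing):
        with pytest.raises(ValueError):
            posthoc_pairwise(crossing, dv="y", effect=["nope"])


class TestConsistencyReport:
    def _null_avg(self, rng, n_subj=6, n_cells=20):
        rows = []
        for s in range(n_subj):
            for c in range(n_cells):
                rows.append({"subject": f"s{s}", "space": "pooled",
                             "rsn": f"R{c % 4}", "band": f"b{c % 5}",
                             "delay": float(c), "r": rng.standard_normal() * 0.1})
        return pd.DataFrame(rows)

    def test_columns_and_flags_consistent(self, rng):
        rep = consistency_report(self._null_avg(rng))
        assert {"group", "space", "rsn", "band", "delay", "n", "mean_r", "t",
                "p", "shapiro_W", "shapiro_p", "fdr_significant",
                "uncorrected_significant"} <= set(rep.columns)
        assert (rep.loc[rep["fdr_significant"], "p"]
                <= rep.loc[rep["fdr_significant"], "p_threshold_family"]).all()

    def test_single_subject_group_rejected(self):
        df = pd.DataFrame([{"subject": "s0", "space": "pooled", "rsn": "R",
                            "band": "b", "delay": 6.0, "r": 0.1}])
        with pytest.raises(ValueError):
            consistency_report(df)

    def test_planted_effect_detected(self, rng):
        df = self._null_avg(rng, n_subj=12)
        df.loc[(df["rsn"] == "R0") & (df["band"] == "b0"), "r"] += 0.5
        rep = consistency_report(df)
        planted = rep[(rep["rsn"] == "R0") & (rep["band"] == "b0")]
        assert planted["fdr_significant"].all()
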