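import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from stiflemorph.stats import (
    art_anova,
    bland_altman,
    bonferroni,
    build_summary,
    gate_assumptions,
    icc_agreement,
    kruskal_wallis,
    posthoc_pairwise,
    ranksum,
)


def kw_statistic_oracle(groups):
    """Independent H computation: midranks by hand, tie-corrected."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2.0) ** 2
        start += len(g)
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie


class TestGateAssumptions:
    def test_null_gaussian_groups_rarely_flagged(self):
        rng = np.random.default_rng(0)
        bartlett_ok = 0
        for _ in range(100):
            groups = [rng.normal(0, 1, 50) for _ in range(3)]
            if gate_assumptions(groups).bartlett_p > 0.05:
                bartlett_ok += 1
        assert bartlett_ok >= 90

    def test_constant_group_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            gate_assumptions([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])

    def test_inflated_variance_detected(self):
        rng = np.random.default_rng(1)
        detected = 0
        for _ in range(100):
            groups = [rng.normal(0, 1, 50), rng.normal(0, 1, 50), rng.normal(0, math.sqrt(10), 50)]
            if gate_assumptions(groups).bartlett_p < 0.05:
                detected += 1
        assert detected >= 90

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            gate_assumptions([[1.0, 2.0]])


class TestKruskalWallis:
    def test_identical_groups(self):
        r = kruskal_wallis([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_hand_ranked_value(self):
        r = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert r.statistic == pytest.approx(7.2, abs=1e-9)
        assert r.df == (2,)

    def test_matches_independent_oracle(self, rng):
        for _ in range(20):
            groups = [rng.normal(size=rng.integers(4, 9)) for _ in range(3)]
            mine = kruskal_wallis(groups).statistic
            assert mine == pytest.approx(kw_statistic_oracle(groups), abs=1e-10)

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.normal(size=8) for _ in range(4)]
        h1 = kruskal_wallis(groups).statistic
        h2 = kruskal_wallis([np.exp(g) for g in groups]).statistic
        assert h1 == pytest.approx(h2, abs=1e-10)


class TestRanksum:
    def test_identical_groups(self):
        assert ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]).p_value == 1.0

    def test_exact_separated(self):
        r = ranksum([1, 2, 3], [4, 5, 6])
        assert r.p_value == pytest.approx(0.1, abs=1e-12)
        assert r.statistic == 6.0  # ranks 1+2+3

    def test_enumeration_oracle(self):
        # all C(6,3)=20 assignments of ranks to group 1: W=6 is one of 2
        # equally extreme two-sided outcomes -> p = 2/20 * 2 tails... enumerate
        from itertools import combinations as comb

        ws = sorted(sum(c) for c in comb(range(1, 7), 3))
        w_obs = 6
        n_extreme = sum(1 for w in ws if w <= w_obs or w >= 21 - w_obs + 6 - 6)
        # two-sided: W <= 6 or W >= 15 (symmetric about 10.5)
        n_extreme = sum(1 for w in ws if w <= 6 or w >= 15)
        assert n_extreme / len(ws) == pytest.approx(0.1)

    def test_exact_vs_asymptotic_at_n20(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        exact = ranksum(a, b).p_value
        u = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert abs(exact - u.pvalue) < 0.01

    def test_well_separated_n10_exact_tail(self):
        a = list(range(10))
        b = list(range(100, 110))
        r = ranksum(a, b)
        assert r.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-9)


class TestPosthoc:
    def test_identical_pair_adjusted_p_one(self):
        rows = posthoc_pairwise([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert rows[0].adjusted_p == 1.0

    def test_four_groups_six_pairs_bonferroni_factor(self, rng):
        groups = [rng.normal(size=6) for _ in range(4)]
        rows = posthoc_pairwise(groups)
        assert len(rows) == 6
        for r in rows:
            assert r.adjusted_p == pytest.approx(min(1.0, r.p * 6))

    def test_tukey_on_ranks_runs(self, rng):
        groups = [rng.normal(loc=m, size=8) for m in (0, 0, 3)]
        rows = posthoc_pairwise(groups, method="tukey_on_ranks")
        assert len(rows) == 3
        assert all(0 <= r.p <= 1 for r in rows)


def _toy_table(values: np.ndarray) -> pd.DataFrame:
    rows = []
    it = iter(values)
    for a in ("a1", "a2"):
        for b in ("b1", "b2"):
            for _ in range(3):
                rows.append(dict(A=a, B=b, value=next(it)))
    return pd.DataFrame(rows)


class TestArtAnova:
    def test_alignment_identity(self, rng):
        tab = _toy_table(rng.normal(size=12))
        res = art_anova(tab, "A", "B")  # raises internally if any sum != 0
        assert set(res) == {"A", "B", "A:B"}

    def test_empty_cell_named(self):
        tab = pd.DataFrame(
            dict(A=["a1"] * 4 + ["a2"] * 2, B=["b1", "b2"] * 2 + ["b1"] * 2,
                 value=np.arange(6.0))
        )
        with pytest.raises(ValueError, match="a2.*b2|empty cell"):
            art_anova(tab, "A", "B")

    def test_hand_alignment_oracle_2x2(self):
        # 12 values; align by explicit cell-mean arithmetic and run the ANOVA
        # on ranks with statsmodels as an independent route
        vals = np.array([3.0, 4, 5, 10, 11, 12, 6, 5, 7, 2, 1, 3])
        tab = _toy_table(vals)
        res = art_anova(tab, "A", "B")

        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        cells = tab.groupby(["A", "B"])["value"].transform("mean")
        cm = tab.groupby(["A", "B"])["value"].mean().unstack()
        grand = cm.to_numpy().mean()
        a_eff = cm.mean(axis=1) - grand
        b_eff = cm.mean(axis=0) - grand
        resid = tab["value"] - cells
        for effect, aligned in (
            ("A", resid + tab["A"].map(a_eff)),
            ("B", resid + tab["B"].map(b_eff)),
        ):
            df = tab.copy()
            df["r"] = sps.rankdata(aligned)
            model = ols("r ~ C(A) * C(B)", data=df).fit()
            table = sm.stats.anova_lm(model, typ=2)
            f_oracle = table.loc[f"C({effect})", "F"]
            assert res[effect].statistic == pytest.approx(f_oracle, rel=1e-9)

    def test_unbalanced_rejected(self):
        tab = pd.DataFrame(
            dict(A=["a1"] * 5 + ["a2"] * 4,
                 B=["b1", "b1", "b2", "b2", "b2"] + ["b1", "b1", "b2", "b2"],
                 value=np.arange(9.0))
        )
        with pytest.raises(ValueError, match="balanced"):
            art_anova(tab, "A", "B")


class TestAgreement:
    def test_bland_altman_identity(self):
        a = np.arange(1.0, 7.0)
        res = bland_altman(np.column_stack([a, a]))
        assert res.bias == 0.0
        assert res.loa_low == 0.0 and res.loa_high == 0.0
        assert res.slope == 0.0

    def test_bland_altman_constant_offset(self):
        a = np.arange(1.0, 7.0)
        res = bland_altman(np.column_stack([a, a - 0.5]))
        assert res.bias == pytest.approx(0.5)
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_bland_altman_proportional_bias_slope(self):
        # m2 = 0.9 m1 -> d = 0.1 m1, mean = 0.95 m1 -> slope = 0.1/0.95 = 2/19
        a = np.linspace(1.0, 10.0, 8)
        res = bland_altman(np.column_stack([a, 0.9 * a]))
        assert res.slope == pytest.approx(2 / 19, rel=1e-9)

    def test_limits_bracket_bias(self, rng):
        pairs = rng.normal(size=(30, 2))
        res = bland_altman(pairs)
        assert res.loa_low <= res.bias <= res.loa_high

    def test_icc_perfect_agreement(self):
        a = np.array([1.0, 2, 3, 4, 5, 6])
        assert icc_agreement(a, a).icc == pytest.approx(1.0)

    def test_icc_offset_below_consistency(self):
        rng = np.random.default_rng(3)
        a = rng.normal(10, 2, 10)
        b = a + 5.0
        agreement = icc_agreement(a, b).icc
        # consistency-type ICC ignores the offset entirely
        x = np.column_stack([a, b])
        n, k = x.shape
        grand = x.mean()
        msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = (((x - grand) ** 2).sum() - msr * (n - 1) - msc * (k - 1)) / ((n - 1) * (k - 1))
        consistency = (msr - mse) / (msr + (k - 1) * mse)
        assert agreement < consistency

    def test_icc_toy_table_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        a = rng.normal(10, 3, 6)
        b = a + rng.normal(0.4, 0.8, 6)
        mine = icc_agreement(a, b).icc
        df = pd.DataFrame(
            dict(subject=list(range(6)) * 2, rater=["A"] * 6 + ["B"] * 6,
                 value=np.concatenate([a, b]))
        )
        tab = pg.intraclass_corr(df, "subject", "rater", "value")
        sel = tab["Type"].isin(["ICC2", "ICC(A,1)"])
        oracle = float(tab.loc[sel, "ICC"].iloc[0])
        assert mine == pytest.approx(oracle, abs=1e-9)

    def test_icc_zero_between_subject_variance(self):
        res = icc_agreement([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert math.isnan(res.icc)
        assert "undefined" in res.note


class TestBonferroni:
    def test_property_bounds_and_monotonicity(self):
        from hypothesis import given, strategies as st

        @given(
            st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8),
            st.integers(min_value=8, max_value=100),
        )
        def check(ps, m):
            adj = bonferroni(ps, m)
            assert np.all(adj >= np.asarray(ps))
            assert np.all(adj <= 1.0)

        check()

    def test_scalar_examples(self):
        assert bonferroni([0.01], 6)[0] == pytest.approx(0.06)
        assert bonferroni([0.5], 4)[0] == 1.0

    def test_order_preserved(self):
        out = bonferroni([0.04, 0.001, 0.2], 3)
        assert out == pytest.approx([0.12, 0.003, 0.6])

    def test_m_too_small(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], 1)


def _long(values, tissue="PCL", species="mouse"):
    return pd.DataFrame(
        [
            dict(specimen_id=f"s{i}", species=species, tissue=tissue, region="",
                 measure="csa_mm2", value=v)
            for i, v in enumerate(values)
        ]
    )


class TestBuildSummary:
    def test_mean_sd(self):
        out = build_summary(_long([0.2, 0.3, 0.4]))
        assert out.loc[0, "mean"] == pytest.approx(0.3)
        assert out.loc[0, "sd"] == pytest.approx(0.1)

    def test_mouse_pcl_cv_rounds_to_37(self):
        # group with exactly the printed mouse PCL mean 0.041 and SD 0.015
        out = build_summary(_long([0.041 - 0.015, 0.041, 0.041 + 0.015]))
        assert out.loc[0, "sd"] == pytest.approx(0.015, abs=1e-12)
        assert round(out.loc[0, "cv_pct"]) == 37

    def test_single_observation_sd_missing(self):
        out = build_summary(_long([0.3]))
        assert math.isnan(out.loc[0, "sd"])

    def test_duplicate_keys_rejected(self):
        df = pd.concat([_long([0.1]), _long([0.2])], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            build_summary(df)
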