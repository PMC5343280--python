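"""Statistical battery: Type III two-way ANOVA, Fisher LSD, Pearson, t-test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from glucotrace.stats import (
    AnovaResult,
    EffectRow,
    fisher_lsd,
    pearson,
    two_way_anova,
    unpaired_t,
)


def make_table(values_by_cell, n=None):
    rows = []
    for (g, m), values in values_by_cell.items():
        for v in values:
            rows.append({"group": g, "metabolite": m, "value": float(v)})
    return pd.DataFrame(rows)


def balanced_decomposition(df):
    """Closed-form balanced two-way decomposition (textbook formulas)."""
    grand = df["value"].mean()
    a_means = df.groupby("group")["value"].mean()
    b_means = df.groupby("metabolite")["value"].mean()
    cell_means = df.groupby(["group", "metabolite"])["value"].mean()
    n = df.groupby(["group", "metabolite"]).size().iloc[0]
    a, b = len(a_means), len(b_means)
    ss_a = n * b * ((a_means - grand) ** 2).sum()
    ss_b = n * a * ((b_means - grand) ** 2).sum()
    ss_ab = n * sum(
        (cell_means[g, m] - a_means[g] - b_means[m] + grand) ** 2
        for g in a_means.index
        for m in b_means.index
    )
    ss_e = sum(
        ((block["value"] - cell_means[key]) ** 2).sum()
        for key, block in df.groupby(["group", "metabolite"])
    )
    return ss_a, ss_b, ss_ab, ss_e


class TestTwoWayAnova:
    def test_balanced_toy_matches_closed_form_exactly(self):
        rng = np.random.default_rng(42)
        df = make_table({
            (g, m): rng.normal(10 + 2 * i + 3 * j, 1, 4)
            for i, g in enumerate(["NoSE", "SE"])
            for j, m in enumerate(["G6P", "CIT", "SUC"])
        })
        res = two_way_anova(df)
        ss_a, ss_b, ss_ab, ss_e = balanced_decomposition(df)
        assert res.effects["group"].ss == pytest.approx(ss_a, abs=1e-10)
        assert res.effects["metabolite"].ss == pytest.approx(ss_b, abs=1e-10)
        assert res.effects["interaction"].ss == pytest.approx(ss_ab, abs=1e-10)
        assert res.residual_ss == pytest.approx(ss_e, abs=1e-10)
        assert res.residual_df == len(df) - 6

    def test_unbalanced_matches_statsmodels_type3(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(3)
        cells = {
            ("NoSE", "G6P"): rng.normal(10, 1, 6),
            ("NoSE", "CIT"): rng.normal(12, 1, 4),
            ("SE", "G6P"): rng.normal(8, 1, 5),
            ("SE", "CIT"): rng.normal(13, 1, 7),
        }
        df = make_table(cells)
        res = two_way_anova(df)
        model = smf.ols(
            "value ~ C(group, Sum) * C(metabolite, Sum)", data=df
        ).fit()
        table = sm.stats.anova_lm(model, typ=3)
        assert res.effects["group"].ss == pytest.approx(
            table.loc["C(group, Sum)", "sum_sq"], rel=1e-9)
        assert res.effects["metabolite"].ss == pytest.approx(
            table.loc["C(metabolite, Sum)", "sum_sq"], rel=1e-9)
        assert res.effects["interaction"].ss == pytest.approx(
            table.loc["C(group, Sum):C(metabolite, Sum)", "sum_sq"], rel=1e-9)
        assert res.effects["group"].p == pytest.approx(
            table.loc["C(group, Sum)", "PR(>F)"], rel=1e-9)

    def test_constant_data_gives_zero_ss_and_f(self):
        df = make_table({
            (g, m): [5.0, 5.0, 5.0]
            for g in ["NoSE", "SE"] for m in ["G6P", "CIT"]
        })
        res = two_way_anova(df)
        for eff in res.effects.values():
            assert eff.ss == pytest.approx(0.0, abs=1e-12)
            assert eff.f == 0.0

    def test_empty_cell_rejected_with_message(self):
        df = make_table({
            ("NoSE", "G6P"): [1, 2], ("NoSE", "CIT"): [3, 4],
            ("SE", "G6P"): [5, 6],
        })
        with pytest.raises(ValueError, match="empty design cells"):
            two_way_anova(df)

    def test_null_interaction_rarely_exceeds_critical_value(self):
        """A pure group shift with no interaction: the interaction F should
        stay below its 95th null percentile in >= 90% of replicates."""
        rng = np.random.default_rng(11)
        below = 0
        reps = 200
        for _ in range(reps):
            df = make_table({
                (g, m): rng.normal(10 + (2 if g == "SE" else 0), 1, 5)
                for g in ["NoSE", "SE"] for m in ["G6P", "CIT", "SUC"]
            })
            res = two_way_anova(df)
            crit = sps.f.ppf(0.95, res.effects["interaction"].df, res.residual_df)
            below += res.effects["interaction"].f < crit
        assert below / reps >= 0.90


class TestFisherLSD:
    def test_known_ms_resid_hand_arithmetic(self):
        """MS_resid = 4, means 10 vs 6, n = 4/4 -> t = 4 / sqrt(4 * 0.5)."""
        df = make_table({
            ("NoSE", "X"): [10.0] * 4,
            ("SE", "X"): [6.0] * 4,
        })
        anova = AnovaResult(
            effects={}, residual_ss=4.0 * 6, residual_df=6,
            group_col="group", within_col="metabolite", value_col="value",
        )
        (res,) = fisher_lsd(anova, df)
        assert res.t == pytest.approx(2.8284271247, rel=1e-9)
        assert res.df == 6

    def test_equal_group_means_give_t0_p1(self):
        df = make_table({
            ("NoSE", "X"): [1.0, 2.0, 3.0], ("SE", "X"): [3.0, 2.0, 1.0],
            ("NoSE", "Y"): [4.0, 5.0, 6.0], ("SE", "Y"): [5.0, 6.0, 4.0],
        })
        anova = two_way_anova(df)
        for res in fisher_lsd(anova, df):
            assert res.t == pytest.approx(0.0)
            assert res.p == pytest.approx(1.0)

    def test_single_metabolite_lsd_equals_pooled_t_test(self):
        """With one metabolite the residual MS is the pooled variance, so
        LSD must reproduce the Student's t-test exactly."""
        rng = np.random.default_rng(5)
        x, y = rng.normal(10, 2, 8), rng.normal(8, 2, 6)
        df = pd.DataFrame({
            "group": ["NoSE"] * 8 + ["SE"] * 6,
            "metabolite": "G6P",
            "value": np.concatenate([x, y]),
        })
        # one-metabolite table: two-way collapses; compute LSD from the
        # pooled variance directly
        pooled = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1))
        anova = AnovaResult({}, pooled, len(x) + len(y) - 2,
                            "group", "metabolite", "value")
        (res,) = fisher_lsd(anova, df)
        t_ref, p_ref = sps.ttest_ind(x, y)
        assert res.t == pytest.approx(t_ref, rel=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-12)

    def test_absent_metabolite_rejected(self):
        df = make_table({("NoSE", "X"): [1, 2], ("SE", "X"): [3, 4],
                         ("NoSE", "Y"): [1, 2], ("SE", "Y"): [3, 4]})
        anova = two_way_anova(df)
        with pytest.raises(ValueError, match="absent"):
            fisher_lsd(anova, df, metabolites=["Z"])


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert pearson(x, x).r == 1.0
        assert pearson(x, -x).r == -1.0
        assert pearson(x, x).p == 0.0

    def test_toy_set_matches_direct_formula_and_scipy(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        res = pearson(x, y)
        cov = ((x - x.mean()) * (y - y.mean())).sum()
        r_direct = cov / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert res.r == pytest.approx(r_direct, rel=1e-12)
        r_sp, p_sp = sps.pearsonr(x, y)
        assert res.r == pytest.approx(r_sp, rel=1e-12)
        assert res.p == pytest.approx(p_sp, rel=1e-9)

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=20), rng.normal(size=20)
        base = pearson(x, y).r
        assert pearson(3 * x + 7, y).r == pytest.approx(base, rel=1e-12)
        assert pearson(-2 * x + 1, y).r == pytest.approx(-base, rel=1e-12)

    def test_constant_vector_flagged(self):
        res = pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.flag == "constant_vector"
        assert np.isnan(res.r)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [3.0, 4.0])


class TestUnpairedT:
    def test_identical_samples_give_t0_p1(self):
        res = unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(10, 2, 9), rng.normal(7, 3, 7)
        res = unpaired_t(x, y)
        t_ref, p_ref = sps.ttest_ind(x, y)
        assert res.t == pytest.approx(t_ref, rel=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-12)
        assert res.df == 14

    def test_hand_computed_toy(self):
        # groups {1,2,3} vs {4,5,6}: pooled var 1, t = -3/sqrt(2/3)
        res = unpaired_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.t == pytest.approx(-3 / np.sqrt(2 / 3), rel=1e-12)

    def test_degenerate_zero_variance_unequal_means_flagged(self):
        res = unpaired_t([1.0, 1.0], [2.0, 2.0])
        assert res.flag == "zero_variance_unequal_means"
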