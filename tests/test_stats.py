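"""The dose-response statistics layer: ANOVA, post hoc, t, Pearson+BH."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from atlasvol import tables
from atlasvol.stats import (
    GroupSummary,
    anova_oneway,
    bonferroni_posthoc,
    pearson_bh,
    percent_change,
    ttest_one_sample,
)


def _table3_total_brain():
    return tables.summaries_for(tables.load_absolute_volume_summaries(),
                                "total_brain")


class TestAnova:
    def test_published_total_brain_summaries_reproduce_F(self):
        res = anova_oneway(_table3_total_brain())
        assert res.df_between == 4
        assert res.df_within == 56
        assert round(res.F) == 108
        assert res.p < 1e-4

    def test_identical_groups_give_zero_F(self):
        groups = [GroupSummary(g, 10, 5.0, 0.3) for g in range(3)]
        assert anova_oneway(groups).F == 0.0

    def test_two_group_F_equals_pooled_t_squared(self, rng):
        a = rng.normal(10, 2, 12)
        b = rng.normal(12, 2, 9)
        res = anova_oneway([a, b])
        t, _ = sps.ttest_ind(a, b)  # independent pooled-variance oracle
        assert abs(res.F - t**2) < 1e-9

    def test_summary_and_raw_forms_agree(self, rng):
        groups = [rng.normal(m, 1.5, n) for m, n in
                  [(10, 8), (11, 12), (9.5, 6), (12, 10)]]
        raw = anova_oneway(groups)
        summaries = [GroupSummary.from_values(i, g) for i, g in enumerate(groups)]
        summ = anova_oneway(summaries)
        assert abs(raw.F - summ.F) < 1e-9
        assert raw.df_within == summ.df_within

    def test_raw_matches_scipy(self, rng):
        groups = [rng.normal(0, 1, 10) for _ in range(4)]
        groups[3] += 1.0
        res = anova_oneway(groups)
        F, p = sps.f_oneway(*groups)
        assert abs(res.F - F) < 1e-9 and abs(res.p - p) < 1e-12

    def test_zero_variance_unequal_means_flagged_infinite(self):
        res = anova_oneway([[1.0, 1.0], [2.0, 2.0]])
        assert res.infinite and math.isinf(res.F)

    def test_mixed_inputs_rejected(self):
        with pytest.raises(TypeError):
            anova_oneway([GroupSummary(0, 5, 1.0, 0.1), [1.0, 2.0]])

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0], [2.0, 3.0]])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 20))
    def test_F_invariant_to_affine_data_changes(self, shift, scale):
        rng = np.random.default_rng(7)
        groups = [rng.normal(m, 1, 8) for m in (0.0, 0.5, 1.0)]
        base = anova_oneway(groups).F
        moved = anova_oneway([g * scale + shift for g in groups]).F
        assert math.isclose(base, moved, rel_tol=1e-9, abs_tol=1e-9)


class TestBonferroni:
    def test_identical_groups_adjusted_p_one(self, rng):
        g = rng.normal(0, 1, 10)
        df = bonferroni_posthoc([g, g.copy(), g.copy()], control_index=0)
        assert (df["p_adjusted"] == 1.0).all()

    def test_single_comparison_unadjusted(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        df = bonferroni_posthoc([a, b], control_index=0)
        assert np.isclose(df["p_adjusted"].iloc[0], df["p"].iloc[0])

    def test_shifted_top_group_detected_selectively(self):
        # 5 groups, only the last shifted by 3 pooled SD: in >= 90% of
        # seeded replicates only that comparison is significant
        hits, false = 0, 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            groups = [rng.normal(0, 1, 10) for _ in range(4)]
            groups.append(rng.normal(3.0, 1, 10))
            df = bonferroni_posthoc(groups, control_index=0)
            sig = df["p_adjusted"] < 0.05
            if sig.iloc[-1] and not sig.iloc[:-1].any():
                hits += 1
            if sig.iloc[:-1].any():
                false += 1
        assert hits >= 0.9 * n_rep
        assert false <= 0.1 * n_rep

    def test_bonferroni_never_below_bh(self, rng):
        groups = [rng.normal(m, 1, 8) for m in (0, 0.3, 0.9, 1.4, 0.1)]
        bon = bonferroni_posthoc(groups, control_index=0)
        pairs = [(row["comparison"], [0.0], [0.0]) for _, row in bon.iterrows()]
        from statsmodels.stats.multitest import multipletests
        bh = multipletests(bon["p"], method="fdr_bh")[1]
        assert (bon["p_adjusted"].to_numpy() >= bh - 1e-12).all()


class TestOneSampleT:
    def test_values_at_reference_give_t_zero(self):
        t, p = ttest_one_sample([5.0, 5.1, 4.9, 5.05, 4.95], 5.0)
        assert abs(t) < 1e-9 or p > 0.9

    def test_symmetric_values_t_zero(self):
        t, _ = ttest_one_sample([4.0, 6.0, 3.0, 7.0], 5.0)
        assert abs(t) < 1e-12

    def test_matches_closed_form(self, rng):
        x = rng.normal(12.11, 1.0, 10)
        t, p = ttest_one_sample(x, 11.11)
        # closed form: t = (mean - ref) / (sd / sqrt(n)); p from t_{n-1}
        tt = (x.mean() - 11.11) / (x.std(ddof=1) / math.sqrt(len(x)))
        pp = 2 * sps.t.sf(abs(tt), len(x) - 1)
        assert abs(t - tt) < 1e-6 and abs(p - pp) < 1e-6

    def test_zero_variance_flagged(self):
        t, p = ttest_one_sample([3.0, 3.0, 3.0], 2.0)
        assert math.isinf(t) and p == 0.0


class TestPearsonBH:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        res = pearson_bh([("lin", x, 2 * x + 1)])
        assert np.isclose(res[0].r, 1.0)

    def test_identical_p_is_bh_fixed_point(self, rng):
        x = rng.normal(0, 1, 20)
        y = 0.5 * x + rng.normal(0, 1, 20)
        pairs = [(f"p{i}", x, y) for i in range(5)]
        res = pearson_bh(pairs)
        for c in res:
            assert np.isclose(c.p_adjusted, c.p)

    def test_bh_monotone_in_raw_p(self, rng):
        pairs = []
        for i in range(8):
            x = rng.normal(0, 1, 30)
            y = (i / 8.0) * x + rng.normal(0, 1, 30)
            pairs.append((f"p{i}", x, y))
        res = sorted(pearson_bh(pairs), key=lambda c: c.p)
        adj = [c.p_adjusted for c in res]
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))
        assert all(c.p_adjusted >= c.p for c in res)

    def test_constant_vector_flagged_and_excluded(self, rng):
        x = rng.normal(0, 1, 10)
        res = pearson_bh([("bad", np.ones(10), x), ("good", x, x)])
        assert res[0].undefined and math.isnan(res[0].r)
        assert not res[1].undefined

    def test_fisher_z_coverage_at_r06(self):
        # r=0.6, n=60: the estimate falls inside the 95% Fisher-z interval
        # around 0.6 in >= 93% of seeded replicates
        n, target = 60, 0.6
        cover = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(5000 + rep)
            x = rng.standard_normal(n)
            y = target * x + math.sqrt(1 - target**2) * rng.standard_normal(n)
            r = pearson_bh([("p", x, y)])[0].r
            z, zt = np.arctanh(r), np.arctanh(target)
            cover += abs(z - zt) <= 1.96 / math.sqrt(n - 3)
        assert cover >= 0.93 * n_rep


class TestPercentChange:
    def test_decrease_convention(self):
        assert np.isclose(percent_change(462.8, 357.2), 22.8176318, atol=1e-6)

    def test_increase_convention(self):
        assert np.isclose(percent_change(4.1, 5.9, "increase"), 43.902439, atol=1e-6)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)
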