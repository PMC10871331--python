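"""Statistical machinery against hand computations and enumeration oracles."""

import numpy as np
import pandas as pd
import pytest

from patchfeat.stats import (
    compare_groups_curvefit,
    dunn_posthoc,
    fit_line_origin,
    fit_one_phase_origin,
    kruskal_wallis,
    mann_whitney,
    nested_f_test,
    rm_anova_gg,
    tukey_posthoc,
)

from oracles import enumerate_mwu_pvalue, hand_ranked_kruskal


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        res = kruskal_wallis([np.full(4, 3.0), np.full(4, 3.0), np.full(4, 3.0)])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_hand_ranked_computation(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        res = kruskal_wallis([np.array(g, dtype=float) for g in groups])
        assert res.statistic == pytest.approx(hand_ranked_kruskal(groups), rel=1e-12)

    def test_matches_permutation_null(self):
        rng = np.random.default_rng(42)
        n = 12
        groups = [rng.normal(0, 1, n), rng.normal(0.8, 1, n), rng.normal(0, 1, n)]
        res = kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        n_perm = 20_000
        count = 0
        for _ in range(n_perm):
            rng.shuffle(pooled)
            h = kruskal_wallis([pooled[:n], pooled[n : 2 * n], pooled[2 * n :]]).statistic
            count += h >= res.statistic - 1e-12
        p_mc = count / n_perm
        se = np.sqrt(p_mc * (1 - p_mc) / n_perm) + 1e-4
        # chi-square reference vs permutation null (approximation error shrinks
        # with n; at n=12/group they agree closely)
        assert abs(res.p_value - p_mc) < max(4 * se, 0.01)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(size=6) for _ in range(3)]
        a = kruskal_wallis(groups).statistic
        b = kruskal_wallis(groups[::-1]).statistic
        assert a == pytest.approx(b)


class TestDunn:
    def test_identical_pair_z_zero(self):
        g = np.array([1.0, 2.0, 3.0])
        out = dunn_posthoc([g, g.copy(), np.array([10.0, 11.0, 12.0])],
                           labels=["a", "b", "c"])
        ab = next(c for c in out if c.pair == ("a", "b"))
        assert ab.statistic == pytest.approx(0.0)

    def test_hand_computed_z_on_toy_table(self):
        # distinct values 1..9 in three groups; N=9, var base = N(N+1)/12 = 7.5
        groups = [np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]),
                  np.array([7.0, 8.0, 9.0])]
        out = dunn_posthoc(groups, labels=["a", "b", "c"], adjust="none")
        # mean ranks: 2, 5, 8; se = sqrt(7.5 * (1/3 + 1/3)) = sqrt(5)
        z_ab = (2 - 5) / np.sqrt(5.0)
        ab = next(c for c in out if c.pair == ("a", "b"))
        assert ab.statistic == pytest.approx(z_ab, rel=1e-12)

    def test_bonferroni_is_m_times_p(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(size=5) for _ in range(3)]
        raw = dunn_posthoc(groups, adjust="none")
        adj = dunn_posthoc(groups, adjust="bonferroni")
        for r, a in zip(raw, adj):
            assert a.p_adjusted == pytest.approx(min(1.0, 3 * r.p_unadjusted))
            assert a.p_adjusted >= a.p_unadjusted


class TestMannWhitney:
    def test_complete_separation_u_zero(self):
        res = mann_whitney(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        # scipy reports U for the first sample: x>y count = 0
        assert res.statistic == 0.0

    def test_exact_p_matches_enumeration_n33(self):
        a, b = [1.0, 4.0, 6.0], [2.0, 3.0, 5.0]
        res = mann_whitney(np.array(a), np.array(b))
        u_obs, p_enum = enumerate_mwu_pvalue(a, b)
        assert res.p_value == pytest.approx(p_enum, abs=1e-9)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=5), rng.normal(size=7)
        ra = mann_whitney(a, b)
        rb = mann_whitney(b, a)
        assert ra.statistic == pytest.approx(5 * 7 - rb.statistic)
        assert ra.p_value == pytest.approx(rb.p_value)


def _mixed_df(rng, n_per_group=8, k=5, effects=None):
    effects = effects or {}
    rows = []
    for geno in ["WT", "Tau"]:
        for trt in ["vehicle", "AR"]:
            for s in range(n_per_group):
                sid = f"{geno}_{trt}_{s}"
                subj = rng.normal(0, 1.0)
                for lvl in range(k):
                    y = (
                        subj
                        + rng.normal(0, 1.0)
                        + effects.get("genotype", 0.0) * (geno == "Tau")
                        + effects.get("treatment", 0.0) * (trt == "AR")
                        + effects.get("level", 0.0) * lvl
                    )
                    rows.append(dict(cell_id=sid, genotype=geno, treatment=trt,
                                     level=lvl, value=y))
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_two_level_within_factor_epsilon_is_one(self):
        rng = np.random.default_rng(0)
        df = _mixed_df(rng, k=2)
        res = rm_anova_gg(df)
        assert res.epsilon == 1.0

    def test_epsilon_near_one_under_compound_symmetry(self):
        # large-n compound-symmetric data satisfies sphericity: eps -> 1
        rng = np.random.default_rng(1)
        df = _mixed_df(rng, n_per_group=50, k=5)
        res = rm_anova_gg(df)
        assert res.epsilon > 0.95

    def test_epsilon_bounds(self):
        rng = np.random.default_rng(2)
        # strongly autocorrelated within-subject responses violate sphericity
        rows = []
        for g, geno in enumerate(["WT", "Tau"]):
            for s in range(10):
                walk = np.cumsum(rng.normal(0, 1, 6))
                for lvl, y in enumerate(walk):
                    rows.append(dict(cell_id=f"{geno}{s}", genotype=geno,
                                     treatment="vehicle", level=lvl, value=y))
        res = rm_anova_gg(pd.DataFrame(rows), between=["genotype"])
        k = 6
        assert 1.0 / (k - 1) <= res.epsilon < 1.0

    def test_f_statistics_match_pingouin_single_between(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        rows = []
        for g, geno in enumerate(["WT", "Tau"]):
            for s in range(12):
                base = rng.normal(g, 1.0)
                for lvl in range(5):
                    rows.append(dict(cell_id=f"{geno}{s}", genotype=geno,
                                     treatment="vehicle", level=lvl,
                                     value=base + 0.5 * lvl + rng.normal()
                                     + (0.2 * lvl if g else 0)))
        df = pd.DataFrame(rows)
        mine = rm_anova_gg(df, between=["genotype"])
        ref = pg.mixed_anova(df, dv="value", within="level", subject="cell_id",
                             between="genotype", correction=True)
        ref = ref.set_index("Source")
        assert mine["genotype"].statistic == pytest.approx(ref.loc["genotype", "F"], rel=1e-6)
        assert mine["level"].statistic == pytest.approx(ref.loc["level", "F"], rel=1e-6)
        assert mine["level:genotype"].statistic == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-6)
        assert mine.epsilon == pytest.approx(float(ref.loc["level", "eps"]), abs=0.05)

    def test_detects_planted_between_effect(self):
        rng = np.random.default_rng(4)
        df = _mixed_df(rng, n_per_group=12, effects={"genotype": 2.0})
        res = rm_anova_gg(df)
        assert res["genotype"].p_value < 0.001
        assert res["treatment"].p_value > 0.01

    def test_incomplete_grid_rejected(self):
        rng = np.random.default_rng(5)
        df = _mixed_df(rng)
        df = df[~((df.cell_id == "WT_vehicle_0") & (df.level == 2))]
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova_gg(df)


class TestTukey:
    def test_identical_groups_p_near_one(self):
        rng = np.random.default_rng(6)
        df = _mixed_df(rng, n_per_group=10)
        res = rm_anova_gg(df)
        out = tukey_posthoc(res)
        assert len(out) == 6  # 4 groups -> 6 pairs
        assert all(c.p_adjusted > 0.2 for c in out)

    def test_q_statistic_matches_hand_computation(self):
        # 4 balanced groups; q = |diff| / sqrt(MS_err / n)
        rng = np.random.default_rng(7)
        df = _mixed_df(rng, n_per_group=6, effects={"genotype": 3.0})
        res = rm_anova_gg(df)
        ctx = res._tukey_ctx
        out = tukey_posthoc(res)
        labels = ctx["group_labels"]
        ybar = ctx["subject_means"]
        for comp in out:
            a, b = comp.pair
            ma = ybar[labels == a].mean()
            mb = ybar[labels == b].mean()
            q_hand = abs(ma - mb) / np.sqrt(ctx["ms_error"] / 6)
            assert comp.statistic == pytest.approx(q_hand, rel=1e-9)

    def test_p_monotone_in_mean_difference(self):
        rng = np.random.default_rng(8)
        df = _mixed_df(rng, n_per_group=10, effects={"genotype": 1.5, "treatment": 3.0})
        out = tukey_posthoc(rm_anova_gg(df))
        qs = np.array([c.statistic for c in out])
        ps = np.array([c.p_adjusted for c in out])
        order = np.argsort(qs)
        assert np.all(np.diff(ps[order]) <= 1e-9)


class TestCurveFits:
    def test_one_phase_exact_recovery(self):
        x = np.arange(0, 500, 20, dtype=float)
        y = 100.0 * (1 - np.exp(-0.01 * x))
        fit = fit_one_phase_origin(x, y)
        assert fit.params[0] == pytest.approx(100.0, rel=1e-6)
        assert fit.params[1] == pytest.approx(0.01, rel=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-9)

    def test_one_phase_all_zero(self):
        fit = fit_one_phase_origin(np.arange(5.0), np.zeros(5))
        assert fit.params[0] == 0.0 and fit.rss == 0.0

    def test_one_phase_passes_through_origin(self):
        rng = np.random.default_rng(9)
        x = np.arange(0, 200, 10, dtype=float)
        y = 80 * (1 - np.exp(-0.02 * x)) + rng.normal(0, 5, len(x))
        fit = fit_one_phase_origin(x, y)
        ymax, k = fit.params
        assert ymax * (1 - np.exp(-k * 0.0)) == 0.0

    def test_line_origin_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = 2.0 * x
        fit = fit_line_origin(x, y)
        assert fit.params[0] == pytest.approx(2.0) and fit.rss == pytest.approx(0.0)

    def test_line_origin_hand_table(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.5, 1.8, 4.5, 5.4])
        fit = fit_line_origin(x, y)
        assert fit.params[0] == pytest.approx(np.sum(x * y) / np.sum(x * x), rel=1e-12)
        resid = y - fit.params[0] * x
        assert np.sum(x * resid) == pytest.approx(0.0, abs=1e-9)  # normal equations

    def test_all_zero_x_rejected(self):
        with pytest.raises(ValueError):
            fit_line_origin(np.zeros(3), np.arange(3.0))


class TestNestedF:
    def test_identical_groups_f_zero(self):
        x = np.arange(1, 6, dtype=float)
        y = 2 * x + np.array([0.1, -0.2, 0.05, 0.0, 0.1])
        fa = fit_line_origin(x, y)
        shared = fit_line_origin(np.concatenate([x, x]), np.concatenate([y, y]))
        res = nested_f_test(shared, [fa, fit_line_origin(x, y)])
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_null_rejection_rate_close_to_alpha(self):
        rng = np.random.default_rng(10)
        x = np.arange(0, 100, 10, dtype=float)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            ya = 1.5 * x + rng.normal(0, 5, len(x))
            yb = 1.5 * x + rng.normal(0, 5, len(x))
            fa, fb = fit_line_origin(x, ya), fit_line_origin(x, yb)
            shared = fit_line_origin(np.concatenate([x, x]), np.concatenate([ya, yb]))
            res = nested_f_test(shared, [fa, fb])
            rejections += res.p_value < 0.05
        rate = rejections / n_rep
        assert 0.02 < rate < 0.09

    def test_power_against_separated_curves(self):
        rng = np.random.default_rng(11)
        x = np.arange(0, 500, 20, dtype=float)
        ya = 100 * (1 - np.exp(-0.01 * x)) + rng.normal(0, 2, len(x))
        yb = 50 * (1 - np.exp(-0.01 * x)) + rng.normal(0, 2, len(x))
        out = compare_groups_curvefit(x, {"WT": ya, "Tau": yb})
        assert out[0].p_adjusted < 1e-6

    def test_bonferroni_family_adjustment(self):
        rng = np.random.default_rng(12)
        x = np.arange(0, 100, 10, dtype=float)
        curves = {g: 2 * x + rng.normal(0, 5, len(x)) for g in "abcd"}
        out = compare_groups_curvefit(x, curves, model="line_origin")
        assert len(out) == 6
        for c in out:
            assert c.p_adjusted == pytest.approx(min(1.0, 6 * c.p_unadjusted))
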