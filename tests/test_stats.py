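import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import tukey_hsd as scipy_tukey

from oirdkit import (choose_branch, kruskal_wallis,
                     mann_whitney_u, one_way_anova, run_decision_tree,
                     shapiro_wilk, tukey_hsd_kramer, two_way_anova_interaction,
                     unpaired_t_test)
from oirdkit.errors import DegenerateSampleError, DesignError
from reference_impl import lstsq_anova_f, lstsq_t_test, permutation_mann_whitney_p


class TestShapiroWilk:
    def test_matches_published_worked_example(self):
        """The classic n = 11 adult-weights sample (published W = 0.79;
        R's shapiro.test gives W = 0.78881, p = 0.006704)."""
        x = [148, 154, 158, 160, 161, 162, 166, 170, 182, 195, 236]
        w, p = shapiro_wilk(x)
        assert w == pytest.approx(0.78881, abs=1e-3)
        assert p == pytest.approx(0.006704, abs=1e-3)
        assert p < 0.05  # the 236 outlier breaks normality

    def test_normal_order_statistics_near_one(self):
        from scipy.stats import norm
        n = 30
        x = norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
        w, _ = shapiro_wilk(x)
        assert w > 0.99

    def test_bimodal_rejected_most_seeds(self):
        """Strongly bimodal n = 20 samples fail normality >= 95% of seeds."""
        rejections = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            x = np.concatenate([rng.normal(-4, 0.3, 10), rng.normal(4, 0.3, 10)])
            _, p = shapiro_wilk(x)
            rejections += p < 0.05
        assert rejections >= 57

    def test_contract_bounds(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError):
            shapiro_wilk(np.arange(51.0))
        with pytest.raises(DegenerateSampleError):
            shapiro_wilk([1.0, 1.0, 1.0])


class TestBranchChoice:
    def test_all_normal_parametric(self):
        rng = np.random.default_rng(1)
        groups = {g: rng.normal(0, 1, 8) for g in "abc"}
        branch, pvals = choose_branch(groups)
        assert branch == "parametric"
        assert set(pvals) == set("abc")

    def test_one_non_normal_group_flips_branch(self):
        rng = np.random.default_rng(2)
        groups = {"a": rng.normal(0, 1, 12),
                  "b": np.concatenate([rng.normal(-5, 0.1, 6), rng.normal(5, 0.1, 6)]),
                  "c": rng.normal(0, 1, 12)}
        branch, pvals = choose_branch(groups)
        assert branch == "nonparametric"
        assert pvals["b"] < 0.05


class TestOneWayAnova:
    def test_identical_groups(self):
        f, p = one_way_anova([[1, 2, 3]] * 3)
        assert f == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_decomposition(self):
        """{1,2,3},{2,3,4},{3,4,5}: SSB = 6, SSW = 6 -> F = 3 on (2,6)."""
        f, p = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert f == pytest.approx(3.0)
        from scipy.stats import f as fdist
        assert p == pytest.approx(fdist.sf(3.0, 2, 6))

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(0, 1, 6) for _ in range(3)]
        f1, _ = one_way_anova(groups)
        f2, _ = one_way_anova([g + 100.0 for g in groups])
        assert f1 == pytest.approx(f2, rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_lstsq_oracle(self, seed):
        """F matches an explicit design-matrix least-squares fit to 1e-10."""
        rng = np.random.default_rng(seed)
        groups = [rng.normal(rng.uniform(-1, 1), 1, n) for n in (5, 6, 7)]
        f, p = one_way_anova(groups)
        f_ref, p_ref = lstsq_anova_f(groups)
        assert f == pytest.approx(f_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)


class TestTukeyKramer:
    def test_identical_groups_q_zero(self):
        out = tukey_hsd_kramer({"a": [1, 2, 3], "b": [1, 2, 3]},
                               allow_nonsignificant=True)
        assert out[0][1] == pytest.approx(0.0)
        assert out[0][2] == pytest.approx(1.0)

    def test_matches_scipy_unequal_n(self):
        rng = np.random.default_rng(4)
        groups = {"a": rng.normal(0, 1, 5), "b": rng.normal(1.5, 1, 6),
                  "c": rng.normal(0, 1, 7)}
        mine = tukey_hsd_kramer(groups, allow_nonsignificant=True)
        ref = scipy_tukey(*groups.values())
        for (pair, q, p), (i, j) in zip(mine, [(0, 1), (0, 2), (1, 2)]):
            assert p == pytest.approx(ref.pvalue[i, j], abs=1e-6)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(5)
        groups = {"a": rng.normal(0, 1, 6), "b": rng.normal(0, 1, 6),
                  "c": rng.normal(6, 1, 6)}
        out = dict((pair, p) for pair, _, p in
                   tukey_hsd_kramer(groups, allow_nonsignificant=True))
        assert out[("a", "c")] < 0.05 and out[("b", "c")] < 0.05
        assert out[("a", "b")] > 0.05

    def test_contract_requires_significant_omnibus(self):
        with pytest.raises(ValueError):
            tukey_hsd_kramer({"a": [1, 2], "b": [1, 2]}, omnibus_p=0.5)


class TestKruskalWallis:
    def test_identical_groups(self):
        h, _ = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0)

    def test_hand_rank_computation(self):
        """Fully separated ranks: H = 7.2 for {1-3},{4-6},{7-9}."""
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(0, 1, 5) for _ in range(3)]
        h1, p1 = kruskal_wallis(groups)
        h2, p2 = kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestMannWhitney:
    def test_identical_multisets(self):
        u, p = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert u == pytest.approx(8.0)  # n^2/2 with mid-rank ties
        assert p == pytest.approx(1.0)

    def test_enumerated_small_case(self):
        """a={1,2}, b={3,4}: U = 0, exact two-sided p = 2/6."""
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_equals_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.permutation(20)[:5].astype(float)
        b = rng.permutation(40)[:6].astype(float) + 0.5  # tie-free vs a
        _, p = mann_whitney_u(a, b)
        assert p == pytest.approx(permutation_mann_whitney_p(a, b), abs=1e-12)

    def test_exact_close_to_asymptotic_for_moderate_n(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
        from scipy.stats import mannwhitneyu
        p_exact = mannwhitneyu(a, b, method="exact").pvalue
        p_asym = mannwhitneyu(a, b, method="asymptotic").pvalue
        assert abs(p_exact - p_asym) < 0.02

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 6), rng.normal(0.4, 1, 7)
        u1, p1 = mann_whitney_u(a, b)
        u2, p2 = mann_whitney_u(2 * a + 1, 2 * b + 1)
        assert (u1, p1) == (u2, p2)


class TestUnpairedT:
    def test_identical_samples(self):
        t, p, ci = unpaired_t_test([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)
        assert ci[0] < 0 < ci[1]

    def test_hand_computation(self):
        """{1,2,3} vs {2,3,4}: pooled SD 1, t = -sqrt(3/2) on 4 df."""
        t, p, ci = unpaired_t_test([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-np.sqrt(1.5), abs=1e-6)

    def test_ci_p_duality(self):
        """The 95% CI of the difference excludes 0 iff p < 0.05."""
        rng = np.random.default_rng(8)
        for _ in range(30):
            a = rng.normal(0, 1, 6)
            b = rng.normal(rng.uniform(-2, 2), 1, 7)
            t, p, ci = unpaired_t_test(a, b)
            assert (p < 0.05) == (ci[0] > 0 or ci[1] < 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_regression_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 5), rng.normal(1, 1, 7)
        t, _, _ = unpaired_t_test(a, b)
        assert t == pytest.approx(lstsq_t_test(a, b), abs=1e-10)

    def test_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            unpaired_t_test([1.0, 1.0], [1.0, 1.0])


class TestTwoWayAnova:
    def test_balanced_equals_textbook(self):
        """In a balanced design Type-II equals the classical two-way table."""
        rng = np.random.default_rng(9)
        vals, gen, drug = [], [], []
        effects = {("a", "s"): 0, ("a", "m"): 1, ("b", "s"): 0.5, ("b", "m"): 2.5}
        for (g, d), mu in effects.items():
            v = mu + rng.normal(0, 1, 4)
            vals.extend(v); gen.extend([g] * 4); drug.extend([d] * 4)
        f, p = two_way_anova_interaction(vals, gen, drug)
        # textbook cell-mean computation
        df = pd.DataFrame({"v": vals, "g": gen, "d": drug})
        cm = df.groupby(["g", "d"])["v"].mean().unstack()
        gm = df["v"].mean()
        inter = cm.sub(cm.mean(1), axis=0).sub(cm.mean(0), axis=1) + gm
        ss_i = 4 * float((inter ** 2).values.sum())
        sse = float(df.groupby(["g", "d"])["v"].transform("mean").rsub(df["v"]).pow(2).sum())
        f_ref = (ss_i / 1) / (sse / 12)
        assert f == pytest.approx(f_ref, rel=1e-9)

    def test_empty_cell_is_design_error(self):
        with pytest.raises(DesignError):
            two_way_anova_interaction([1, 2, 3, 4], ["a", "a", "b", "b"],
                                      ["s", "s", "s", "m"])

    def test_multiplicative_effect_detected(self):
        """A strong crossed (multiplicative) genotype x drug effect gives
        a small interaction p at n = 6 per cell."""
        rng = np.random.default_rng(10)
        vals, gen, drug = [], [], []
        mult = {"a": 1.0, "b": 0.5}
        for g in ("a", "b"):
            for d, mu in (("s", 7.0), ("m", 7.0 * 0.4 * mult[g] / 1.0)):
                v = mu + rng.normal(0, 0.5, 6)
                vals.extend(v); gen.extend([g] * 6); drug.extend([d] * 6)
        f, p = two_way_anova_interaction(vals, gen, drug)
        assert p < 0.05


class TestDecisionTree:
    def test_parametric_path_and_report_contract(self):
        rng = np.random.default_rng(11)
        groups = {"+/+": rng.normal(0.47, 0.03, 5),
                  "+/-": rng.normal(0.38, 0.03, 6),
                  "-/-": rng.normal(0.38, 0.03, 7)}
        rep = run_decision_tree(groups)
        assert rep.branch == "parametric"
        assert set(rep.normality_p) == {"+/+", "+/-", "-/-"}
        assert rep.omnibus[0] == "one_way_anova"
        if rep.omnibus[2] < 0.05:
            assert len(rep.posthoc) == 3
        assert rep.pairwise_focus[0] == ("+/+", "-/-")
        assert rep.pairwise_focus[1] == "unpaired_t_test"
        assert rep.pairwise_focus[4] is not None  # CI of the difference

    def test_nonparametric_path(self):
        rng = np.random.default_rng(12)
        groups = {"+/+": np.concatenate([rng.normal(-3, 0.05, 4), rng.normal(3, 0.05, 4)]),
                  "+/-": rng.normal(0, 1, 6),
                  "-/-": rng.normal(0, 1, 7)}
        rep = run_decision_tree(groups)
        assert rep.branch == "nonparametric"
        assert rep.omnibus[0] == "kruskal_wallis"
        assert rep.posthoc == []
        assert rep.pairwise_focus[1] == "mann_whitney_u"

    def test_posthoc_only_after_significant_omnibus(self):
        rng = np.random.default_rng(13)
        groups = {"+/+": rng.normal(0.5, 0.05, 5),
                  "+/-": rng.normal(0.5, 0.05, 6),
                  "-/-": rng.normal(0.5, 0.05, 7)}
        rep = run_decision_tree(groups)
        if rep.branch == "parametric" and rep.omnibus[2] >= 0.05:
            assert rep.posthoc == []

    def test_two_way_attached_from_raw(self):
        rng = np.random.default_rng(14)
        raw = pd.DataFrame({
            "value": rng.normal(5, 1, 24),
            "genotype": ["+/+"] * 8 + ["+/-"] * 8 + ["-/-"] * 8,
            "drug": (["saline"] * 4 + ["morphine"] * 4) * 3,
        })
        groups = {g: rng.normal(0.4, 0.05, n) for g, n in
                  [("+/+", 5), ("+/-", 6), ("-/-", 7)]}
        rep = run_decision_tree(groups, raw=raw)
        assert rep.two_way is not None
        assert 0 <= rep.two_way[1] <= 1
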