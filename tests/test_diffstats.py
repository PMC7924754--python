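"""Transform, tests, FDR, fold-change classification and the ANOVA screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import statsmodels.api as sm
from statsmodels.formula.api import ols

from rootcue import synth
from rootcue.curation import curate
from rootcue.diffstats import (
    DifferentialScreen,
    TwoWayAnovaScreen,
    arcsinh_transform,
    bh_fdr,
    differential_screen,
    feature_t_test,
    fold_change,
    interaction_screen,
    volcano_classify,
)

from conftest import small_params
from helpers import micro_table, pooled_t_oracle, recovery_stats


class TestArcsinh:
    def test_zero_maps_to_zero(self):
        assert arcsinh_transform(0.0) == 0.0

    def test_known_value(self):
        assert arcsinh_transform(1.0) == pytest.approx(np.log(1 + np.sqrt(2)),
                                                       abs=1e-12)

    def test_large_x_asymptote(self):
        x = 1e5
        assert arcsinh_transform(x) == pytest.approx(np.log(2 * x), rel=1e-6)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            arcsinh_transform(-1.0)

    def test_strictly_increasing(self):
        x = np.linspace(0, 100, 500)
        assert (np.diff(arcsinh_transform(x)) > 0).all()


class TestTTest:
    def test_identical_groups(self):
        t, p = feature_t_test([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_constant_equal_groups(self):
        t, p = feature_t_test([5, 5, 5], [5, 5, 5])
        assert (t, p) == (0.0, 1.0)

    def test_constant_unequal_groups_warns(self):
        with pytest.warns(UserWarning, match="zero pooled variance"):
            t, p = feature_t_test([5, 5], [3, 3])
        assert p == 0.0 and t == np.inf

    def test_matches_textbook_pooled_formula(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, int(rng.integers(3, 12)))
            b = rng.normal(0.5, 2, int(rng.integers(3, 12)))
            t, p = feature_t_test(a, b)
            t0, p0 = pooled_t_oracle(a, b)
            assert t == pytest.approx(t0, abs=1e-10)
            assert p == pytest.approx(p0, abs=1e-10)

    def test_spec_example_values(self):
        t, p = feature_t_test([0.5, 0.7, 0.6, 0.8], [1.5, 1.7, 1.6, 1.8])
        t0, p0 = pooled_t_oracle([0.5, 0.7, 0.6, 0.8], [1.5, 1.7, 1.6, 1.8])
        assert p == pytest.approx(p0, abs=1e-10)

    def test_welch_differs_under_unequal_variance(self, rng):
        a = rng.normal(0, 0.1, 5)
        b = rng.normal(1, 5, 20)
        _, p_pooled = feature_t_test(a, b)
        t_w, p_w = feature_t_test(a, b, welch=True)
        t_s, p_s = stats.ttest_ind(a, b, equal_var=False)
        assert p_w == pytest.approx(float(p_s), abs=1e-12)
        assert p_w != pytest.approx(p_pooled, abs=1e-6)


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_zero(self):
        assert bh_fdr([0.0, 0.0, 0.0]) == pytest.approx([0.0] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_dominates_p_and_permutation_equivariance(self, p):
        p = np.asarray(p)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all()
        assert (q <= 1).all()
        perm = np.random.default_rng(0).permutation(len(p))
        assert bh_fdr(p[perm]) == pytest.approx(q[perm])


class TestFoldChange:
    @pytest.mark.parametrize(
        "ma,mb,ratio,direction",
        [(10, 5, 2.0, "A"), (5, 10, 2.0, "B"), (7, 7, 1.0, "none"),
         (0, 3, np.inf, "B"), (3, 0, np.inf, "A")],
    )
    def test_cases(self, ma, mb, ratio, direction):
        assert fold_change(ma, mb) == (ratio, direction)

    def test_both_zero_flagged(self):
        with pytest.warns(UserWarning, match="both means are zero"):
            assert fold_change(0, 0) == (1.0, "none")

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fold_change(-1, 2)


class TestDifferentialScreen:
    def _table_with_effect(self, rng, fold=4.0):
        n = 40
        base = rng.lognormal(9, 0.3, (n, 12))
        base[0, 6:] *= fold  # postembryonic samples up for feature 0
        specs = [(f"f{i:02d}", 200 + i, 1.0 + 0.1 * i) for i in range(n)]
        return micro_table(specs, base)

    def test_planted_feature_classified(self, rng):
        table = self._table_with_effect(rng)
        res = differential_screen(table)
        assert res.loc["f00", "enrichment"] == "postembryonic_enriched"
        assert res.loc["f00", "fold_change"] > 2

    def test_class_invariants(self, rng):
        res = differential_screen(self._table_with_effect(rng))
        assert ((res["q"] >= res["p"] - 1e-12)).all()
        sig = res[res["enrichment"] != "not_significant"]
        assert (sig["q"] < 0.05).all() and (sig["fold_change"] > 2).all()

    def test_raw_p_mode_is_more_liberal(self, rng):
        table = self._table_with_effect(rng, fold=2.5)
        fdr = DifferentialScreen(p_mode="fdr").fit(table).results_
        raw = DifferentialScreen(p_mode="raw").fit(table).results_
        n_fdr = (fdr["enrichment"] != "not_significant").sum()
        n_raw = (raw["enrichment"] != "not_significant").sum()
        assert n_raw >= n_fdr

    def test_volcano_reclassification(self, rng):
        res = differential_screen(self._table_with_effect(rng))
        strict = volcano_classify(res, alpha=1e-30)
        assert (strict == "not_significant").all()

    def test_fc_cut_blocks_small_effects(self):
        # significant but below the 2-fold cut
        rng = np.random.default_rng(1)
        base = rng.lognormal(9, 0.02, (5, 20))
        base[0, 10:] *= 1.5
        specs = [(f"f{i}", 200 + i, 1.0 + i) for i in range(5)]
        table = micro_table(specs, base,
                            root_types=["embryonic"] * 10 + ["postembryonic"] * 10)
        res = differential_screen(table)
        assert res.loc["f0", "q"] < 0.05
        assert res.loc["f0", "enrichment"] == "not_significant"

    def test_sample_filter_restricts_to_genotype(self, rng):
        n = 10
        base = rng.lognormal(9, 0.3, (n, 24))
        specs = [(f"f{i}", 200 + i, 1.0 + i) for i in range(n)]
        root = (["embryonic"] * 6 + ["postembryonic"] * 6) * 2
        geno = ["WT"] * 12 + ["bx1"] * 12
        base[0, 18:24] *= 50  # effect only in bx1 postembryonic
        table = micro_table(specs, base, root_types=root, genotypes=geno)
        wt_only = DifferentialScreen(sample_filter={"genotype": "WT"}).fit(table)
        assert wt_only.results_.loc["f0", "enrichment"] == "not_significant"
        pooled = DifferentialScreen().fit(table)
        assert pooled.results_.loc["f0", "p"] < wt_only.results_.loc["f0", "p"]


class TestTwoWayAnova:
    def _design(self, n_per_cell=(3, 3, 3, 3)):
        root, geno = [], []
        for (r, g), n in zip(
            [("embryonic", "WT"), ("postembryonic", "WT"),
             ("embryonic", "bx1"), ("postembryonic", "bx1")], n_per_cell
        ):
            root += [r] * n
            geno += [g] * n
        return root, geno

    def test_all_equal_gives_zero_f(self):
        root, geno = self._design()
        table = micro_table([("f0", 200.1, 1.0)], np.full((1, 12), 42.0),
                            root_types=root, genotypes=geno)
        res = TwoWayAnovaScreen().fit(table).results_
        assert res.loc["f0", ["F_root_type", "F_genotype", "F_interaction"]].eq(0).all()

    def test_matches_statsmodels_type2_on_unbalanced_data(self, rng):
        root, geno = self._design((3, 4, 5, 6))
        vals = rng.lognormal(6, 0.8, (5, 18))
        specs = [(f"f{i}", 200 + i, 1.0 + i) for i in range(5)]
        table = micro_table(specs, vals, root_types=root, genotypes=geno)
        res = TwoWayAnovaScreen().fit(table).results_
        for i in range(5):
            df = pd.DataFrame({
                "y": np.arcsinh(vals[i]),
                "root": root,
                "geno": geno,
            })
            fit = ols("y ~ C(root) * C(geno)", data=df).fit()
            tab = sm.stats.anova_lm(fit, typ=2)
            assert res.iloc[i]["F_root_type"] == pytest.approx(
                tab.loc["C(root)", "F"], abs=1e-8)
            assert res.iloc[i]["F_genotype"] == pytest.approx(
                tab.loc["C(geno)", "F"], abs=1e-8)
            assert res.iloc[i]["F_interaction"] == pytest.approx(
                tab.loc["C(root):C(geno)", "F"], abs=1e-8)
            assert res.iloc[i]["p_interaction"] == pytest.approx(
                tab.loc["C(root):C(geno)", "PR(>F)"], abs=1e-10)

    def test_pure_interaction_power(self, rng):
        # cells (+d, -d, -d, +d) at d = 3 sigma, n = 5 per cell: the
        # interaction should be detected in >= 90% of replicates.
        root, geno = self._design((5, 5, 5, 5))
        n_rep = 500
        sigma, d = 1.0, 3.0
        pattern = np.array([+d] * 5 + [-d] * 5 + [-d] * 5 + [+d] * 5)
        vals = np.sinh(10 + pattern + rng.normal(0, sigma, (n_rep, 20)))
        specs = [(f"f{i}", 200.1, 1.0) for i in range(n_rep)]
        table = micro_table(specs, vals, root_types=root, genotypes=geno)
        res = TwoWayAnovaScreen().fit(table).results_
        assert (res["p_interaction"] < 0.05).mean() >= 0.9

    def test_empty_cell_raises_with_name(self):
        root = ["embryonic"] * 6 + ["postembryonic"] * 6
        geno = ["WT"] * 12
        table = micro_table([("f0", 200.1, 1.0)], np.ones((1, 12)),
                            root_types=root, genotypes=geno)
        with pytest.raises(ValueError, match="exactly 2 levels"):
            TwoWayAnovaScreen().fit(table)

    def test_single_replicate_cell_raises(self):
        root, geno = self._design((1, 3, 3, 3))
        table = micro_table([("f0", 200.1, 1.0)], np.ones((1, 10)),
                            root_types=root, genotypes=geno)
        with pytest.raises(ValueError, match=">= 2 replicates"):
            TwoWayAnovaScreen().fit(table)


class TestInteractionScreen:
    def test_null_data_yields_no_discoveries(self):
        table, _ = synth.generate_feature_table(
            small_params(seed=9, n_features=300, n_diff_features=0)
        )
        res = TwoWayAnovaScreen().fit(table).results_
        out = interaction_screen(res)
        assert out["n_interaction"] <= 2
        assert out["n_genotype"] <= 2

    def test_planted_interactions_recovered(self):
        params = small_params(
            seed=10, n_features=400, n_diff_features=0,
            n_interaction_features=8, interaction_fold=10.0,
        )
        table, truth = synth.generate_feature_table(params)
        informative, _ = curate(table)
        res = TwoWayAnovaScreen().fit(informative).results_
        out = interaction_screen(res)
        hits = {truth.group_membership[f] for f in out["interaction_features"]
                if f in truth.group_membership}
        assert len(hits & set(truth.interaction_compound_ids)) >= 7

    def test_identified_features_are_excluded(self, rng):
        res = pd.DataFrame({
            "q_interaction": [0.001, 0.001, 0.5],
            "q_genotype": [0.5, 0.5, 0.001],
        }, index=["a", "b", "c"])
        out = interaction_screen(res, identified_ids=["a"])
        assert out["interaction_features"] == ["b"]
        assert out["genotype_features"] == ["c"]


class TestRecovery:
    def test_planted_eightfold_effects_recovered(self):
        params = small_params(seed=12, n_features=400, n_diff_features=20,
                              diff_fold=8.0)
        table, truth = synth.generate_feature_table(params)
        informative, _ = curate(table)
        screen = DifferentialScreen().fit(informative)
        tp, fp, n_planted = recovery_stats(
            screen.results_, None, truth,
            {"postembryonic": "postembryonic_enriched",
             "embryonic": "embryonic_enriched"},
        )
        assert tp >= 18  # >= 18/20 planted compounds recovered
        assert fp <= 2
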