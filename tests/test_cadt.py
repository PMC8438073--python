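import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dendrocp import (
    DataError,
    GroundTruth,
    alr_standardize,
    generate_gradient,
    scale_by_roottips,
    simulate_gene_counts,
    simulate_trait_table,
    threshold_contrast_genes,
    threshold_contrast_traits,
)


@pytest.fixture
def random_tables():
    rng = np.random.default_rng(12)
    counts = pd.DataFrame(
        rng.integers(0, 500, (5, 8)),
        index=[f"s{i}" for i in range(5)],
        columns=[f"g{j}" for j in range(8)],
    )
    sc = pd.DataFrame(
        rng.integers(1, 300, (5, 6)),
        index=counts.index,
        columns=[f"sc{j}" for j in range(6)],
    )
    return counts, sc


class TestAlr:
    def test_loop_oracle(self, random_tables):
        counts, sc = random_tables
        p = 0.5
        out = alr_standardize(counts, sc, pseudocount=p)
        for s in counts.index:
            logs = [np.log(sc.loc[s, k] + p) for k in sc.columns]
            geomean_log = sum(logs) / len(logs)
            for gcol in counts.columns:
                expect = np.log(counts.loc[s, gcol] + p) - geomean_log
                assert abs(out.loc[s, gcol] - expect) <= 1e-12

    def test_ratio_one_case(self):
        counts = pd.DataFrame({"g": [100]}, index=["s"])
        sc = pd.DataFrame({"a": [10], "b": [1000]}, index=["s"])
        out = alr_standardize(counts, sc, pseudocount=1e-12)
        assert out.loc["s", "g"] == pytest.approx(0.0, abs=1e-10)

    def test_scale_invariance(self, random_tables):
        counts, sc = random_tables
        out = alr_standardize(counts, sc, pseudocount=1e-9)
        out7 = alr_standardize(counts * 7, sc * 7, pseudocount=1e-9)
        assert np.allclose(out.to_numpy(), out7.to_numpy(), atol=1e-7)

    def test_all_zero_single_copy_row(self, random_tables):
        counts, sc = random_tables
        sc.loc["s2"] = 0
        with pytest.raises(DataError, match="s2"):
            alr_standardize(counts, sc)

    def test_pseudocount_positive(self, random_tables):
        counts, sc = random_tables
        with pytest.raises(ValueError):
            alr_standardize(counts, sc, pseudocount=0.0)


class TestRootTipScaling:
    def test_equal_tips_identity(self, random_tables):
        counts, sc = random_tables
        alr = alr_standardize(counts, sc)
        tips = pd.Series(100.0, index=alr.index)
        out = scale_by_roottips(alr, tips)
        assert np.allclose(out.to_numpy(), alr.to_numpy())

    def test_doubled_sample_mean_ratio(self):
        alr = pd.DataFrame({"g": [1.0, 1.0]}, index=["a", "b"])
        tips = pd.Series([100.0, 200.0], index=["a", "b"])
        out = scale_by_roottips(alr, tips, mode="mean-ratio")
        # brute-force: factors are tips / mean(tips) = (2/3, 4/3)
        assert out.loc["b", "g"] == pytest.approx(4.0 / 3.0)
        assert out.loc["a", "g"] == pytest.approx(2.0 / 3.0)

    def test_zero_tips_zero_row(self, random_tables):
        counts, sc = random_tables
        alr = alr_standardize(counts, sc)
        tips = pd.Series(100.0, index=alr.index)
        tips.iloc[0] = 0.0
        out = scale_by_roottips(alr, tips)
        assert (out.iloc[0] == 0).all()

    def test_missing_tip_count(self, random_tables):
        counts, sc = random_tables
        alr = alr_standardize(counts, sc)
        tips = pd.Series(100.0, index=alr.index[:-1])
        with pytest.raises(DataError, match="missing"):
            scale_by_roottips(alr, tips)

    def test_zscore_mode(self, random_tables):
        counts, sc = random_tables
        alr = alr_standardize(counts, sc)
        tips = pd.Series([10, 20, 30, 40, 50.0], index=alr.index)
        out = scale_by_roottips(alr, tips, mode="zscore")
        z = (tips - tips.mean()) / tips.std(ddof=1)
        assert np.allclose(out.to_numpy(), alr.mul(z, axis=0).to_numpy())


class TestGeneContrasts:
    @pytest.fixture
    def contrast_input(self):
        rng = np.random.default_rng(7)
        vals = pd.DataFrame(
            rng.normal(0, 1, (12, 5)),
            index=[f"s{i}" for i in range(12)],
            columns=[f"g{j}" for j in range(5)],
        )
        nm = pd.Series(np.linspace(0.1, 1.1, 12), index=vals.index)
        return vals, nm

    def test_identical_groups_f_zero(self, contrast_input):
        vals, nm = contrast_input
        vals.iloc[:, 0] = 3.14
        res = threshold_contrast_genes(vals, nm, 0.6)
        row = res[res.family == "g0"].iloc[0]
        assert row.f_stat == 0.0 and row.p_raw == 1.0

    def test_f_equals_t_squared(self, contrast_input):
        vals, nm = contrast_input
        res = threshold_contrast_genes(vals, nm, 0.6)
        below = (nm < 0.6).to_numpy()
        for fam in vals.columns:
            t, _ = stats.ttest_ind(
                vals.loc[below, fam], vals.loc[~below, fam], equal_var=True
            )
            f = res[res.family == fam].f_stat.iloc[0]
            assert f == pytest.approx(t**2, abs=1e-10)

    def test_textbook_anova_oracle(self, contrast_input):
        vals, nm = contrast_input
        res = threshold_contrast_genes(vals, nm, 0.6)
        below = (nm < 0.6).to_numpy()
        for fam in vals.columns:
            a, b = vals.loc[below, fam].to_numpy(), vals.loc[~below, fam].to_numpy()
            grand = np.concatenate([a, b]).mean()
            ss_between = len(a) * (a.mean() - grand) ** 2 + len(b) * (
                b.mean() - grand
            ) ** 2
            ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            f_oracle = (ss_between / 1.0) / (ss_within / (len(a) + len(b) - 2))
            assert res[res.family == fam].f_stat.iloc[0] == pytest.approx(
                f_oracle, abs=1e-10
            )

    def test_bonferroni_monotone_and_capped(self, contrast_input):
        vals, nm = contrast_input
        res = threshold_contrast_genes(vals, nm, 0.6)
        fam = res[res.family != "total"]
        assert (fam.p_bonferroni >= fam.p_raw - 1e-15).all()
        assert (fam.p_bonferroni <= 1.0).all()

    def test_small_group_rejected(self, contrast_input):
        vals, nm = contrast_input
        with pytest.raises(DataError, match=">= 2"):
            threshold_contrast_genes(vals, nm, 0.15)

    def test_total_row_present(self, contrast_input):
        vals, nm = contrast_input
        res = threshold_contrast_genes(vals, nm, 0.6)
        assert (res.family == "total").sum() == 1

    def test_decay_recall_on_synthetic_defaults(self):
        """Injected decay families are rediscovered below the break."""
        truth = GroundTruth()
        recalls = []
        for rep in range(5):
            g = generate_gradient(54, 12, 0.06, 1.19, seed=60 + rep)
            gc = simulate_gene_counts(g, truth, 100, 100, seed=70 + rep)
            alr = alr_standardize(gc.counts, gc.single_copy)
            scaled = scale_by_roottips(alr, gc.root_tips)
            nm = g.set_index("tree_id")["nminer"]
            res = threshold_contrast_genes(scaled, nm, truth.bai.change_point)
            hits = set(
                res[(res.family != "total") & (res.p_bonferroni < 0.05)
                    & res.enriched_below].family
            )
            recalls.append(
                len(hits & set(gc.decay_families)) / len(gc.decay_families)
            )
        assert np.mean(recalls) >= 0.8


class TestTraitContrasts:
    @pytest.fixture
    def trait_setup(self):
        g = generate_gradient(40, 10, 0.06, 1.19, seed=80)
        truth = GroundTruth()
        traits, ab = simulate_trait_table(g, truth, seed=81)
        nm = g.set_index("tree_id")["nminer"]
        return traits, ab, nm, truth

    def test_enrichment_detected_in_replicates(self):
        truth = GroundTruth()
        sig = 0
        for rep in range(10):
            g = generate_gradient(40, 10, 0.06, 1.19, seed=90 + rep)
            traits, ab = simulate_trait_table(g, truth, seed=100 + rep)
            nm = g.set_index("tree_id")["nminer"]
            res = threshold_contrast_traits(
                traits, ab, nm, truth.bai.change_point
            ).set_index("trait")
            row = res.loc["rhizomorphs"]
            sig += (row.p_raw < 0.05) and row.enriched_below
        assert sig >= 9

    def test_unknown_exploration_label(self, trait_setup):
        traits, ab, nm, truth = trait_setup
        bad = traits.copy()
        bad.loc[0, "exploration_type"] = "warp-drive"
        with pytest.raises(DataError, match="warp-drive"):
            threshold_contrast_traits(bad, ab, nm, 0.53)

    def test_low_coverage_warns_but_returns(self, trait_setup):
        traits, ab, nm, truth = trait_setup
        partial = traits.iloc[:3]
        with pytest.warns(UserWarning, match="cover"):
            res = threshold_contrast_traits(partial, ab, nm, 0.53)
        assert len(res) == 5

    def test_degenerate_trait_f_zero(self, trait_setup):
        traits, ab, nm, truth = trait_setup
        flat = ab.copy()
        rhizo = traits[traits.rhizomorphs].genus
        flat[list(rhizo)] = 1.0 / len(rhizo) * 0.5
        res = threshold_contrast_traits(traits, flat, nm, 0.53).set_index("trait")
        assert res.loc["rhizomorphs"].f_stat == 0.0
        assert res.loc["rhizomorphs"].p_raw == 1.0
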