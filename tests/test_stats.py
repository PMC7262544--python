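"""Rank tests, ANOVA/LSD letters, PCA, enrichment and biosorption."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from metalloscreen import datasets, stats, synthetic


def kw_h_oracle(groups):
    """Independent H formula: (N-1) * SSB_ranks / SST_ranks (tie-robust)."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = pooled.size
    grand = ranks.mean()
    sst = np.sum((ranks - grand) ** 2)
    if sst == 0:
        return 0.0
    offsets = np.cumsum([0] + [len(g) for g in groups])
    ssb = sum(
        (offsets[i + 1] - offsets[i]) * (ranks[offsets[i] : offsets[i + 1]].mean() - grand) ** 2
        for i in range(len(groups))
    )
    return (n - 1) * ssb / sst


class TestKruskalWallis:
    def test_hand_computed_case(self):
        res = stats.kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.statistic == pytest.approx(3.857, abs=1e-3)
        assert res.pvalue == pytest.approx(0.0495, abs=1e-3)
        assert res.df == (1,)

    def test_identical_groups_give_zero(self):
        res = stats.kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_all_values_tied_handled(self):
        res = stats.kruskal_wallis([[5, 5], [5, 5]])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(25):
            g = [rng.integers(0, 5, size=rng.integers(2, 10)) for _ in range(3)]
            ours = stats.kruskal_wallis(g)
            theirs = sps.kruskal(*g)
            assert ours.statistic == pytest.approx(theirs.statistic, rel=1e-10)
            assert ours.pvalue == pytest.approx(theirs.pvalue, rel=1e-10)

    def test_matches_rank_variance_oracle_small_n(self):
        for n1, n2 in [(2, 2), (2, 3), (3, 3)]:
            for values in itertools.product(range(1, 4), repeat=n1 + n2):
                groups = [np.array(values[:n1], float), np.array(values[n1:], float)]
                ours = stats.kruskal_wallis(groups).statistic
                assert ours == pytest.approx(kw_h_oracle(groups), abs=1e-10)


class TestDunnBonferroni:
    def test_hand_computed_z(self):
        res = stats.dunn_bonferroni([[1, 2, 3], [4, 5, 6]])
        assert abs(res.pairwise["z"].iloc[0]) == pytest.approx(1.964, abs=1e-3)

    def test_identical_groups_share_a_letter(self):
        res = stats.dunn_bonferroni({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.pairwise["p_adj"].iloc[0] == 1.0
        assert res.letters["a"] == res.letters["b"]

    def test_bonferroni_adjustment(self):
        res = stats.dunn_bonferroni([[1, 2], [3, 4], [9, 10]])
        m = 3  # k(k-1)/2
        for _, row in res.pairwise.iterrows():
            assert row.p_adj == pytest.approx(min(1.0, row.p_raw * m))
            assert row.p_adj >= row.p_raw

    def test_adjusted_p_monotone_in_abs_z(self, rng):
        g = [rng.normal(i, 1, 8) for i in range(4)]
        res = stats.dunn_bonferroni(g)
        df = res.pairwise.sort_values("p_adj")
        order = df["z"].abs().to_numpy()
        assert np.all(np.diff(order) <= 1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            stats.dunn_bonferroni([[1, 2, 3]])


class TestAnova:
    def test_hand_computed_case(self):
        res = stats.anova_oneway([[1, 2, 3], [3, 4, 5], [5, 6, 7]])
        assert res.statistic == pytest.approx(12.0, rel=1e-10)
        assert res.pvalue == pytest.approx(0.008, abs=1e-3)
        assert res.df == (2, 6)

    def test_equal_means_give_zero_f(self):
        res = stats.anova_oneway([[1, 3], [0, 4]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy(self, rng):
        g = [rng.normal(i, 1, 6) for i in range(3)]
        ours = stats.anova_oneway(g)
        theirs = sps.f_oneway(*g)
        assert ours.statistic == pytest.approx(theirs.statistic, rel=1e-10)
        assert ours.pvalue == pytest.approx(theirs.pvalue, rel=1e-10)

    def test_f_equals_squared_pooled_t_for_two_groups(self, rng):
        a, b = rng.normal(0, 1, 7), rng.normal(1, 1, 5)
        res = stats.anova_oneway([a, b])
        t = sps.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(t.statistic**2, rel=1e-10)

    def test_shift_invariance(self, rng):
        g = [rng.normal(i, 1, 5) for i in range(3)]
        shifted = [x + 1234.5 for x in g]
        assert stats.anova_oneway(g).statistic == pytest.approx(
            stats.anova_oneway(shifted).statistic, rel=1e-8
        )

    def test_degenerate_conventions(self):
        assert stats.anova_oneway([[2, 2], [2, 2]]).pvalue == 1.0
        assert stats.anova_oneway([[2, 2], [3, 3]]).pvalue == 0.0


class TestFisherLSD:
    def test_hand_computed_letters(self):
        res = stats.fisher_lsd({"g1": [1, 2, 3], "g2": [3, 4, 5], "g3": [5, 6, 7]})
        assert res.pairwise["lsd"].iloc[0] == pytest.approx(1.998, abs=1e-3)
        assert res.letters == {"g1": "a", "g2": "b", "g3": "c"}

    def test_identical_groups_share_letter(self):
        res = stats.fisher_lsd({"a": [1, 2, 3], "b": [1.01, 2.01, 2.99]})
        assert res.letters["a"] == res.letters["b"]

    def test_letters_order_invariant_under_relabeling(self):
        g = {"g1": [1, 2, 3], "g2": [3, 4, 5], "g3": [5, 6, 7]}
        rev = dict(reversed(list(g.items())))
        a = stats.fisher_lsd(g).letters
        b = stats.fisher_lsd(rev).letters
        # same partition structure: pairs share a letter iff they did before
        for x, y in itertools.combinations(g, 2):
            assert (set(a[x]) & set(a[y]) != set()) == (set(b[x]) & set(b[y]) != set())

    def test_protected_blocks_after_nonsignificant_omnibus(self, rng):
        g = {"a": rng.normal(0, 1, 4), "b": rng.normal(0, 1, 4), "c": rng.normal(0, 1, 4)}
        res = stats.fisher_lsd(g, protected=True)
        if res.pvalue > 0.05:
            assert not res.pairwise["significant"].any()
            assert len(set(res.letters.values())) == 1

    def test_zero_within_variance_rejected(self):
        with pytest.raises(ValueError, match="tie"):
            stats.fisher_lsd([[1, 1], [2, 2]])

    def test_letters_consistent_with_pairwise(self, rng):
        """Two groups share a letter iff their comparison is non-significant."""
        for trial in range(10):
            g = {f"g{i}": rng.normal(rng.uniform(0, 3), 1, 5) for i in range(4)}
            res = stats.fisher_lsd(g, protected=False)
            for _, row in res.pairwise.iterrows():
                share = set(res.letters[row.group_i]) & set(res.letters[row.group_j])
                assert bool(share) == (not row.significant)


class TestPCA:
    def test_collinear_data_first_component_100pct(self):
        x = np.arange(10, dtype=float)
        data = pd.DataFrame({"a": x, "b": 2 * x})
        res = stats.pca(data, standardize=False)
        assert res.variance_explained_pct[0] == pytest.approx(100.0)

    def test_variance_explained_sums_to_100(self, rng):
        data = pd.DataFrame(rng.normal(size=(12, 5)))
        res = stats.pca(data)
        assert res.variance_explained_pct.sum() == pytest.approx(100.0)

    def test_full_rank_reconstruction(self, rng):
        data = pd.DataFrame(rng.normal(size=(10, 4)))
        res = stats.pca(data, standardize=True)
        x = data.to_numpy()
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.abs(recon - x).max() < 1e-8

    def test_loadings_orthonormal(self, rng):
        data = pd.DataFrame(rng.normal(size=(10, 4)))
        v = stats.pca(data).loadings.to_numpy()
        assert np.allclose(v.T @ v, np.eye(4), atol=1e-10)

    def test_standardized_pca_invariant_to_affine_rescaling(self, rng):
        data = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        rescaled = data * [3.0, 0.5, 10.0, 1.0] + [5.0, -2.0, 0.0, 100.0]
        a = stats.pca(data, standardize=True)
        b = stats.pca(rescaled, standardize=True)
        assert np.allclose(a.variance_explained_pct, b.variance_explained_pct)
        assert np.allclose(a.scores.to_numpy(), b.scores.to_numpy(), atol=1e-8)

    def test_matches_sklearn_explained_variance(self, rng):
        skd = pytest.importorskip("sklearn.decomposition")
        data = pd.DataFrame(rng.normal(size=(15, 5)))
        ours = stats.pca(data, standardize=False)
        ref = skd.PCA().fit(data.to_numpy())
        assert np.allclose(
            ours.variance_explained_pct, 100 * ref.explained_variance_ratio_, atol=1e-8
        )

    def test_constant_column_named_in_error(self):
        data = pd.DataFrame({"Fe": [1.0, 2.0, 3.0], "Ga": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="Ga"):
            stats.pca(data, standardize=True)

    def test_long_format_pivot(self):
        table = synthetic.generate_element_table(
            {"wt": {"Fe": 2.0, "La": 1.0}, "ad": {"Fe": 1.0, "La": 2.0}},
            n_per_group=3, noise_sd=0.1, seed=5,
        )
        matrix = stats.pivot_elements(table)
        assert matrix.shape == (6, 2)
        res = stats.pca(matrix)
        assert res.scores.shape == (6, 2)


class TestEnrichment:
    def test_gallium_factor_about_ten(self):
        ef = stats.enrichment_factor((126.7, 12.9, 4), (13.1, 0.3, 4))
        assert ef.factor == pytest.approx(9.67, abs=0.01)

    def test_molybdenum_factor_about_two(self):
        ef = stats.enrichment_factor((335.2, 2.3, 4), (160.4, 2.6, 4))
        assert ef.factor == pytest.approx(2.09, abs=0.01)

    def test_equal_eluate_and_blank_give_unity(self):
        assert stats.enrichment_factor([5.0, 5.0], [5.0, 5.0]).factor == 1.0

    def test_zero_blank_rejected(self):
        with pytest.raises(ValueError):
            stats.enrichment_factor([5.0, 5.0], [0.0, 0.0])

    def test_summary_table_from_packaged_eluates(self):
        eluates = datasets.load_tmos_eluates()
        out = stats.enrichment_factors_from_summary(eluates, "BlankTMOS")
        ga = out[(out.material == "DFOB") & (out.element == "Ga")].iloc[0]
        assert ga.factor == pytest.approx(126.7 / 13.1)
        assert ga.se > 0


class TestBiosorption:
    def test_lanthanum_wild_type_fraction(self):
        res = stats.biosorption_balance(2.20, 0.58)
        assert res.sorbed_fraction == pytest.approx(0.736, abs=1e-3)
        # (2.20 - 0.58) ug/mL * 10 mL / 0.1 g
        assert res.amount_ug_per_g == pytest.approx(162.0, abs=0.01)

    def test_no_sorption(self):
        assert stats.biosorption_balance(2.0, 2.0).sorbed_fraction == 0.0

    def test_release_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            res = stats.biosorption_balance(0.99, 3.66)
        assert res.sorbed_fraction == 0.0 and res.amount_ug_per_g == 0.0

    def test_nonpositive_initial_rejected(self):
        with pytest.raises(ValueError):
            stats.biosorption_balance(0.0, 1.0)
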