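import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bafdomains import (
    ExpressionMatrix,
    GeneModel,
    GeneSignature,
    assign_width_quantiles,
    bh_adjust,
    binding_enrichment,
    breadth_vs_signature,
    fold_signature,
    peaks_to_genes,
    quantile_binding_fractions,
    tpm_transform,
    two_group_de,
    welch_test,
)
from bafdomains.expression import ExpressionError

from conftest import iv
from oracles import bh_oracle, welch_oracle


def make_expr(values, groups, lengths=None, scale="counts"):
    df = pd.DataFrame(values)
    return ExpressionMatrix(
        df,
        pd.Series(groups),
        gene_lengths=pd.Series(lengths) if lengths is not None else None,
        scale=scale,
    )


class TestTpmTransform:
    def test_single_gene_gets_full_million(self):
        expr = make_expr({"s1": [42.0]}, {"s1": "g"}, lengths=[500.0])
        assert tpm_transform(expr).values.iloc[0, 0] == pytest.approx(1e6)

    def test_length_normalization_worked_example(self):
        expr = ExpressionMatrix(
            pd.DataFrame({"s1": [10.0, 10.0]}, index=["g1", "g2"]),
            pd.Series({"s1": "g"}),
            gene_lengths=pd.Series({"g1": 1_000.0, "g2": 2_000.0}),
        )
        tpm = tpm_transform(expr).values["s1"]
        assert tpm["g1"] == pytest.approx(666_666.67, rel=1e-6)
        assert tpm["g2"] == pytest.approx(333_333.33, rel=1e-6)

    def test_all_zero_sample_flagged(self):
        expr = ExpressionMatrix(
            pd.DataFrame({"s1": [1.0, 2.0], "s2": [0.0, 0.0]}, index=["g1", "g2"]),
            pd.Series({"s1": "g", "s2": "g"}),
            gene_lengths=pd.Series({"g1": 100.0, "g2": 100.0}),
        )
        out = tpm_transform(expr)
        assert out.zero_total_samples == ["s2"]
        assert (out.values["s2"] == 0).all()

    def test_columns_sum_to_one_million(self, rng):
        counts = rng.integers(0, 1_000, size=(50, 8)).astype(float)
        expr = ExpressionMatrix(
            pd.DataFrame(counts, columns=[f"s{i}" for i in range(8)]),
            pd.Series({f"s{i}": "g" for i in range(8)}),
            gene_lengths=pd.Series(rng.integers(200, 10_000, size=50).astype(float)),
        )
        sums = tpm_transform(expr).values.sum(axis=0)
        np.testing.assert_allclose(sums, 1e6, rtol=1e-6)

    def test_missing_lengths_error(self):
        expr = make_expr({"s1": [1.0]}, {"s1": "g"})
        with pytest.raises(ExpressionError):
            tpm_transform(expr)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_exhaustive_small_cases_match_closed_form(self):
        grid = [0.01, 0.05, 0.5, 1.0]
        for n in range(1, 5):
            for p in itertools.product(grid, repeat=n):
                np.testing.assert_allclose(bh_adjust(list(p)), bh_oracle(list(p)),
                                           atol=1e-12)

    def test_matches_statsmodels_and_dominates_raw(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.random(int(rng.integers(1, 40)))
            q = bh_adjust(p)
            assert (q >= p - 1e-15).all()
            _, q_sm, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(q, q_sm, atol=1e-12)

    def test_permutation_equivariant(self, rng):
        p = rng.random(25)
        perm = rng.permutation(25)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_out_of_range_errors(self):
        with pytest.raises(ExpressionError):
            bh_adjust([0.5, 1.5])


class TestWelchTest:
    def test_identical_samples_degenerate(self):
        out = welch_test([3.0, 3.0, 3.0], [3.0, 3.0])
        assert out.t == 0.0 and out.p == 1.0

    def test_worked_example(self):
        out = welch_test([1, 2, 3, 4], [2, 3, 4, 5])
        assert out.t == pytest.approx(-1.0954, abs=1e-4)
        assert out.df == pytest.approx(6.0)
        assert out.p == pytest.approx(0.3153, abs=1e-4)

    def test_antisymmetric(self, rng):
        x, y = rng.normal(size=6), rng.normal(size=8)
        assert welch_test(x, y).t == pytest.approx(-welch_test(y, x).t)

    def test_matches_textbook_oracle(self, rng):
        for _ in range(100):
            x = rng.normal(rng.normal(), 1 + rng.random(), size=int(rng.integers(2, 30)))
            y = rng.normal(rng.normal(), 1 + rng.random(), size=int(rng.integers(2, 30)))
            out = welch_test(x, y)
            t, df, p = welch_oracle(x, y)
            assert out.t == pytest.approx(t, abs=1e-10)
            assert out.df == pytest.approx(df, abs=1e-10)
            assert out.p == pytest.approx(p, abs=1e-10)

    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=10), rng.normal(1.0, 2.0, size=7)
        out = welch_test(x, y)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert out.t == pytest.approx(ref.statistic, abs=1e-12)
        assert out.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_ci_covers_point_estimate(self, rng):
        x, y = rng.normal(size=9), rng.normal(size=9)
        out = welch_test(x, y)
        diff = x.mean() - y.mean()
        assert out.ci_low <= diff <= out.ci_high

    def test_too_small_sample_errors(self):
        with pytest.raises(ExpressionError):
            welch_test([1.0], [2.0, 3.0])


class TestFoldSignature:
    def expr_with_means(self, mean_a, mean_b):
        return ExpressionMatrix(
            pd.DataFrame(
                {"a1": [mean_a], "a2": [mean_a], "b1": [mean_b], "b2": [mean_b]},
                index=["g"],
            ),
            pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"}),
            scale="tpm",
        )

    def test_fivefold_gene_selected(self):
        sig = fold_signature(self.expr_with_means(10.0, 1.0), "A", "B", 5.0,
                             pseudocount=0.0)
        assert sig.set_high_a == {"g"} and sig.set_high_b == set()

    def test_twentyfold_cutoff_not_met(self):
        sig = fold_signature(self.expr_with_means(10.0, 1.0), "A", "B", 20.0,
                             pseudocount=0.0)
        assert sig.set_high_a == set() and sig.set_high_b == set()

    def test_identical_groups_empty_sets(self):
        sig = fold_signature(self.expr_with_means(7.0, 7.0), "A", "B", 5.0)
        assert sig.set_high_a == set() and sig.set_high_b == set()

    def test_sets_disjoint_and_shrink_with_fold(self, rng):
        values = pd.DataFrame(
            rng.exponential(10.0, size=(100, 6)),
            index=[f"g{i}" for i in range(100)],
            columns=[f"s{i}" for i in range(6)],
        )
        expr = ExpressionMatrix(
            values,
            pd.Series({f"s{i}": ("A" if i < 3 else "B") for i in range(6)}),
            scale="tpm",
        )
        sizes = []
        for fold in (2.0, 5.0, 20.0):
            sig = fold_signature(expr, "A", "B", fold)
            assert not (sig.set_high_a & sig.set_high_b)
            sizes.append((len(sig.set_high_a), len(sig.set_high_b)))
        assert sizes[0][0] >= sizes[1][0] >= sizes[2][0]
        assert sizes[0][1] >= sizes[1][1] >= sizes[2][1]


class TestTwoGroupDe:
    def make(self, n_null=50, n_up=5, fold=8.0, seed=5):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n_null + n_up)]
        samples = [f"t{i}" for i in range(4)] + [f"c{i}" for i in range(4)]
        base = rng.lognormal(np.log(200), 0.3, size=len(genes))
        rows = []
        for i, g in enumerate(genes):
            mu = np.array([base[i] * (fold if i < n_up else 1.0)] * 4
                          + [base[i]] * 4)
            rows.append(rng.poisson(mu))
        expr = ExpressionMatrix(
            pd.DataFrame(rows, index=genes, columns=samples).astype(float),
            pd.Series({s: ("tumor" if s.startswith("t") else "control")
                       for s in samples}),
            gene_lengths=pd.Series(1_000.0, index=genes),
        )
        return expr, genes[:n_up]

    def test_identical_gene_not_significant(self):
        expr, _ = self.make(n_up=0)
        de = two_group_de(expr, "tumor", "control")
        assert not de.significant.any()

    def test_planted_eightfold_flagged(self):
        expr, up = self.make()
        de = two_group_de(expr, "tumor", "control")
        assert de.loc[up, "significant"].all()

    def test_flags_obey_conjunction_rule(self):
        expr, _ = self.make()
        de = two_group_de(expr, "tumor", "control", fold=4.0, alpha=0.05)
        rederived = (de.log2_fold_change.abs() >= 2.0) & (de.p_adjusted < 0.05)
        assert (de.significant == rederived).all()
        assert (de.p_adjusted >= de.p_value - 1e-15).all()

    def test_small_group_errors(self):
        expr, _ = self.make()
        expr.groups[:] = "tumor"
        expr.groups.iloc[-1] = "control"
        with pytest.raises(ExpressionError):
            two_group_de(expr, "tumor", "control")


@pytest.fixture
def mapping_setup():
    genes = [
        GeneModel("up1", "chr1", "+", 10_000, 20_000),
        GeneModel("up2", "chr1", "+", 50_000, 60_000),
        GeneModel("down1", "chr1", "+", 100_000, 110_000),
        GeneModel("none1", "chr1", "+", 150_000, 160_000),
    ]
    peaks = [
        iv("chr1", 9_500, 10_500),     # promoter of up1
        iv("chr1", 55_000, 56_000),    # inside up2 body
        iv("chr1", 130_000, 130_500),  # intergenic, nearest down1 (gap 20000 vs 19500)
    ]
    labels = ["promoter", "distal_intragenic", "distal_intergenic"]
    return genes, peaks, labels


class TestPeaksToGenes:
    def test_rules(self, mapping_setup):
        genes, peaks, labels = mapping_setup
        gene_map = peaks_to_genes(peaks, labels, genes)
        assert gene_map == {"up1": [0], "up2": [1], "none1": [2]}

    def test_promoter_peak_spanning_two_tss_windows(self):
        genes = [
            GeneModel("a", "chr1", "+", 10_000, 12_000),
            GeneModel("b", "chr1", "+", 13_000, 15_000),
        ]
        gene_map = peaks_to_genes(
            [iv("chr1", 10_900, 12_100)], ["promoter"], genes
        )
        assert gene_map == {"a": [0], "b": [0]}

    def test_intergenic_maps_to_single_nearest(self):
        genes = [
            GeneModel("near", "chr1", "+", 0, 1_000),
            GeneModel("far", "chr1", "+", 2_000, 3_000),
        ]
        gene_map = peaks_to_genes([iv("chr1", 1_200, 1_300)], ["distal_intergenic"],
                                  genes)
        assert gene_map == {"near": [0]}

    def test_order_independent(self, mapping_setup, rng):
        genes, peaks, labels = mapping_setup
        expected = peaks_to_genes(peaks, labels, genes)
        perm = [2, 0, 1]
        remapped = peaks_to_genes([peaks[i] for i in perm],
                                  [labels[i] for i in perm], genes)
        as_sets = {g: {perm[i] for i in ix} for g, ix in remapped.items()}
        assert as_sets == {g: set(ix) for g, ix in expected.items()}


class TestBreadthVsSignature:
    def test_identical_width_samples(self):
        gene_map = {f"a{i}": [i] for i in range(4)}
        gene_map.update({f"b{i}": [4 + i] for i in range(4)})
        widths = [1_000] * 8
        sig = GeneSignature({f"a{i}" for i in range(4)},
                            {f"b{i}" for i in range(4)}, 4.0)
        report = breadth_vs_signature(gene_map, widths, sig)
        assert report.median_a == report.median_b
        assert report.welch.p == 1.0

    def test_planted_width_contrast(self):
        n = 30
        gene_map = {f"a{i}": [i] for i in range(n)}
        gene_map.update({f"b{i}": [n + i] for i in range(n)})
        widths = [5_000] * n + [600] * n
        # tiny deterministic spread so variances are nonzero
        widths = [w + (i % 5) * 10 for i, w in enumerate(widths)]
        sig = GeneSignature({f"a{i}" for i in range(n)},
                            {f"b{i}" for i in range(n)}, 4.0)
        report = breadth_vs_signature(gene_map, widths, sig)
        assert report.median_a / report.median_b > 8
        assert report.welch.p < 1e-10

    def test_max_width_per_gene_and_unmapped_counted(self):
        gene_map = {"a0": [0, 1], "a1": [4], "b0": [2], "b1": [3]}
        widths = [500, 4_000, 700, 800, 900]
        sig = GeneSignature({"a0", "a1", "a_missing"}, {"b0", "b1"}, 4.0)
        report = breadth_vs_signature(gene_map, widths, sig)
        assert sorted(report.widths_a.tolist()) == [900.0, 4_000.0]
        assert report.unmapped_a == 1


class TestQuantileBindingFractions:
    def make_qset(self):
        widths = list(range(100, 900, 100))  # 8 peaks -> Q1..Q4
        peaks = [iv("chr1", i * 10_000, i * 10_000 + w)
                 for i, w in enumerate(widths)]
        return assign_width_quantiles(peaks, 4)

    def test_all_genes_bound_by_q4_only(self):
        qset = self.make_qset()
        # peaks 6, 7 are Q4
        gene_map = {"g1": [6], "g2": [7]}
        sig = GeneSignature({"g1", "g2"}, set(), 4.0)
        out = quantile_binding_fractions(sig, gene_map, qset)
        assert out.loc["set_high_a", "pct_bound_top"] == 100.0
        assert out.loc["set_high_a", "pct_bound_bottom"] == 0.0

    def test_fisher_p_matches_hypergeometric(self):
        qset = self.make_qset()
        gene_map = {}
        for i in range(30):
            gene_map[f"g{i}"] = [6]  # Q4-bound
        for i in range(30, 40):
            gene_map[f"g{i}"] = [0]  # Q1-bound
        for i in range(40, 100):
            gene_map[f"g{i}"] = [3]  # neither
        sig = GeneSignature({f"g{i}" for i in range(100)}, set(), 4.0)
        out = quantile_binding_fractions(sig, gene_map, qset)
        expected = stats.fisher_exact([[30, 70], [10, 90]])[1]
        assert out.loc["set_high_a", "fisher_p"] == pytest.approx(expected)
        assert out.loc["set_high_a", "pct_bound_top"] == pytest.approx(30.0)
        assert out.loc["set_high_a", "pct_bound_bottom"] == pytest.approx(10.0)

    def test_empty_set_skipped(self):
        qset = self.make_qset()
        sig = GeneSignature({"g1"}, set(), 4.0)
        out = quantile_binding_fractions(sig, {"g1": [0]}, qset)
        assert list(out.index) == ["set_high_a"]


class TestBindingEnrichment:
    def make_de(self, n_up, n_down):
        genes = [f"u{i}" for i in range(n_up)] + [f"d{i}" for i in range(n_down)]
        lfc = [3.0] * n_up + [-3.0] * n_down
        return pd.DataFrame(
            {
                "log2_fold_change": lfc,
                "p_value": 1e-6,
                "p_adjusted": 1e-5,
                "significant": True,
            },
            index=genes,
        )

    def test_worked_ratio(self):
        de = self.make_de(100, 100)
        gene_map = {f"u{i}": [0] for i in range(60)}
        gene_map.update({f"d{i}": [1] for i in range(25)})
        out = binding_enrichment(de, gene_map)
        assert out.ratio == pytest.approx(2.4)
        assert out.prop_up_bound == pytest.approx(0.6)

    def test_equal_proportions_ratio_one(self):
        de = self.make_de(10, 10)
        gene_map = {f"u{i}": [0] for i in range(5)}
        gene_map.update({f"d{i}": [1] for i in range(5)})
        assert binding_enrichment(de, gene_map).ratio == pytest.approx(1.0)

    def test_unbound_down_genes_give_infinite_ratio(self):
        de = self.make_de(10, 10)
        gene_map = {f"u{i}": [0] for i in range(5)}
        out = binding_enrichment(de, gene_map)
        assert np.isinf(out.ratio)
        assert out.n_down_bound == 0

    def test_no_significant_genes_errors(self):
        de = self.make_de(10, 0)
        with pytest.raises(ExpressionError):
            binding_enrichment(de, {})
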