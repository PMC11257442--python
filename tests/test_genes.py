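"""Gene assignment, TPM, expressed fractions, flow, size factors, rank tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import perichrom as pc
from perichrom.genes import (CountsMatrix, GeneModel, assign_genes,
                             compare_groups, domain_flow, expressed_fraction,
                             size_factors, tpm, welch_de_table)
from perichrom.intervals import CLASS1, CLASS2, DomainSet


def counts_matrix(arr, conditions, features=None):
    arr = np.asarray(arr)
    names = []
    reps = {}
    for c in conditions:
        reps[c] = reps.get(c, 0) + 1
        names.append(f"{c}_rep{reps[c]}")
    counts = pd.DataFrame(arr, columns=names,
                          index=features or [f"f{i}" for i in range(len(arr))])
    samples = pd.DataFrame({"condition": conditions,
                            "replicate": [int(n.rsplit("rep", 1)[1]) for n in names]},
                           index=counts.columns)
    return CountsMatrix(counts, samples)


DOMAINS = DomainSet.from_records([
    ("c", 10_000, 20_000, CLASS1),
    ("c", 30_000, 40_000, CLASS2),
])


class TestAssignGenes:
    def test_fully_inside_class2(self):
        g = GeneModel("g", "c", 32_000, 38_000)
        assert assign_genes([g], DOMAINS)["g"] == CLASS2

    def test_no_overlap_outside(self):
        g = GeneModel("g", "c", 50_000, 60_000)
        assert assign_genes([g], DOMAINS)["g"] == "outside"

    def test_sixty_forty_majority(self):
        # 6 kb in class1, 4 kb outside -> class1
        g = GeneModel("g", "c", 14_000, 24_000)
        assert assign_genes([g], DOMAINS)["g"] == CLASS1

    def test_domain_outside_tie_goes_to_domain(self):
        # 5 kb in class1, 5 kb outside
        g = GeneModel("g", "c", 15_000, 25_000)
        assert assign_genes([g], DOMAINS)["g"] == CLASS1

    def test_class_tie_goes_to_class2(self):
        ds = DomainSet.from_records([("c", 0, 10, CLASS1), ("c", 10, 20, CLASS2)])
        g = GeneModel("g", "c", 0, 20)
        assert assign_genes([g], ds)["g"] == CLASS2

    def test_any_overlap_rule(self):
        g = GeneModel("g", "c", 19_000, 50_000)  # 1 kb of 31 kb in domains... per class
        assert assign_genes([g], DOMAINS, rule="majority")["g"] == "outside"
        assert assign_genes([g], DOMAINS, rule="any_overlap")["g"] == CLASS2

    def test_gene_outside_layout_rejected(self):
        layout = pc.GenomeLayout(("c",), (40_000,))
        g = GeneModel("g", "c", 30_000, 50_000)
        with pytest.raises(ValueError):
            assign_genes([g], DOMAINS, layout)


class TestTpm:
    def test_single_gene_gets_million(self):
        cm = counts_matrix([[7, 30]], ["a", "a"], features=["g"])
        mat = tpm(cm, [GeneModel("g", "c", 0, 1_000)])
        assert np.allclose(mat.to_numpy(), 1e6)

    def test_length_normalization_ratio(self):
        cm = counts_matrix([[100], [100]], ["a"], features=["short", "long"])
        genes = [GeneModel("short", "c", 0, 1_000),
                 GeneModel("long", "c", 0, 2_000)]
        mat = tpm(cm, genes)
        assert mat.loc["short", "a_rep1"] / mat.loc["long", "a_rep1"] == pytest.approx(2.0)

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(0)
        cm = counts_matrix(rng.integers(0, 500, size=(50, 4)),
                           ["a", "a", "b", "b"])
        genes = [GeneModel(f"f{i}", "c", 0, int(l))
                 for i, l in enumerate(rng.integers(200, 50_000, size=50))]
        mat = tpm(cm, genes)
        assert np.allclose(mat.sum(axis=0), 1e6, atol=1e-6)

    def test_zero_sample_rejected(self):
        cm = counts_matrix([[5, 0], [3, 0]], ["a", "b"])
        genes = [GeneModel("f0", "c", 0, 1000), GeneModel("f1", "c", 0, 1000)]
        with pytest.raises(ValueError, match="zero total rate"):
            tpm(cm, genes)


class TestExpressedFraction:
    def _setup(self, tpm_vals):
        assignment = pd.Series({"g0": "outside", "g1": CLASS1, "g2": CLASS2})
        mat = pd.DataFrame({"a_rep1": tpm_vals, "a_rep2": tpm_vals},
                           index=assignment.index)
        samples = pd.DataFrame({"condition": ["a", "a"], "replicate": [1, 2]},
                               index=mat.columns)
        return assignment, mat, samples

    def test_all_above_threshold(self):
        a, m, s = self._setup([10.0, 10.0, 10.0])
        assert expressed_fraction(a, m, s, "a") == {
            "outside": 1.0, CLASS1: 1.0, CLASS2: 1.0}

    def test_infinite_threshold_zero(self):
        a, m, s = self._setup([10.0, 10.0, 10.0])
        fr = expressed_fraction(a, m, s, "a", threshold=np.inf)
        assert all(v == 0.0 for v in fr.values())

    def test_empty_category_missing(self):
        a, m, s = self._setup([10.0, 10.0, 10.0])
        a = a[a != CLASS2]
        fr = expressed_fraction(a, m[m.index != "g2"], s, "a")
        assert np.isnan(fr[CLASS2])

    def test_planted_repression_ordering(self, small_truth, small_counts):
        """Expressed fraction outside > class1 > class2 under planted
        domain repression."""
        gene_counts, _ = small_counts
        genes = [GeneModel(i, r.chrom, r.start, r.end, r.strand)
                 for i, r in small_truth.genes.iterrows()]
        assignment = assign_genes(genes, small_truth.planted_domains())
        mat = tpm(gene_counts, genes)
        fr = expressed_fraction(assignment, mat, gene_counts.samples, "wildtype")
        assert fr["outside"] > fr[CLASS1] > fr[CLASS2]


class TestDomainFlow:
    def test_identical_assignments_no_movement(self):
        a = pd.Series({"g0": CLASS1, "g1": "outside", "g2": CLASS2})
        flow = domain_flow(a, a)
        assert flow.aggregates == {"constitutive": 2, "gained": 0,
                                   "lost": 0, "never": 1}

    def test_six_gene_hand_crosstab(self):
        a = pd.Series({"g0": "outside", "g1": "outside", "g2": CLASS1,
                       "g3": CLASS2, "g4": CLASS1, "g5": "outside"})
        b = pd.Series({"g0": CLASS1, "g1": "outside", "g2": CLASS2,
                       "g3": "outside", "g4": CLASS1, "g5": CLASS2})
        flow = domain_flow(a, b)
        # hand table: g0 gained, g1 never, g2 constitutive (class change is
        # still in-domain), g3 lost, g4 constitutive, g5 gained
        assert flow.aggregates == {"constitutive": 2, "gained": 2,
                                   "lost": 1, "never": 1}
        assert sum(flow.aggregates.values()) == 6

    def test_mismatched_universe_rejected(self):
        a = pd.Series({"g0": CLASS1})
        b = pd.Series({"g1": CLASS1})
        with pytest.raises(ValueError):
            domain_flow(a, b)

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        cats = np.array(["outside", CLASS1, CLASS2])
        a = pd.Series(rng.choice(cats, n), index=[f"g{i}" for i in range(n)])
        b = pd.Series(rng.choice(cats, n), index=[f"g{i}" for i in range(n)])
        flow = domain_flow(a, b)
        assert sum(flow.aggregates.values()) == n
        # brute-force cross-tabulation
        in_a = np.isin(a.to_numpy(), [CLASS1, CLASS2])
        in_b = np.isin(b.to_numpy(), [CLASS1, CLASS2])
        assert flow.aggregates["constitutive"] == int((in_a & in_b).sum())
        assert flow.aggregates["gained"] == int((~in_a & in_b).sum())
        assert flow.aggregates["lost"] == int((in_a & ~in_b).sum())


class TestSizeFactors:
    def test_identical_columns_unit_factors(self):
        col = np.array([10, 200, 3000, 50])
        cm = counts_matrix(np.tile(col[:, None], 4), ["a", "a", "b", "b"])
        assert np.allclose(size_factors(cm), 1.0)

    def test_doubled_column_factor_two(self):
        col = np.array([10, 200, 3000, 50])
        mat = np.tile(col[:, None], 4).astype(float)
        mat[:, 3] *= 2
        cm = counts_matrix(mat.astype(int), ["a", "a", "b", "b"])
        sf = size_factors(cm)
        assert np.allclose(sf[:3], 1.0)
        assert sf.iloc[3] == pytest.approx(2.0)

    def test_feature_order_invariance(self):
        rng = np.random.default_rng(1)
        mat = rng.integers(1, 1000, size=(30, 3))
        cm = counts_matrix(mat, ["a", "a", "b"])
        perm = rng.permutation(30)
        cm_perm = counts_matrix(mat[perm], ["a", "a", "b"],
                                features=[f"f{i}" for i in perm])
        assert np.allclose(size_factors(cm), size_factors(cm_perm))

    def test_all_zero_feature_rows_rejected(self):
        cm = counts_matrix([[0, 0], [0, 5]], ["a", "b"])
        with pytest.raises(ValueError):
            size_factors(cm)

    def test_recovers_planted_depth_multipliers(self):
        """Median-of-ratios recovers planted depth within 5% at 2,000+ features."""
        cfg = pc.SynthConfig(seed=3, n_chromosomes=2, chrom_length_bp=20_000_000,
                             depth_multipliers=(0.5, 1.0, 2.0, 0.8, 1.2, 1.0))
        truth = pc.generate_truth(cfg)
        gene_counts, _ = pc.simulate_counts(truth)
        assert len(gene_counts.counts) >= 2_000
        sf = size_factors(gene_counts).to_numpy()
        planted = np.asarray(cfg.depth_multipliers, dtype=float)
        planted /= np.median(planted)
        assert np.abs(sf / planted - 1).max() < 0.05


class TestCompareGroups:
    def test_identical_values_null(self):
        res = compare_groups({"a": [2.0, 2.0, 2.0], "b": [2.0, 2.0]})
        assert res.h_statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_computed_h(self):
        res = compare_groups({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        # rank means 2, 5, 8; H = 12/(9*10) * 3*(4+25+64) - 3*10 = 7.2
        assert res.h_statistic == pytest.approx(7.2)
        assert res.p_value == pytest.approx(stats.chi2.sf(7.2, df=2))

    def test_two_groups_match_rank_sum(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1, 15)
        res = compare_groups({"a": a, "b": b})
        mwu = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        assert res.p_value == pytest.approx(mwu.pvalue, rel=1e-9)

    def test_adjusted_p_not_below_raw(self):
        rng = np.random.default_rng(3)
        groups = {k: rng.normal(i, 1, 8) for i, k in enumerate("abcd")}
        for method in ("holm", "bonferroni", "fdr_bh"):
            res = compare_groups(groups, adjust=method)
            assert (res.pairwise["p_adj"] >= res.pairwise["p_raw"] - 1e-12).all()

    def test_dunn_z_symmetry_and_significance(self):
        res = compare_groups({"lo": [1, 2, 3, 4, 5], "hi": [10, 11, 12, 13, 14],
                              "mid": [6, 7, 8, 9, 15]})
        pw = res.pairwise.set_index(["group_a", "group_b"])
        assert pw.loc[("lo", "hi"), "z"] < 0  # hi has larger mean rank
        assert pw.loc[("lo", "hi"), "p_adj"] < 0.05


class TestWelchDeTable:
    def test_null_data_no_small_padj(self):
        rng = np.random.default_rng(4)
        mat = rng.poisson(100, size=(300, 6))
        cm = counts_matrix(mat, ["a"] * 3 + ["b"] * 3)
        de = welch_de_table(cm, "a", "b")
        assert (de["padj"] > 0.05).mean() > 0.95

    def test_fold_uses_pseudocount(self):
        mat = np.array([[0, 0, 0, 9, 9, 9], [100, 100, 100, 100, 100, 100]])
        cm = counts_matrix(mat, ["a"] * 3 + ["b"] * 3)
        de = welch_de_table(cm, "a", "b")
        assert de.loc["f0", "fold"] == pytest.approx(10.0)
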