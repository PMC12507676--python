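"""Site filtering, allele-frequency posteriors, GWAS and gene-set tests."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from dielniche.phylo import Phylogeny
from dielniche.synth import simulate_genotype_likelihoods, simulate_tree
from dielniche.variants import (af_posterior, af_table, call_havs,
                                cluster_hav_patterns, depth_mask,
                                gene_overlap_test, glm_gwas, pgls_gwas,
                                quality_mask, read_vcf, scale_af,
                                site_selection, write_vcf)


class TestQualityMask:
    def test_qd_below_two_fails(self):
        assert not quality_mask({"QD": 1.9, "FS": 0, "MQ": 60,
                                 "MQRankSum": 0, "ReadPosRankSum": 0})

    def test_printed_boundaries_all_pass(self):
        site = {"QD": 2.0, "FS": 60.0, "MQ": 40.0,
                "MQRankSum": -12.5, "ReadPosRankSum": -8.0}
        assert quality_mask(site)

    def test_each_clause_fires(self):
        base = {"QD": 30, "FS": 1, "MQ": 59, "MQRankSum": 0, "ReadPosRankSum": 0}
        for key, bad in [("QD", 1.0), ("FS", 61.0), ("MQ", 39.0),
                         ("MQRankSum", -13.0), ("ReadPosRankSum", -9.0)]:
            assert not quality_mask({**base, key: bad})

    def test_missing_annotations_pass(self):
        assert quality_mask({})
        assert quality_mask({"QD": None, "FS": np.nan})


class TestDepthMask:
    @pytest.mark.parametrize("dp,ok", [
        (899, False), (900, True), (1400, True), (1900, True), (1901, False)])
    def test_depth_boundaries(self, dp, ok):
        assert depth_mask({"DP": dp}) is ok

    def test_missing_depth_fails(self):
        assert not depth_mask({})


class TestSiteSelection:
    def test_labelled_sites_filtered_exactly(self):
        tree = simulate_tree(20, seed=1)
        panel = simulate_genotype_likelihoods(tree, n_sites=1000, seed=2)
        keep = site_selection(panel.sites, panel.pl)
        s = panel.sites
        truth = ~(s.true_quality_fail | s.true_depth_fail | s.true_indel
                  | s.true_multiallelic | s.true_unplaced | s.true_singleton
                  | s.true_monomorphic)
        assert np.array_equal(keep, truth.to_numpy())

    def test_singleton_minor_allele_excluded(self):
        # one het individual, everyone else hom-ref
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [100],
                              "ref": ["A"], "alt": ["G"],
                              "QD": [30.0], "FS": [1.0], "MQ": [55.0],
                              "MQRankSum": [0.0], "ReadPosRankSum": [0.0],
                              "DP": [1200]})
        pl = np.zeros((1, 6, 3))
        pl[:, :, 1:] = 60                # all hom-ref
        pl[0, 2] = [60, 0, 60]           # one het
        assert not site_selection(sites, pl)[0]
        pl[0, 4] = [60, 0, 60]           # a second carrier
        assert site_selection(sites, pl)[0]

    def test_indel_excluded(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [5], "ref": ["A"],
                              "alt": ["AT"], "QD": [30.0], "FS": [1.0],
                              "MQ": [55.0], "MQRankSum": [0.0],
                              "ReadPosRankSum": [0.0], "DP": [1200]})
        assert not site_selection(sites)[0]

    def test_mappability_bed_is_half_open(self):
        sites = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [10, 11],
                              "ref": ["A", "A"], "alt": ["G", "G"],
                              "QD": [30.0] * 2, "FS": [1.0] * 2,
                              "MQ": [55.0] * 2, "MQRankSum": [0.0] * 2,
                              "ReadPosRankSum": [0.0] * 2, "DP": [1200] * 2})
        bed = pd.DataFrame({"chrom": ["chr1"], "start": [5], "end": [10]})
        keep = site_selection(sites, mappability_bed=bed)
        assert keep[0] and not keep[1]   # pos 10 is 0-based 9 < 10; pos 11 is 10


class TestAfPosterior:
    def test_certain_hom_ref_gives_zero(self):
        pl = np.array([[0, 90, 90], [0, 90, 90]])
        assert af_posterior(pl)["f"] == pytest.approx(0.0, abs=1e-6)

    def test_het_plus_hom_alt_gives_three_quarters(self):
        pl = np.array([[90, 0, 90], [90, 90, 0]])
        assert af_posterior(pl)["f"] == pytest.approx(0.75, abs=1e-6)

    def test_ref_alt_swap_equivariance_exact(self, rng):
        for _ in range(50):
            pl = rng.integers(0, 80, (2, 3)).astype(float)
            pl -= pl.min(axis=1, keepdims=True)
            f = af_posterior(pl)["f"]
            f_swapped = af_posterior(pl[:, ::-1])["f"]
            # exact in the canonical direction (the other direction can
            # lose low bits to float absorption near 0/1)
            assert (f_swapped == 1.0 - f) or (f == 1.0 - f_swapped)

    def test_flat_likelihoods_flagged(self):
        res = af_posterior(np.zeros((2, 3)))
        assert res["f"] == 0.5 and res["flagged"]

    def test_table_matches_scalar_and_swap(self, rng):
        tree = simulate_tree(6, seed=3)
        panel = simulate_genotype_likelihoods(tree, n_sites=40, seed=4,
                                              contaminate=False)
        f = af_table(panel.pl, list(tree.tip_labels))
        for i in (0, 7, 23):
            for s in (0, 3, 5):
                assert f[i, s] == pytest.approx(
                    af_posterior(panel.pl[i, 2 * s:2 * s + 2])["f"], abs=1e-6)
        f_sw = af_table(panel.pl[:, :, ::-1], list(tree.tip_labels))
        # palindromic PL blocks are their own swap: f stays at 1/2 +- 1 ulp
        symmetric = (f == f_sw) & np.isclose(f, 0.5, atol=1e-12)
        assert np.all((f_sw == 1.0 - f) | (f == 1.0 - f_sw) | symmetric)

    def test_scaled_frequency_roundtrip_exact(self, rng):
        f = rng.random(100)
        x = scale_af(f)
        assert ((x >= -1) & (x <= 1)).all()
        assert np.array_equal((x + 1.0) / 2.0, f) or np.allclose(
            (x + 1.0) / 2.0, f, atol=0)


class TestGwas:
    def test_constant_column_gives_p_one(self, rng):
        trait = rng.normal(0, 1, 10)
        X = np.column_stack([np.full(10, 0.3), rng.normal(0, 1, 10)])
        res = glm_gwas(trait, X)
        assert res.loc[0, "p"] == 1.0 and res.loc[0, "slope"] == 0.0
        assert res.loc[1, "p"] < 1.0

    def test_exact_linear_trait(self):
        x = np.linspace(-1, 1, 12)
        res = glm_gwas(3.0 * x, x[:, None])
        assert res.loc[0, "slope"] == pytest.approx(3.0)
        assert res.loc[0, "p"] < 1e-12

    def test_star_tree_pgls_equals_glm(self, rng):
        star = Phylogeny.from_newick(
            "(" + ",".join(f"t{i}:1" for i in range(20)) + ");")
        trait = rng.normal(0, 1, 20)
        X = rng.random((20, 50))
        glm = glm_gwas(trait, X)
        pg = pgls_gwas(trait, X, star)
        assert np.allclose(glm["slope"], pg["slope"], atol=1e-10)
        assert np.allclose(glm["p"], pg["p"], atol=1e-10)

    def test_null_pvalues_uniform_on_star_tree(self):
        from scipy import stats
        rng = np.random.default_rng(11)
        trait = rng.normal(0, 1, 40)
        X = rng.random((40, 2000))
        res = glm_gwas(trait, X)
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    def test_pgls_absorbs_phylogenetic_structure(self):
        tree = simulate_tree(60, seed=5)
        C = tree.mrca_depths()
        L = np.linalg.cholesky(C + 1e-12 * np.eye(60))
        rng = np.random.default_rng(6)
        trait = L @ rng.standard_normal(60)
        X = L @ rng.standard_normal((60, 2000))   # structured null sites
        glm_rate = (glm_gwas(trait, X)["p"] < 0.05).mean()
        pgls_rate = (pgls_gwas(trait, X, tree)["p"] < 0.05).mean()
        assert pgls_rate < 0.08
        assert glm_rate > 0.15


class TestHavs:
    def test_trivial_cutoffs(self, rng):
        p1, p2 = rng.random(100), rng.random(100)
        assert call_havs(p1, p2, pgls_quantile=1.0, glm_cutoff=1.0).all()
        assert not call_havs(p1, p2, pgls_quantile=0.0, glm_cutoff=0.0).any()

    def test_pattern_clustering_properties(self, rng):
        A = np.vstack([np.tile(rng.random(6), (4, 1)),
                       np.tile(1 - rng.random(6) * 0.1, (3, 1))])
        labels = cluster_hav_patterns(A, k=2)
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[-1]
        perm = rng.permutation(len(A))
        relabeled = cluster_hav_patterns(A[perm], k=2)
        same = np.array([labels[i] for i in perm])
        agree = ((relabeled == relabeled[0]) == (same == same[0])).all()
        assert agree

    def test_identical_rows_one_cluster(self):
        A = np.tile(np.linspace(0, 1, 8), (5, 1))
        assert len(set(cluster_hav_patterns(A, k=1))) == 1


class TestGeneOverlap:
    def test_hypergeometric_matches_direct_summation(self):
        N, na, nb, k = 10_000, 100, 100, 10
        direct = sum(comb(na, i) * comb(N - na, nb - i) for i in
                     range(k, min(na, nb) + 1)) / comb(N, nb)
        res = gene_overlap_test([f"g{i}" for i in range(na)],
                                [f"g{i}" for i in range(na - k, na - k + nb)],
                                N)
        assert res["overlap"] == k
        assert res["p"] == pytest.approx(direct, rel=1e-9)

    def test_disjoint_sets_not_enriched(self):
        res = gene_overlap_test({"a", "b"}, {"c", "d"}, 8)
        assert res["overlap"] == 0 and res["p"] > 0.5

    def test_identical_sets_minimal_p(self):
        res = gene_overlap_test(set("abcde"), set("abcde"), 1000)
        assert res["overlap"] == 5 and res["p"] < 1e-10

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            gene_overlap_test({"a"}, {"a"}, 0)


class TestVcfRoundtrip:
    def test_panel_roundtrips_through_vcf(self, tmp_path):
        tree = simulate_tree(5, seed=6)
        panel = simulate_genotype_likelihoods(tree, n_sites=60, seed=7)
        path = tmp_path / "panel.vcf"
        write_vcf(path, panel.sites, panel.pl, panel.individuals)
        sites, pl, individuals = read_vcf(path)
        assert individuals == panel.individuals
        assert np.array_equal(pl, panel.pl)
        assert list(sites["pos"]) == list(panel.sites["pos"])
        assert list(sites["alt"]) == list(panel.sites["alt"])
        assert np.allclose(sites["QD"], panel.sites["QD"], rtol=1e-5)  # float32 INFO
        assert list(sites["DP"]) == list(panel.sites["DP"])


class TestScalingProperty:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(0.0, 1.0, allow_nan=False),
                    min_size=1, max_size=40))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_scaled_frequency_affine_map_round_trips(self, fs):
        f = np.asarray(fs)
        x = scale_af(f)
        assert ((x >= -1.0) & (x <= 1.0)).all()
        back = (x + 1.0) / 2.0
        # the map is exact where no rounding can occur (f = 0 or f >= 1/2,
        # by Sterbenz) and within half an ulp of 1 everywhere else
        exact = (f == 0.0) | (f >= 0.5)
        assert np.array_equal(back[exact], f[exact])
        assert np.abs(back - f).max() <= 2.0**-53
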