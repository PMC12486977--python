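"""Mixed-model association scans, inflation control, pooling, thresholds."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from resilind.gwas import (CHI2_1DF_MEDIAN, AssocResult, compute_grm_yang,
                           fisher_pool, genomic_inflation, manhattan_table,
                           mlma_scan, pooled_inflation, select_model,
                           significance_thresholds)
from resilind.plink import GenotypePanel
from resilind.simulate import simulate_indicator_trait


class TestYangGrm:
    def test_two_by_two_hand_oracle(self):
        g = np.array([[0, 2], [1, 1]], dtype=np.int8)
        panel = GenotypePanel(
            genotypes=g,
            snp_map=pd.DataFrame({"chrom": ["1", "1"], "snp": ["a", "b"],
                                  "cm": 0.0, "pos": [1, 2], "a1": "A", "a2": "B"}),
            samples=pd.DataFrame({"fid": ["f", "f"], "iid": ["1", "2"]}),
        )
        G, used = compute_grm_yang(panel)
        p = np.array([0.25, 0.75])
        het = 2 * p * (1 - p)
        z = (g - 2 * p) / np.sqrt(het)
        off = (z[0] * z[1]).mean()
        diag = [1 + np.mean((g[i] ** 2 - (1 + 2 * p) * g[i] + 2 * p ** 2) / het)
                for i in range(2)]
        assert G[0, 1] == pytest.approx(off, abs=1e-12)
        assert G[0, 0] == pytest.approx(diag[0], abs=1e-12)
        assert G[1, 1] == pytest.approx(diag[1], abs=1e-12)

    def test_duplicated_individuals(self, one_breed_panel):
        dup = one_breed_panel.subset(individuals=np.r_[0, 0, 1:40])
        G, _ = compute_grm_yang(dup)
        g = dup.dosages()
        p = g.mean(axis=0) / 2.0
        z = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
        # the off-diagonal of a duplicated pair is the plain standardized
        # self-similarity; the estimator's corrected diagonal agrees with it
        # only in expectation under HWE
        assert G[0, 1] == pytest.approx(np.mean(z[0] ** 2), abs=1e-12)
        assert G[0, 1] == pytest.approx(G[0, 0], abs=0.15)

    def test_mean_diagonal_near_one(self, one_breed_panel):
        G, _ = compute_grm_yang(one_breed_panel)
        assert np.diag(G).mean() == pytest.approx(1.0, abs=0.02)


class TestGenomicInflation:
    def test_unit_lambda_at_theoretical_median(self):
        chi2 = np.full(101, CHI2_1DF_MEDIAN)
        assert genomic_inflation(chi2=chi2) == pytest.approx(1.0)
        assert CHI2_1DF_MEDIAN == pytest.approx(0.455, abs=5e-4)

    def test_double_lambda(self):
        assert genomic_inflation(chi2=np.full(11, 0.91)) == pytest.approx(
            0.91 / CHI2_1DF_MEDIAN)

    def test_uniform_pvalues_give_unit_lambda(self):
        rng = np.random.default_rng(23)
        lam = genomic_inflation(pvalues=rng.uniform(size=100_000))
        assert lam == pytest.approx(1.0, abs=0.02)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            genomic_inflation(chi2=np.array([]))


class TestMlmaScan:
    def test_planted_qtl_is_top_hit(self, one_breed_panel):
        y, truth = simulate_indicator_trait(one_breed_panel, h2=0.3, rng=8,
                                            n_qtl=1, qtl_effect_sd=1.2)
        res = mlma_scan(y, one_breed_panel, "mlma")
        qtl = truth.qtl_positions["trait"][0]
        assert res.table["p"].idxmin() == qtl

    def test_loco_requires_multiple_chromosomes(self, one_breed_panel):
        chrom1 = one_breed_panel.snp_map["chrom"] == "1"
        single = one_breed_panel.subset(snps=chrom1.to_numpy())
        y = np.random.default_rng(0).standard_normal(single.n_individuals)
        with pytest.raises(ValueError, match="leave-one-chromosome-out"):
            mlma_scan(y, single, "loco")

    def test_zero_variance_snp_skipped(self, one_breed_panel):
        panel = one_breed_panel.subset(snps=np.arange(100))
        g = panel.genotypes.copy()
        g[:, 7] = 1
        panel.genotypes = g
        y = np.random.default_rng(1).standard_normal(panel.n_individuals)
        res = mlma_scan(y, panel, "mlma")
        assert np.isnan(res.table.loc[7, "p"])
        assert res.table["p"].drop(7).notna().all()

    def test_loco_equals_mlma_when_left_out_chromosome_is_duplicate(self, one_breed_panel):
        """Leaving out a chromosome that duplicates the rest of the genome
        does not change the (normalized) GRM, so LOCO == MLMA exactly."""
        chrom1 = (one_breed_panel.snp_map["chrom"] == "1").to_numpy()
        sub = one_breed_panel.subset(snps=chrom1)
        dup_map = sub.snp_map.copy()
        dup_map["chrom"] = "2"
        dup_map["snp"] = dup_map["snp"] + "_dup"
        panel = GenotypePanel(
            genotypes=np.hstack([sub.genotypes, sub.genotypes]),
            snp_map=pd.concat([sub.snp_map, dup_map], ignore_index=True),
            samples=sub.samples,
        )
        y = np.random.default_rng(2).standard_normal(panel.n_individuals)
        res_mlma = mlma_scan(y, panel, "mlma")
        res_loco = mlma_scan(y, panel, "loco")
        on_2 = res_loco.table["chrom"] == "2"
        np.testing.assert_allclose(res_loco.table.loc[on_2, "chi2"],
                                   res_mlma.table.loc[on_2, "chi2"], atol=1e-8)

    def test_pc_covariates_reduce_stratification_inflation(self):
        from resilind.config import SimConfig
        from resilind.simulate import simulate_genotypes
        cfg = SimConfig(n_per_breed=(250, 250), n_breeds=2, n_chrom=4,
                        n_snp_per_chrom=200, n_farms=4, fst=0.15, seed=19)
        panel = simulate_genotypes(cfg)
        rng = np.random.default_rng(4)
        # phenotype confounded with breed membership
        y = (panel.breed_label == "B1") * 1.0 + rng.standard_normal(panel.n_individuals) * 0.5
        lam_pc = mlma_scan(y, panel, "loco-pc", n_pcs=5).lambda_gc
        # plain GLS association without any polygenic/PC correction
        g = panel.dosages()
        g = (g - g.mean(axis=0))
        yc = y - y.mean()
        r = g.T @ yc / np.sqrt((g ** 2).sum(axis=0) * (yc ** 2).sum())
        chi2 = r ** 2 * (panel.n_individuals - 2) / (1 - r ** 2)
        lam_naive = genomic_inflation(chi2=chi2)
        assert lam_pc < lam_naive

    def test_null_calibration_all_variants(self, one_breed_panel):
        rng = np.random.default_rng(6)
        y = rng.standard_normal(one_breed_panel.n_individuals)
        for variant in ("mlma", "loco", "loco-pc"):
            res = mlma_scan(y, one_breed_panel, variant, n_pcs=5)
            p = res.table["p"].dropna()
            assert 0.8 < res.lambda_gc < 1.25
            assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.03)
            # p-value histogram roughly uniform
            hist, _ = np.histogram(p, bins=10, range=(0, 1))
            gof = stats.chisquare(hist).pvalue
            assert gof > 0.01


class TestSelectModel:
    @pytest.mark.parametrize("lams,expected", [
        ({"a": 0.98, "b": 1.30}, "a"),
        ({"a": 1.02, "b": 0.95}, "a"),
    ])
    def test_argmin_distance_to_one(self, lams, expected):
        chosen, report = select_model(lams)
        assert chosen == expected
        assert not report["rejected"].any()

    def test_guard_rejects_strong_inflation(self):
        chosen, report = select_model({"a": 1.6, "b": 1.45})
        assert chosen == "b"
        assert report.set_index("variant").loc["a", "rejected"]

    def test_all_rejected_raises_with_table(self):
        with pytest.raises(ValueError, match="lambda_GC"):
            select_model({"a": 1.6, "b": 1.9})

    def test_needs_two_candidates(self):
        with pytest.raises(ValueError):
            select_model({"a": 1.0})


class TestFisherPool:
    def test_all_ones_pool_to_one(self):
        p = pd.DataFrame({"b1": [1.0], "b2": [1.0], "b3": [1.0]})
        out = fisher_pool(p)
        assert out.loc[0, "fisher_x2"] == 0.0
        assert out.loc[0, "p_pooled"] == 1.0
        assert out.loc[0, "df"] == 6

    def test_exp_minus_one_inputs(self):
        p = pd.DataFrame({"b1": [np.exp(-1)], "b2": [np.exp(-1)], "b3": [np.exp(-1)]})
        out = fisher_pool(p)
        assert out.loc[0, "fisher_x2"] == pytest.approx(6.0)
        assert out.loc[0, "p_pooled"] == pytest.approx(stats.chi2.sf(6.0, 6), abs=1e-12)
        assert out.loc[0, "p_pooled"] == pytest.approx(0.4232, abs=1e-4)

    def test_uniform_inputs_pool_to_uniform(self):
        rng = np.random.default_rng(1)
        p = pd.DataFrame(rng.uniform(size=(50_000, 3)), columns=["a", "b", "c"])
        out = fisher_pool(p)
        ks = stats.kstest(out["p_pooled"], "uniform")
        assert ks.pvalue > 0.01

    def test_breed_order_invariance_and_monotonicity(self):
        p = pd.DataFrame({"b1": [0.3, 0.3], "b2": [0.01, 0.01], "b3": [0.7, 0.5]})
        out = fisher_pool(p)
        perm = fisher_pool(p[["b3", "b1", "b2"]])
        np.testing.assert_allclose(out["p_pooled"], perm["p_pooled"])
        assert out.loc[1, "p_pooled"] < out.loc[0, "p_pooled"]  # smaller input p

    def test_missing_snp_dropped_and_zero_clamped(self):
        p = pd.DataFrame({"b1": [0.5, np.nan], "b2": [0.0, 0.5], "b3": [0.5, 0.5]})
        out = fisher_pool(p)
        assert len(out) == 1
        assert out.attrs["n_dropped"] == 1
        assert out.attrs["n_zero_clamped"] == 1
        assert np.isfinite(out.loc[0, "fisher_x2"])


class TestThresholdsAndManhattan:
    @pytest.mark.parametrize("n,gw", [(500_000, 1e-7), (1, 0.05), (2969, 0.05 / 2969)])
    def test_threshold_values(self, n, gw):
        genome_wide, suggestive = significance_thresholds(n)
        assert genome_wide == pytest.approx(gw)
        assert suggestive == 5e-5

    def test_tier_counts_on_constructed_pvalues(self):
        n = 10_000  # Bonferroni level 5e-6, below the suggestive level
        gw, sug = significance_thresholds(n)
        p = np.full(n, 0.5)
        p[0] = gw / 2          # genome-wide
        p[1] = sug / 2          # suggestive only (> gw)
        p[2] = sug / 1.5        # suggestive only
        df = pd.DataFrame({"snp": [f"s{i}" for i in range(n)], "chrom": "1",
                           "pos": np.arange(1, n + 1), "p": p})
        annotated, counts = manhattan_table(df, (gw, sug))
        assert counts["genome-wide"] == 1
        assert counts["suggestive"] == 2
        assert counts["none"] == n - 3

    def test_tier_monotone_in_p(self):
        df = pd.DataFrame({"snp": ["a", "b", "c"], "chrom": "1",
                           "pos": [1, 2, 3], "p": [1e-9, 1e-5, 0.5]})
        annotated, _ = manhattan_table(df, (1e-7, 5e-5))
        order = {"genome-wide": 2, "suggestive": 1, "none": 0}
        tiers = annotated["tier"].map(order).to_numpy()
        assert np.all(np.diff(tiers) <= 0)

    def test_all_half_pvalues_nothing_significant(self):
        df = pd.DataFrame({"snp": ["a", "b"], "chrom": "1", "pos": [1, 2],
                           "p": [0.5, 0.5]})
        _, counts = manhattan_table(df)
        assert counts["genome-wide"] == 0 and counts["suggestive"] == 0


def test_pooled_lambda_convention():
    rng = np.random.default_rng(41)
    lam = pooled_inflation(rng.uniform(size=50_000))
    assert lam == pytest.approx(1.0, abs=0.03)
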