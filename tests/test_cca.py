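import math

import numpy as np
import pytest

from pleiocca import (
    BetaPanel,
    CausalGene,
    SimConfig,
    assemble_full_cov,
    cca_from_cov,
    effective_n,
    estimate_sigma_xx,
    estimate_sigma_yy,
    gene_scan,
    harmonize,
    oracle_cca,
    shrink_to_psd,
    simulate_gwas,
    simulate_reference,
    snp_scan,
    standardize_beta,
)
from pleiocca.cca import StandardizedBetaPanel, bartlett_chi2
from pleiocca.simulate import gene_table

from conftest import make_study


def sample_moment_bundle(X, Y, rng_id="u"):
    """Covariance blocks as the sample moments of one individual-level dataset."""
    Xs = (X - X.mean(0)) / X.std(0)
    Ys = (Y - Y.mean(0)) / Y.std(0)
    n = X.shape[0]
    sxx = Xs.T @ Xs / n
    syy = Ys.T @ Ys / n
    sxy = Xs.T @ Ys / n
    return assemble_full_cov(sxx, sxy, syy, rng_id)


class TestStandardize:
    def test_direct_evaluation(self):
        s = make_study("d", [("rs1", "1", 100, "A", "G", 0.05, 0.025)], n=400)
        std = standardize_beta(harmonize([s]))
        assert std.Bstd[0, 0] == pytest.approx(0.1)

    def test_zero_beta_stays_zero(self):
        s = make_study("d", [("rs1", "1", 100, "A", "G", 0.0, 0.3)], n=50)
        assert standardize_beta(harmonize([s])).Bstd[0, 0] == 0.0

    def test_approximates_genotype_phenotype_correlation(self):
        """Regression identity: beta/(se sqrt(n)) ~ sample correlation."""
        rng = np.random.default_rng(0)
        n = 2000
        g = rng.integers(0, 3, size=n).astype(float)
        y = 0.2 * (g - g.mean()) / g.std() + rng.standard_normal(n)
        gc = g - g.mean()
        beta = gc @ y / (gc @ gc)
        resid = y - y.mean() - beta * gc
        se = np.sqrt(resid @ resid / (n - 2) / (gc @ gc))
        bstd = beta / (se * np.sqrt(n))
        assert bstd == pytest.approx(np.corrcoef(g, y)[0, 1], abs=2 / np.sqrt(n))


class TestSigmaYY:
    def test_identical_columns_give_unit_offdiagonal(self):
        B = np.random.default_rng(0).standard_normal((100, 1))
        std = StandardizedBetaPanel(None, ["a", "b"], np.hstack([B, B]), np.array([10, 10]))
        syy = estimate_sigma_yy(std)
        assert syy[0, 1] == pytest.approx(1.0)

    def test_single_trait(self):
        B = np.random.default_rng(0).standard_normal((10, 1))
        std = StandardizedBetaPanel(None, ["a"], B, np.array([10]))
        np.testing.assert_array_equal(estimate_sigma_yy(std), [[1.0]])

    def test_null_offdiagonals_near_zero(self):
        S = 10_000
        B = np.random.default_rng(1).standard_normal((S, 4))
        std = StandardizedBetaPanel(None, list("abcd"), B, np.full(4, 10))
        syy = estimate_sigma_yy(std)
        off = syy[np.triu_indices(4, k=1)]
        assert np.all(np.abs(off) < 3 / np.sqrt(S))

    def test_too_few_rows_rejected(self):
        std = StandardizedBetaPanel(None, ["a"], np.ones((2, 1)), np.array([10]))
        with pytest.raises(ValueError, match="3 SNP rows"):
            estimate_sigma_yy(std)


class TestSigmaXX:
    def test_single_and_duplicate_snps(self, small_sim):
        panel = simulate_reference(small_sim)
        np.testing.assert_array_equal(estimate_sigma_xx(panel, np.array([0])), [[1.0]])

    def test_ar1_block_recovered(self):
        cfg = SimConfig(seed=5, n_reference=4000, n_cohorts=(100,), n_snps=8,
                        n_genes=1, block_rho=0.6)
        panel = simulate_reference(cfg)
        sxx = estimate_sigma_xx(panel, np.arange(8))
        # dosage correlation of thresholded latents is attenuated relative to
        # the latent rho; check monotone decay with distance instead of level
        d1 = np.mean(np.diag(sxx, 1))
        d4 = np.mean(np.diag(sxx, 4))
        assert d1 > d4 > -0.05
        assert d1 > 0.2


class TestAssembleAndShrink:
    def test_small_psd_case(self):
        b = assemble_full_cov(np.ones((1, 1)), [[0.1]], np.ones((1, 1)))
        np.testing.assert_allclose(b.full, [[1, 0.1], [0.1, 1]])
        assert b.psd

    def test_non_psd_min_eigenvalue(self):
        b = assemble_full_cov(np.ones((1, 1)), [[1.2]], np.ones((1, 1)))
        assert not b.psd
        assert b.min_eigenvalue == pytest.approx(-0.2)

    def test_blocks_reconstructed_exactly(self):
        rng = np.random.default_rng(3)
        sxx = np.corrcoef(rng.standard_normal((50, 3)), rowvar=False)
        syy = np.corrcoef(rng.standard_normal((50, 2)), rowvar=False)
        sxy = rng.standard_normal((3, 2)) * 0.1
        b = assemble_full_cov(sxx, sxy, syy)
        np.testing.assert_array_equal(b.full[:3, :3], sxx)
        np.testing.assert_array_equal(b.full[:3, 3:], sxy)
        np.testing.assert_array_equal(b.full[3:, 3:], syy)

    def test_psd_bundle_unchanged(self):
        b = assemble_full_cov(np.eye(2), np.zeros((2, 2)), np.eye(2))
        assert shrink_to_psd(b) is b

    def test_closed_form_iteration_count(self):
        tol, factor = 1e-8, 0.999
        b = assemble_full_cov(np.ones((1, 1)), [[1.2]], np.ones((1, 1)))
        s = shrink_to_psd(b, factor=factor, tol=tol)
        expected = math.ceil(math.log((1 - tol) / 1.2) / math.log(factor))
        assert s.shrink_iterations == expected
        assert s.psd

    def test_shrink_preserves_diagonal_and_shrinks_offdiagonal(self):
        rng = np.random.default_rng(8)
        sxy = rng.uniform(0.5, 0.9, size=(3, 3))
        b = assemble_full_cov(np.eye(3), sxy, np.eye(3))
        s = shrink_to_psd(b)
        np.testing.assert_array_equal(np.diag(s.full), np.diag(b.full))
        assert np.all(np.abs(s.full) <= np.abs(b.full) + 1e-15)


class TestCcaFromCov:
    def test_scalar_case_r_is_offdiagonal(self):
        b = assemble_full_cov(np.ones((1, 1)), [[0.1]], np.ones((1, 1)))
        res = cca_from_cov(b, 100)
        assert res.r == pytest.approx(0.1)
        assert res.df == 1

    def test_zero_cross_covariance(self):
        b = assemble_full_cov(np.eye(2), np.zeros((2, 3)), np.eye(3))
        res = cca_from_cov(b, 100)
        assert res.r == 0.0
        assert res.pvalue == 1.0
        assert res.df == 6

    def test_non_psd_rejected(self):
        b = assemble_full_cov(np.ones((1, 1)), [[1.2]], np.ones((1, 1)))
        with pytest.raises(ValueError, match="PSD"):
            cca_from_cov(b, 100)

    def test_matches_individual_level_oracle(self):
        """Sample-moment CCA equals textbook individual-level CCA."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            g, p = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            n = 500
            X = rng.standard_normal((n, g)) + 0.1 * rng.standard_normal((n, 1))
            Y = rng.standard_normal((n, p)) + 0.3 * X[:, :1]
            b = sample_moment_bundle(X, Y)
            if not b.psd:
                b = shrink_to_psd(b)
            assert cca_from_cov(b, n).r == pytest.approx(oracle_cca(X, Y).r, abs=1e-8)

    def test_scale_invariance(self, two_studies):
        panel = harmonize(two_studies, ambiguous_policy="keep")
        scaled = BetaPanel(
            snps=panel.snps, diseases=panel.diseases,
            B=panel.B * np.array([1.0, 7.5]), SE=panel.SE * np.array([1.0, 7.5]),
            N=panel.N,
        )
        np.testing.assert_allclose(
            standardize_beta(panel).Bstd, standardize_beta(scaled).Bstd
        )

    def test_monotone_in_cross_covariance_scale(self):
        rng = np.random.default_rng(6)
        sxx = np.corrcoef(rng.standard_normal((200, 3)), rowvar=False)
        syy = np.corrcoef(rng.standard_normal((200, 2)), rowvar=False)
        sxy = rng.standard_normal((3, 2)) * 0.05
        rs = []
        for c in (0.2, 0.5, 1.0):
            b = assemble_full_cov(sxx, c * sxy, syy)
            if not b.psd:
                b = shrink_to_psd(b)
            rs.append(cca_from_cov(b, 200).r)
        assert rs[0] <= rs[1] <= rs[2] + 1e-12


class TestScans:
    def test_zero_beta_snp_has_p_one(self):
        std = StandardizedBetaPanel(
            __import__("pandas").DataFrame({"SNP": ["rs0"]}),
            ["a", "b"], np.zeros((1, 2)), np.array([500, 500]),
        )
        res = snp_scan(std, np.eye(2), np.array([0]), 400)
        assert res[0].pvalue == 1.0

    def test_single_trait_scan_monotone_in_z(self):
        """With p=1 the chi-square statistic is the Bartlett-scaled squared
        standardized beta, so it must be monotone in |z|."""
        import pandas as pd

        n = 1000
        z = np.array([-3.0, -1.0, 0.5, 2.0, 4.0])
        bstd = (z / np.sqrt(n)).reshape(-1, 1)
        std = StandardizedBetaPanel(
            pd.DataFrame({"SNP": [f"rs{i}" for i in range(5)]}),
            ["a"], bstd, np.array([n]),
        )
        res = snp_scan(std, np.ones((1, 1)), np.arange(5), n)
        stats_by_absz = [r.statistic for r in sorted(res, key=lambda r: abs(bstd[int(r.unit_id[2:]), 0]))]
        assert stats_by_absz == sorted(stats_by_absz)
        expected = -(n - 1 - 1.5) * np.log(1 - (z[-1] ** 2) / n)
        assert res[4].statistic == pytest.approx(expected)

    def test_single_member_gene_equals_snp_result(self, small_sim):
        ref = simulate_reference(small_sim)
        studies, _, _ = simulate_gwas(small_sim)
        panel = harmonize(studies, ambiguous_policy="keep")
        std = standardize_beta(panel)
        syy = estimate_sigma_yy(std)
        n_eff = effective_n(panel.N)
        from pleiocca.reference import GeneRegion

        gene = GeneRegion("g1", "1", 1, 10, member_snps=np.array([4]))
        [gr] = gene_scan(std, ref, [gene], syy, np.arange(panel.n_snps), n_eff)
        [sr] = snp_scan(std, syy, np.array([4]), n_eff)
        assert gr.r == pytest.approx(sr.r)
        assert gr.pvalue == pytest.approx(sr.pvalue)

    def test_causal_gene_ranks_first(self):
        """A gene with a shared effect across traits beats all null genes."""
        wins = 0
        for seed in range(10):
            cfg = SimConfig(
                seed=seed, n_reference=300, n_cohorts=(5000,) * 5, n_snps=200,
                n_genes=25, block_rho=0.5,
                causal_genes=[CausalGene(11, (0, 1, 2), 0.05)],
            )
            ref = simulate_reference(cfg)
            studies, truth, _ = simulate_gwas(cfg)
            panel = harmonize(studies, ambiguous_policy="keep")
            std = standardize_beta(panel)
            syy = estimate_sigma_yy(std)
            from pleiocca.reference import assign_snps_to_genes

            genes, _ = assign_snps_to_genes(ref, gene_table(cfg))
            res = gene_scan(std, ref, genes, syy, np.arange(ref.n_snps),
                            effective_n(panel.N))
            best = min(res, key=lambda r: (r.pvalue, -r.statistic))
            wins += best.unit_id == "GENE011"
        assert wins >= 9

    def test_effective_n_rules(self):
        N = np.array([100, 400])
        assert effective_n(N, "min") == 100
        assert effective_n(N, "harmonic") == 160
        assert effective_n(N, "mean") == 250
        with pytest.raises(ValueError):
            effective_n(N, "median")
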