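"""Synthetic genotypes, RINT, expression studies, and summary-stat pairs."""

import math

import numpy as np
import pytest
from scipy import stats

from eqtlpower import (
    LocusConfig,
    coloc_abf,
    rank_inverse_normal,
    simulate_expression_study,
    simulate_genotypes,
    simulate_summary_stats_pair,
)


class TestSimulateGenotypes:
    def test_hwe_genotype_frequencies(self):
        maf, n = 0.25, 50_000
        g = simulate_genotypes(n, 4, maf, ld_rho=0.0, seed=1)
        expected = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
        for j in range(4):
            freqs = np.bincount(g.values[:, j], minlength=3) / n
            se = np.sqrt(expected * (1 - expected) / n)
            assert np.all(np.abs(freqs - expected) < 3 * se + 1e-9)

    def test_no_ld_when_rho_zero(self):
        g = simulate_genotypes(10_000, 5, 0.3, ld_rho=0.0, seed=2)
        corr = np.corrcoef(g.values.T)
        off = corr[np.triu_indices(5, k=1)]
        assert np.all(np.abs(off) < 3.0 / math.sqrt(10_000))

    def test_ld_decays_with_distance(self):
        g = simulate_genotypes(20_000, 10, 0.3, ld_rho=0.7, seed=3)
        corr = np.corrcoef(g.values.T)
        adjacent = np.mean([corr[i, i + 1] for i in range(9)])
        distant = np.mean([corr[i, i + 5] for i in range(5)])
        assert adjacent > distant > -0.05
        assert adjacent > 0.2

    def test_determinism(self):
        a = simulate_genotypes(500, 8, 0.2, ld_rho=0.4, seed=7)
        b = simulate_genotypes(500, 8, 0.2, ld_rho=0.4, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            simulate_genotypes(100, 2, 0.6, seed=0)
        with pytest.raises(ValueError):
            simulate_genotypes(100, 2, 0.3, ld_rho=1.0, seed=0)

    def test_tsv_round_trip(self, tmp_path):
        g = simulate_genotypes(50, 4, 0.3, seed=5)
        path = tmp_path / "g.tsv"
        g.to_tsv(path)
        back = type(g).from_tsv(path)
        assert np.array_equal(back.values, g.values)
        assert np.array_equal(back.positions, g.positions)


class TestRankInverseNormal:
    def test_blom_three_values(self):
        # Phi^-1 of (i - 3/8) / 3.25 for i = 1, 2, 3
        out = rank_inverse_normal([10.0, -5.0, 3.0])
        expected = stats.norm.ppf((np.array([3, 1, 2]) - 0.375) / 3.25)
        assert np.allclose(out, expected, atol=1e-12)
        assert out[1] == pytest.approx(-0.8694, abs=1e-4)

    def test_matches_brute_force_oracle(self, rng):
        x = rng.normal(size=101) ** 3  # heavy-tailed input
        out = rank_inverse_normal(x)
        # brute force: rank each value by counting, then quantile
        n = len(x)
        expected = np.array([
            stats.norm.ppf(((np.sum(x < xi) + (np.sum(x == xi) + 1) / 2) - 0.375)
                           / (n + 0.25))
            for xi in x
        ])
        assert np.allclose(out, expected, atol=1e-12)

    def test_rank_invariance_under_shuffle(self, rng):
        x = rng.normal(size=50)
        perm = rng.permutation(50)
        assert np.allclose(np.sort(rank_inverse_normal(x)),
                           np.sort(rank_inverse_normal(x[perm])))

    def test_output_symmetric_around_zero(self, rng):
        out = rank_inverse_normal(rng.uniform(size=999))
        assert abs(out.mean()) < 1e-10

    def test_ties_get_average_rank(self):
        out = rank_inverse_normal([1.0, 2.0, 2.0, 3.0])
        assert out[1] == pytest.approx(out[2])

    def test_degenerate_input(self):
        with pytest.raises(ValueError, match="degenerate"):
            rank_inverse_normal([2.0, 2.0, 2.0])


class TestSimulateExpressionStudy:
    def test_planted_r_recovered(self):
        n = 50_000
        g = simulate_genotypes(n, 3, 0.3, seed=21)
        study = simulate_expression_study(g, [(1, 0.2)], noise_seed=22)
        r_hat = np.corrcoef(g.values[:, 1], study.expression)[0, 1]
        se = (1 - 0.2**2) / math.sqrt(n)
        assert abs(r_hat - 0.2) < 3 * se

    def test_two_orthogonal_signals_recovered(self):
        n = 100_000
        g = simulate_genotypes(n, 4, 0.3, ld_rho=0.0, seed=23)
        study = simulate_expression_study(g, [(0, 0.3), (3, 0.2)], noise_seed=24)
        X = np.column_stack([np.ones(n), g.values[:, 0], g.values[:, 3]])
        coef, *_ = np.linalg.lstsq(X, study.expression, rcond=None)
        sd_g = math.sqrt(2 * 0.3 * 0.7)
        assert coef[1] * sd_g == pytest.approx(0.3, abs=0.01)
        assert coef[2] * sd_g == pytest.approx(0.2, abs=0.01)

    def test_null_study_uncorrelated(self):
        n = 20_000
        g = simulate_genotypes(n, 10, 0.3, seed=25)
        study = simulate_expression_study(g, [], noise_seed=26)
        corrs = [abs(np.corrcoef(g.values[:, j], study.expression)[0, 1])
                 for j in range(10)]
        assert max(corrs) < 4.0 / math.sqrt(n)

    def test_infeasible_architecture_rejected(self):
        g = simulate_genotypes(100, 3, 0.3, seed=27)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_expression_study(g, [(0, 0.8), (1, 0.7)])

    def test_expression_is_rint_standardized(self):
        g = simulate_genotypes(1000, 2, 0.3, seed=28)
        study = simulate_expression_study(g, [(0, 0.2)], noise_seed=29)
        # RINT output is a deterministic set of normal quantiles
        assert abs(study.expression.mean()) < 1e-10
        assert study.expression.std() == pytest.approx(1.0, abs=0.01)


class TestSummaryStatsPair:
    def test_shared_strong_signal_colocalizes(self):
        locus = LocusConfig(n_variants=30, ld_rho=0.3, r_eqtl=0.3, r_gwas=0.1,
                            causal_index=10)
        eqtl, gwas = simulate_summary_stats_pair(
            locus, n_eqtl=10_000, n_gwas=50_000, shared=True, seed=31
        )
        res = coloc_abf(eqtl, gwas)
        assert res.pph4 > 0.9

    def test_distinct_unlinked_signals_do_not_colocalize(self):
        locus = LocusConfig(n_variants=30, ld_rho=0.0, r_eqtl=0.3, r_gwas=0.1,
                            causal_index=2, gwas_causal_index=27)
        eqtl, gwas = simulate_summary_stats_pair(
            locus, n_eqtl=10_000, n_gwas=50_000, shared=False, seed=32
        )
        res = coloc_abf(eqtl, gwas)
        assert res.pph3 > 0.9

    def test_empty_study_rejected(self):
        with pytest.raises(ValueError):
            simulate_summary_stats_pair(LocusConfig(), n_eqtl=0, n_gwas=100,
                                        shared=True)

    def test_determinism(self):
        locus = LocusConfig(n_variants=10, r_eqtl=0.2)
        a1, b1 = simulate_summary_stats_pair(locus, 500, 500, True, seed=33)
        a2, b2 = simulate_summary_stats_pair(locus, 500, 500, True, seed=33)
        assert np.array_equal(a1.betas, a2.betas)
        assert np.array_equal(b1.ses, b2.ses)
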