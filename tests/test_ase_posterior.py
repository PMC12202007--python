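"""Posterior quadrature, latent-π marginalization, p-values, FDR."""

import numpy as np
import pytest
from scipy.stats import binom, norm

from beastie.ase_posterior import (
    AseResult,
    PriorSpec,
    bh_fdr,
    fit_genes,
    null_pvalue,
    posterior_theta,
    posterior_theta_latent_pi,
    select_extreme_ase,
)

from conftest import brute_force_likelihood, make_gene


def dense_posterior_median_log2(N, X, sigma, K=100_001, bound=np.log(128.0)):
    """Independent 1-D quadrature oracle for a SINGLE-site gene."""
    grid = np.linspace(-bound, bound, K)
    p = 1.0 / (1.0 + np.exp(-grid))
    dens = norm.pdf(grid, 0, sigma) * binom.pmf(X, N, p)
    cdf = np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))
    cdf = np.concatenate([[0], cdf]) / cdf[-1]
    return np.interp(0.5, cdf, grid) / np.log(2)


class TestPosteriorTheta:
    def test_density_normalized(self):
        g = make_gene([10, 20, 15], [3, 12, 9], [0, 1, 0], pi=[0.05, 0.1])
        post = posterior_theta(g)
        assert np.trapezoid(post.density, post.grid) == pytest.approx(1.0, abs=1e-8)
        assert np.all(post.density >= 0)

    def test_balanced_gene_centered_at_zero(self):
        g = make_gene([20, 20, 20, 20], [10, 10, 10, 10], [0, 1, 0, 1], pi=[0.1] * 3)
        post = posterior_theta(g)
        step = post.grid[1] - post.grid[0]
        assert abs(post.median_log2) < step / np.log(2)
        assert abs(post.mean_log2) < 1e-8

    def test_single_site_matches_dense_quadrature_oracle(self):
        g = make_gene([20], [15], [0])
        post = posterior_theta(g, PriorSpec(sigma=10.0))
        oracle = dense_posterior_median_log2(20, 15, sigma=10.0)
        assert post.median_log2 == pytest.approx(oracle, abs=2e-3)
        # theta mode near 3 (p near 0.75)
        mode = np.exp(post.grid[np.argmax(post.density)])
        assert 2.5 < mode < 3.6

    def test_mirror_symmetry(self):
        g = make_gene([20, 10], [15, 2], [0, 1], pi=[0.08])
        m = make_gene([20, 10], [5, 8], [0, 1], pi=[0.08])
        a = posterior_theta(g)
        b = posterior_theta(m)
        assert np.allclose(a.density, b.density[::-1], rtol=1e-8, atol=1e-12)
        assert a.median_log2 == pytest.approx(-b.median_log2, abs=1e-6)

    def test_median_inside_credible_interval(self):
        g = make_gene([30, 25], [22, 6], [0, 1], pi=[0.05])
        post = posterior_theta(g)
        lo, hi = post.credible_interval(0.05)
        assert lo <= post.theta_median <= hi

    def test_grid_convergence(self):
        g = make_gene([20, 20, 20], [14, 13, 15], [0, 0, 0], pi=[0.05, 0.05])
        a = posterior_theta(g, K=1001)
        b = posterior_theta(g, K=2001)
        assert a.median_log2 == pytest.approx(b.median_log2, abs=1e-4)
        assert a.mean_log2 == pytest.approx(b.mean_log2, abs=1e-4)

    def test_no_reads_rejected(self):
        g = make_gene([0, 0], [0, 0], [0, 1], pi=[0.05])
        with pytest.raises(ValueError, match="no reads"):
            posterior_theta(g)

    def test_default_pi_filled_when_missing(self):
        g = make_gene([10, 10], [7, 6], [0, 0])  # pi None
        a = posterior_theta(g)
        b = posterior_theta(g.with_pi(0.05))
        assert np.allclose(a.density, b.density)


class TestLatentPi:
    def test_single_site_identical_to_known_pi(self):
        g = make_gene([20], [14], [0])
        a = posterior_theta_latent_pi(g)
        b = posterior_theta(g)
        assert np.allclose(a.density, b.density)

    def test_point_mass_prior_equals_fixed_pi(self):
        g = make_gene([15, 10, 20], [11, 3, 13], [0, 1, 0])
        a = posterior_theta_latent_pi(g, PriorSpec(latent_pi=("point", 0.05)))
        b = posterior_theta(g.with_pi(0.05))
        assert np.allclose(a.density, b.density, rtol=1e-10)

    def test_uniform_prior_matches_brute_force_2d_quadrature(self):
        import itertools

        g = make_gene([15, 10, 20], [11, 3, 13], [0, 1, 0])
        K = 201
        post = posterior_theta_latent_pi(g, K=K)
        # Independent oracle: enumerate the 4 phasings explicitly; each
        # phasing's chain weight is a polynomial in the shared pi, integrated
        # by dense trapezoid against the Uniform(0, 0.5) prior; the emission
        # product is computed per grid point.
        grid = post.grid
        N, X, ph = g.total_counts, g.alt_counts, g.phases
        r = int(np.argmax(N))
        pis = np.linspace(0.0, 0.5, 4001)
        dens = np.zeros(K)
        for par in itertools.product((0, 1), repeat=g.n):
            if par[r] != 0:
                continue
            w = np.ones_like(pis)
            for i in range(g.n - 1):
                w = w * (pis if par[i] != par[i + 1] else 1.0 - pis)
            w_int = np.trapezoid(w, pis) / 0.5  # prior density 2 on [0, 0.5]
            p = 1.0 / (1.0 + np.exp(-grid))
            lik = np.ones(K)
            for i in range(g.n):
                q = p if (ph[i] ^ par[i]) == 0 else 1.0 - p
                lik = lik * binom.pmf(X[i], N[i], q)
            dens += w_int * lik
        dens *= norm.pdf(grid, 0, 1.0)
        dens /= np.trapezoid(dens, grid)
        assert np.allclose(post.density, dens, rtol=1e-6, atol=1e-9)

    def test_latent_interval_not_sharper_than_true_pi_interval(self):
        # marginalizing an unknown pi cannot beat knowing the true pi, on average
        from beastie.simulator import SimConfig, simulate_gene

        rng = np.random.default_rng(8)
        cfg = SimConfig(n_hets=8, depth=10, theta=0.5, switch_rate=0.05)
        widths_known, widths_latent = [], []
        for i in range(40):
            g, _ = simulate_gene(cfg, rng, f"g{i}")
            lo, hi = posterior_theta(g.with_pi(0.05)).credible_interval()
            widths_known.append(np.log(hi) - np.log(lo))
            lo, hi = posterior_theta_latent_pi(g).credible_interval()
            widths_latent.append(np.log(hi) - np.log(lo))
        assert np.mean(widths_latent) >= np.mean(widths_known)


class TestNullPvalue:
    def test_b_too_small_rejected(self):
        g = make_gene([20], [15], [0])
        with pytest.raises(ValueError):
            null_pvalue(g, B=50)

    def test_extreme_imbalance_gives_minimal_p(self):
        g = make_gene([200, 200], [197, 2], [0, 1], pi=[0.01])
        p = null_pvalue(g, B=199, seed=3)
        assert p == pytest.approx(1 / 200)

    def test_balanced_gene_gives_large_p(self):
        g = make_gene([50, 50], [25, 25], [0, 1], pi=[0.05])
        p = null_pvalue(g, B=199, seed=4)
        assert p > 0.5

    def test_seed_reproducible(self):
        g = make_gene([20, 10], [14, 3], [0, 1], pi=[0.05])
        assert null_pvalue(g, B=200, seed=11) == null_pvalue(g, B=200, seed=11)


class TestBhFdr:
    def test_step_up_hand_example(self):
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_equal_ps_unchanged(self):
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_empty_and_invalid(self):
        assert len(bh_fdr([])) == 0
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


class TestSelectExtremeAse:
    @staticmethod
    def _res(gid, mag, fdr):
        return AseResult(gid, 1, 10, 1.0, mag, abs(mag), 0.5, 2.0, 0.01, fdr, fdr < 0.05)

    def test_none_significant(self):
        results = [self._res(f"g{i}", 1.0, 0.5) for i in range(4)]
        assert select_extreme_ase(results) == []

    def test_top_quartile_rule(self):
        mags = [0.1, 0.5, 1.0, 4.0]
        results = [self._res(f"g{i}", m, 0.001) for i, m in enumerate(mags)]
        assert select_extreme_ase(results) == ["g3"]

    def test_single_gene_is_its_own_quartile(self):
        results = [self._res("only", 0.3, 0.001)]
        assert select_extreme_ase(results) == ["only"]


class TestFitGenes:
    def test_results_and_reordering_stability(self):
        genes = [
            make_gene([20, 20], [18, 3], [0, 1], pi=[0.05], gene_id="a"),
            make_gene([20, 20], [11, 10], [0, 1], pi=[0.05], gene_id="b"),
            make_gene([20, 20], [15, 5], [0, 1], pi=[0.05], gene_id="c"),
        ]
        res = fit_genes(genes, B=200, seed=1)
        res_rev = fit_genes(genes[::-1], B=200, seed=1)
        by_id = {r.gene_id: r for r in res_rev}
        for r in res:
            assert r.pvalue == by_id[r.gene_id].pvalue
            assert r.fdr == by_id[r.gene_id].fdr
        # FDR never below its own p-value
        for r in res:
            assert r.fdr >= r.pvalue - 1e-12
            assert r.ase_call == (r.fdr < 0.05)

    def test_empty_genes_skipped(self):
        genes = [make_gene([], [], [], pi=np.empty(0), gene_id="empty"),
                 make_gene([20], [15], [0], gene_id="ok")]
        res = fit_genes(genes, compute_pvalues=False)
        assert [r.gene_id for r in res] == ["ok"]
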