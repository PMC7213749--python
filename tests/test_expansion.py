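"""Expansion prior, two-time-point likelihood, s0 constraint, EM, family comparison."""

import numpy as np
import pytest
from scipy import integrate, optimize, stats

from clonexp.expansion import (
    EXPANSION_FAMILIES,
    ExpansionKernel,
    ExpansionPrior,
    SGrid,
    compare_prior_families,
    em_fit_sbar,
    em_update_sbar,
    expansion_prior_density,
    fit_expansion,
    pair_likelihood_expansion,
)
from clonexp.noise import NoiseModel, SampleContext
from clonexp.null_inference import pair_likelihood
from clonexp.simulate import SimulationConfig, sample_expansion_pair


class TestPriorDensity:
    def test_alpha_zero_puts_all_mass_in_atom(self):
        dens, atom = expansion_prior_density(np.linspace(-5, 5, 11), ExpansionPrior("sym_exp", 0.0, 1.0, s0=-0.3))
        assert atom == 1.0
        assert np.all(dens == 0.0)

    def test_symmetric_exponential_integrates_to_alpha(self):
        """Grid quadrature of the continuous part converges to alpha: the
        default 0.1 step carries the O(h^2) trapezoid error of the kink
        (~1e-3 relative), a 0.02 step is inside 1e-4."""
        prior = ExpansionPrior("sym_exp", 0.37, 0.8, s0=0.2)
        coarse = SGrid.make()
        dens, atom = expansion_prior_density(coarse.nodes, prior)
        assert np.isclose(coarse.trap_weights @ dens, 0.37, atol=2e-3)
        assert atom == pytest.approx(0.63)
        fine = SGrid.make(step=0.02)
        dens_f, _ = expansion_prior_density(fine.nodes, prior)
        assert np.isclose(fine.trap_weights @ dens_f, 0.37, atol=1e-4)

    def test_one_sided_family_has_no_mass_below_s0(self):
        prior = ExpansionPrior("asym_exp", 0.5, 1.0, s0=-1.0)
        s = np.array([-3.0, -1.5, -1.0, -0.5, 2.0])
        dens, _ = expansion_prior_density(s, prior)
        assert np.all(dens[s <= -1.0] == 0.0)
        assert np.all(dens[s > -1.0] > 0.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ExpansionPrior("sym_exp", -0.1, 1.0)
        with pytest.raises(ValueError):
            ExpansionPrior("sym_exp", 1.2, 1.0)
        with pytest.raises(ValueError):
            ExpansionPrior("sym_exp", 0.1, 0.0)
        with pytest.raises(ValueError):
            ExpansionPrior("weibull", 0.1, 1.0)


class TestPairLikelihoodExpansion:
    def test_reduces_to_null_likelihood_when_prior_collapses(self):
        """alpha = 0 and s0 = 0 recover the replicate (null) pair likelihood:
        the two conditioning code paths agree."""
        cfg = SimulationConfig(N=10**4, nu=2.0, noise="poisson", n_reads_1=2e3, n_reads_2=2e3)
        prior, model = cfg.prior(), cfg.model()
        ctx, ctxp = cfg.contexts()
        collapsed = ExpansionPrior("sym_exp", 0.0, 1.0, s0=0.0)
        for n, npr in [(0, 0), (1, 0), (3, 5), (40, 35)]:
            a = pair_likelihood_expansion(n, npr, prior, model, ctx, ctxp, collapsed, grid_points=400)
            b = pair_likelihood(n, npr, prior, model, ctx, ctxp, grid_points=400)
            assert np.isclose(a, b, rtol=1e-12)

    def test_sums_to_one_over_count_plane(self):
        """Sum over every (n, n') including (0,0) is 1 to grid accuracy."""
        cfg = SimulationConfig(N=5000, nu=2.0, noise="poisson", n_reads_1=300, n_reads_2=300)
        prior, model = cfg.prior(), cfg.model()
        ctx, ctxp = cfg.contexts()
        exp_prior = ExpansionPrior("sym_exp", 0.3, 0.8, s0=-0.1)
        n_max = 100
        nn, pp = np.meshgrid(np.arange(n_max), np.arange(n_max), indexing="ij")
        probs = pair_likelihood_expansion(
            nn.ravel(), pp.ravel(), prior, model, ctx, ctxp, exp_prior,
            sgrid=SGrid.make(lo=-10.0, hi=10.0), grid_points=400,
        )
        assert np.isclose(probs.sum(), 1.0, atol=1e-4)

    def test_point_mass_prior_matches_quad_oracle(self):
        """With a frequency point mass the double integral collapses to 1-D in
        s; piecewise adaptive quadrature is the independent oracle.  The
        default 0.1 step is accurate to ~1e-3 relative; a 10x-refined grid
        tightens to ~1e-5 (trapezoid convergence through the prior kink)."""
        f0, Nr = 1e-4, 1e6
        model = NoiseModel("poisson")
        ctx = SampleContext(Nr)
        ep = ExpansionPrior("sym_exp", 0.3, 0.8, s0=-0.05)

        def integrand(s):
            return (
                np.exp(-abs(s - ep.s0) / ep.sbar) / (2 * ep.sbar)
                * stats.poisson.pmf(100, f0 * Nr)
                * stats.poisson.pmf(150, f0 * np.exp(s) * Nr)
            )

        edges = np.concatenate([np.linspace(-15, ep.s0, 25), np.linspace(ep.s0, 15, 35)[1:]])
        tail = sum(
            integrate.quad(integrand, a, b, limit=200, epsabs=1e-18, epsrel=1e-13)[0]
            for a, b in zip(edges[:-1], edges[1:])
        )
        oracle = (
            (1 - ep.alpha) * stats.poisson.pmf(100, f0 * Nr)
            * stats.poisson.pmf(150, f0 * np.exp(ep.s0) * Nr)
            + ep.alpha * tail
        )
        coarse = pair_likelihood_expansion(
            100, 150, None, model, ctx, ctx, ep, sgrid=SGrid.make(step=0.1), f_measure=([f0], [1.0])
        )
        fine = pair_likelihood_expansion(
            100, 150, None, model, ctx, ctx, ep, sgrid=SGrid.make(step=0.01), f_measure=([f0], [1.0])
        )
        assert abs(coarse / oracle - 1.0) < 2e-3
        assert abs(fine / oracle - 1.0) < 5e-5


class TestSolveS0:
    def test_collapsed_prior_needs_no_shift(self, expansion_dataset):
        """alpha = 0 leaves both repertoire budgets identical: s0 = 0."""
        cfg, table, truth, null, kernel = expansion_dataset
        prior = kernel.solve_s0("sym_exp", 0.0, 1.0)
        assert prior.s0 == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_shift_identity(self, expansion_dataset):
        """s0 = -ln(Z'_0 / Z) with Z'_0 evaluated at zero shift."""
        cfg, table, truth, null, kernel = expansion_dataset
        prior = kernel.solve_s0("sym_exp", 0.04, 1.2)
        Z, Zp0 = kernel.normalizations(ExpansionPrior("sym_exp", 0.04, 1.2, s0=0.0))
        assert prior.s0 == pytest.approx(-np.log(Zp0 / Z), rel=1e-12)

    def test_more_expansion_needs_more_contraction(self, expansion_dataset):
        """Raising the responding fraction drives the global shift further
        negative (expansion of a few compensated by contraction of all)."""
        cfg, table, truth, null, kernel = expansion_dataset
        s0s = [kernel.solve_s0("asym_exp", a, 1.0).s0 for a in (0.001, 0.01, 0.1)]
        assert s0s[0] > s0s[1] > s0s[2]
        assert s0s[0] < 0.0


class TestFitExpansion:
    def test_recovers_scale_on_one_realization(self, expansion_dataset):
        """A single mouse-sized fit lands on the likelihood ridge through the
        generating point (sbar within a factor ~2, alpha within a factor ~4;
        the ensemble-mean behavior is exercised in the acceptance suite)."""
        cfg, table, truth, null, kernel = expansion_dataset
        fit = fit_expansion(table, null, family="sym_exp", kernel=kernel, compute_errors=False)
        assert 0.5 < fit.prior.sbar < 2.0
        assert 0.0125 < fit.prior.alpha < 0.2
        assert fit.prior.s0 < 0.0

    def test_deeper_repertoires_constrain_the_prior_more(self):
        """A larger, more deeply sequenced repertoire shrinks the
        inverse-Fisher ellipse of (ln alpha, ln sbar) by orders of magnitude
        relative to the mouse-sized configuration: more sampled responders,
        much tighter empirical-Bayes estimates."""
        dets = {}
        for name, kw in [
            ("mouse", dict(N=10**6, n_reads_1=1e4, n_reads_2=1e4)),
            ("deep", dict(N=10**7, n_reads_1=2e5, n_reads_2=2e5)),
        ]:
            cfg = SimulationConfig(
                nu=2.0, noise="poisson", seed=4,
                expansion=ExpansionPrior("asym_exp", 0.01, 1.0), **kw,
            )
            table, _ = sample_expansion_pair(cfg)
            fit = fit_expansion(
                table, (cfg.prior(), cfg.model(), *cfg.contexts()), family="asym_exp",
                grid_points=800,
            )
            dets[name] = float(np.linalg.det(fit.covariance))
        assert dets["deep"] < dets["mouse"] / 10.0

    def test_likelihood_ridge_orientation(self, expansion_dataset):
        """The inverse-Fisher ellipse in (ln alpha, ln sbar) has its long axis
        on a negative-slope diagonal: the product alpha*sbar is identified,
        the factors are not."""
        cfg, table, truth, null, kernel = expansion_dataset
        fit = fit_expansion(table, null, family="sym_exp", kernel=kernel)
        cov = fit.covariance
        eigvals, eigvecs = np.linalg.eigh(cov)
        major = eigvecs[:, np.argmax(eigvals)]
        assert major[0] * major[1] < 0.0
        assert eigvals.max() / max(eigvals.min(), 1e-12) > 4.0


@pytest.fixture(scope="module")
def em_kernel():
    """Data from the tractable regime the M-step is derived for: pure
    symmetric-exponential fold changes (alpha = 1), no shift."""
    cfg = SimulationConfig(
        N=3 * 10**4, nu=2.0, noise="poisson", n_reads_1=6e3, n_reads_2=6e3,
        expansion=ExpansionPrior("sym_exp", 1.0, 0.5), seed=8,
    )
    table, _ = sample_expansion_pair(cfg)
    return ExpansionKernel(table, cfg.prior(), cfg.model(), *cfg.contexts(), grid_points=500)


class TestEm:
    def test_delta_posterior_returns_its_location(self):
        """If every clone's posterior is a spike at s = 1 the update gives
        sbar* = 1 exactly."""
        sgrid = SGrid.make()
        j = int(np.argmin(np.abs(sgrid.nodes - 1.0)))

        class SpikeKernel:
            pass

        k = SpikeKernel()
        k.sgrid = sgrid
        k.L = np.zeros((4, len(sgrid.nodes)))
        k.L[:, j] = 1.0  # includes the (0,0) row; observed rows are L[:-1]
        k.counts = np.ones(3)
        k.n_obs = 3
        assert em_update_sbar(k, sbar_current=2.0) == pytest.approx(1.0, rel=1e-12)

    def test_fixed_point_matches_grid_mle(self, em_kernel):
        """Iterated EM lands on the direct 1-D maximizer of the same
        (unconditioned, alpha = 1) likelihood."""
        sbar_em, _ = em_fit_sbar(em_kernel, sbar_init=2.0, tol=1e-9)
        w0 = em_kernel.sgrid.trap_weights

        def negll(sbar):
            w = w0 * np.exp(-np.abs(em_kernel.sgrid.nodes) / sbar) / (2 * sbar)
            return -float(em_kernel.counts @ np.log(em_kernel.L[:-1] @ w))

        res = optimize.minimize_scalar(
            negll, bounds=(0.05, 5.0), method="bounded", options={"xatol": 1e-8}
        )
        assert abs(sbar_em - res.x) < 1e-3

    def test_monotone_likelihood_ascent(self, em_kernel):
        _, traj = em_fit_sbar(em_kernel, sbar_init=3.0, tol=1e-9)
        assert np.all(np.diff(traj) >= -1e-10)


class TestFamilyComparison:
    def test_generating_family_wins_or_ties(self, expansion_dataset):
        """On symmetric-exponential data the sym_exp family attains the best
        per-clone average likelihood among the four, or ties within 1e-3."""
        cfg, table, truth, null, kernel = expansion_dataset
        ranked = compare_prior_families(table, null, kernel=kernel)
        assert set(ranked["family"]) == set(EXPANSION_FAMILIES)
        best = ranked["avg_log_likelihood"].iloc[0]
        sym = ranked.loc[ranked.family == "sym_exp", "avg_log_likelihood"].iloc[0]
        assert sym >= best - 1e-3

    def test_offcentered_gaussian_is_strictly_offcentered(self, expansion_dataset):
        cfg, table, truth, null, kernel = expansion_dataset
        fit = fit_expansion(
            table, null, family="gauss_offcentered", kernel=kernel, compute_errors=False
        )
        assert fit.prior.s1 >= 0.1
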