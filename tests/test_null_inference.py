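"""Replicate-pair likelihoods, the constrained ML fit, and error propagation."""

import numpy as np
import pytest
from scipy import stats

from clonexp.clone_size import CloneSizePrior, FrequencyGrid, solve_fmin
from clonexp.noise import NoiseModel, SampleContext, count_pmf_matrix
from clonexp.null_inference import (
    FitError,
    conditioned_log_likelihood,
    diversity_with_errors,
    estimate_total_clones,
    fisher_errors,
    fit_null,
    normalization_Z,
    pair_likelihood,
    zero_count_probability,
)
from clonexp.simulate import SimulationConfig, sample_null_pair
from clonexp.tables import PairTable


@pytest.fixture(scope="module")
def small_setup():
    prior = CloneSizePrior(2.0, solve_fmin(2.0, 2e4))
    model = NoiseModel("poisson")
    ctx = SampleContext(2e3)
    return prior, model, ctx


class TestPairLikelihood:
    def test_joint_normalizes_over_all_pairs(self, small_setup):
        """Sum of P(n, n') over the full count plane, (0,0) included, is 1."""
        prior, model, ctx = small_setup
        grid = FrequencyGrid(prior, 600)
        n = np.arange(0, 800)
        A = count_pmf_matrix(model, ctx, grid.f, n)
        total = float(grid.rho_w @ (A.sum(axis=1) ** 2))
        assert np.isclose(total, 1.0, atol=1e-5)

    def test_replicate_exchangeability(self, small_setup):
        prior, model, ctx = small_setup
        assert np.isclose(
            pair_likelihood(3, 17, prior, model, ctx, ctx),
            pair_likelihood(17, 3, prior, model, ctx, ctx),
            rtol=1e-12,
        )

    def test_point_mass_prior_factorizes_to_poisson_product(self):
        """With all frequency mass at f0, the pair likelihood is the product
        of two independent Poisson pmfs (closed form)."""
        model = NoiseModel("poisson")
        ctx = SampleContext(1e6)
        f0 = 1e-4
        got = pair_likelihood(
            100, 100, None, model, ctx, ctx, f_measure=([f0], [1.0])
        )
        want = stats.poisson.pmf(100, 100.0) ** 2
        assert np.isclose(got, want, rtol=1e-12)

    def test_zero_probability_closed_forms(self):
        """The PGF shortcut for P(0|f) matches explicit pmf evaluation."""
        ctx = SampleContext(5e4)
        f = np.array([1e-6, 1e-5, 1e-4, 1e-3])
        for model in (
            NoiseModel("poisson"),
            NoiseModel("negbin", a=0.8, gamma=1.2),
            NoiseModel("negbin_poisson", a=0.7, gamma=1.1, M=1e5),
        ):
            direct = count_pmf_matrix(model, ctx, f, np.array([0]))[:, 0]
            closed = zero_count_probability(model, ctx, f)
            assert np.allclose(direct, closed, rtol=1e-7)


@pytest.fixture(scope="module")
def table():
    rng = np.random.default_rng(1)
    n = rng.poisson(2.0, 300)
    npr = rng.poisson(2.0, 300)
    keep = n + npr > 0
    return PairTable.from_counts(n[keep], npr[keep])


class TestConditionedLogLikelihood:
    def test_is_nonpositive(self, small_setup, table):
        prior, model, ctx = small_setup
        assert conditioned_log_likelihood(table, prior, model, ctx, ctx) <= 0.0

    def test_matches_naive_per_row_loop(self, small_setup, table):
        """Unique-pair vectorization equals a brute-force per-row loop."""
        prior, model, ctx = small_setup
        grid = FrequencyGrid(prior, 400)
        fast = conditioned_log_likelihood(table, prior, model, ctx, ctx, grid)
        p00 = pair_likelihood(0, 0, prior, model, ctx, ctx, grid)
        slow = sum(
            np.log(pair_likelihood(int(r.n), int(r.n_prime), prior, model, ctx, ctx, grid))
            - np.log1p(-p00)
            for r in table.df.itertuples()
        ) / table.n_obs
        assert np.isclose(fast, slow, rtol=1e-12)

    def test_duplicated_row_adds_exactly_one_contribution(self, small_setup, table):
        prior, model, ctx = small_setup
        grid = FrequencyGrid(prior, 400)
        base = conditioned_log_likelihood(table, prior, model, ctx, ctx, grid)
        df = table.df
        bigger = PairTable(
            list(df.clone_id) + ["dup"],
            np.append(df.n.to_numpy(), 3),
            np.append(df.n_prime.to_numpy(), 1),
        )
        p00 = pair_likelihood(0, 0, prior, model, ctx, ctx, grid)
        extra = np.log(pair_likelihood(3, 1, prior, model, ctx, ctx, grid)) - np.log1p(-p00)
        withdup = conditioned_log_likelihood(bigger, prior, model, ctx, ctx, grid)
        assert np.isclose(withdup * bigger.n_obs, base * table.n_obs + extra, rtol=1e-12)

    def test_invariant_to_row_order(self, small_setup, table):
        prior, model, ctx = small_setup
        perm = np.random.default_rng(3).permutation(table.n_obs)
        shuffled = PairTable(
            [f"s{i}" for i in range(table.n_obs)],
            table.df.n.to_numpy()[perm],
            table.df.n_prime.to_numpy()[perm],
        )
        assert np.isclose(
            conditioned_log_likelihood(table, prior, model, ctx, ctx),
            conditioned_log_likelihood(shuffled, prior, model, ctx, ctx),
            rtol=1e-13,
        )


class TestFitNull:
    def test_poisson_recovery(self):
        """Poisson-kind fit on Poisson-simulated data recovers nu within 0.05."""
        cfg = SimulationConfig(
            N=10**5, nu=2.0, noise="poisson", n_reads_1=5e4, n_reads_2=5e4, seed=5
        )
        table = sample_null_pair(cfg)
        ctx1, ctx2 = cfg.contexts()
        fit = fit_null(
            table, kind="poisson", grid_points=300, ctx=ctx1, ctx_prime=ctx2,
            compute_errors=False,
        )
        assert abs(fit.params["nu"] - 2.0) < 0.05
        assert np.isclose(10 ** fit.params["log10_f_min"], cfg.f_min, rtol=0.3)

    def test_degenerate_table_fails_gracefully(self):
        """All-equal large counts cannot come from a power-law repertoire; the
        fit must report the flat/degenerate likelihood instead of a result."""
        table = PairTable.from_counts(np.full(200, 1000), np.full(200, 1000))
        with pytest.raises((FitError, FloatingPointError)):
            fit_null(table, kind="poisson", grid_points=250, compute_errors=False)

    def test_total_clone_estimate(self, poisson_null_fit):
        """N = N_obs / (1 - P(0,0)) recovers the generating repertoire size
        within a factor 1.5; the single-sample variant is the same order."""
        cfg, table, fit = poisson_null_fit
        assert fit.N_total >= table.n_obs
        assert cfg.N / 1.5 < fit.N_total < cfg.N * 1.5
        single = estimate_total_clones(
            table, fit.prior, fit.model, fit.ctx, mode="single", grid_points=300
        )
        assert cfg.N / 2 < single < cfg.N * 2


class TestNormalizationZ:
    def test_posterior_mean_frequencies_in_unit_interval(self, poisson_null_fit):
        cfg, table, fit = poisson_null_fit
        Z = normalization_Z(table, fit.prior, fit.model, fit.ctx, fit.ctx_prime)
        assert 0.0 < Z < 10.0

    def test_self_consistency_near_one(self):
        """Under the generating model the realized frequency budget Z is close
        to 1.  This needs a light-tailed exponent (nu=2.5, finite variance of
        the total frequency); at nu~2 single giant clones make Z swing by
        tens of percent from realization to realization."""
        cfg = SimulationConfig(
            N=10**5, nu=2.5, noise="poisson", n_reads_1=5e4, n_reads_2=5e4, seed=2
        )
        table = sample_null_pair(cfg)
        ctx = SampleContext(5e4)
        Z = normalization_Z(table, cfg.prior(), cfg.model(), ctx, ctx, grid_points=500)
        assert abs(Z - 1.0) < 0.05

    def test_monotone_in_fmin_across_decades(self, poisson_null_fit):
        """Z grows with f_min over the decades the constrained solver scans
        (a larger cutoff gives every unseen clone a larger frequency budget);
        near the optimum the dependence is smooth and continuous."""
        cfg, table, fit = poisson_null_fit
        fmins = 10.0 ** np.arange(-7.0, -2.5, 0.5)
        zs = [
            normalization_Z(
                table, CloneSizePrior(fit.prior.nu, fm), fit.model, fit.ctx,
                fit.ctx_prime, grid_points=300,
            )
            for fm in fmins
        ]
        assert all(a < b for a, b in zip(zs[:-1], zs[1:]))
        # continuity near the optimum: a 10% nudge moves Z by < 1%
        z0 = normalization_Z(
            table, fit.prior, fit.model, fit.ctx, fit.ctx_prime, grid_points=300
        )
        z1 = normalization_Z(
            table, CloneSizePrior(fit.prior.nu, fit.prior.f_min * 1.1), fit.model,
            fit.ctx, fit.ctx_prime, grid_points=300,
        )
        assert abs(z1 - z0) < 0.01


class TestFisherErrors:
    def test_projection_is_idempotent(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((4, 4))
        H = -(A @ A.T)  # negative definite
        nvec = rng.standard_normal(4)
        once = fisher_errors(H, nvec)
        # projecting an already-projected Hessian changes nothing
        n_unit = nvec / np.linalg.norm(nvec)
        P = np.outer(n_unit, n_unit)
        H1 = H - P @ H - H @ P + P @ H @ P
        twice = fisher_errors(H1, nvec)
        assert np.allclose(once, twice, atol=1e-10)

    def test_diagonal_case_leaves_other_axes_untouched(self):
        H = np.diag([-2.0, -4.0, -8.0])
        cov = fisher_errors(H, np.array([1.0, 0.0, 0.0]))
        assert np.allclose(np.diag(cov), [0.0, 0.25, 0.125], atol=1e-12)

    def test_matches_bordered_hessian_on_quadratic(self):
        """For a Gaussian log-likelihood with a linear constraint, the
        projected-Hessian pseudo-inverse equals the conditional covariance
        from the Lagrange / bordered-Hessian construction."""
        rng = np.random.default_rng(7)
        B = rng.standard_normal((5, 5))
        A = B @ B.T + 5 * np.eye(5)  # precision of the quadratic
        c = rng.standard_normal(5)
        c /= np.linalg.norm(c)
        Sigma = np.linalg.inv(A)
        conditional = Sigma - Sigma @ np.outer(c, c) @ Sigma / (c @ Sigma @ c)
        ours = fisher_errors(-A, c)
        assert np.allclose(ours, conditional, atol=1e-10)

    def test_null_direction_along_constraint(self):
        rng = np.random.default_rng(1)
        B = rng.standard_normal((3, 3))
        H = -(B @ B.T + np.eye(3))
        c = np.array([0.3, -1.2, 0.5])
        cov = fisher_errors(H, c)
        assert np.allclose(cov @ c, 0.0, atol=1e-10)


class TestDiversityWithErrors:
    def test_zero_covariance_gives_zero_error_bars(self, poisson_null_fit):
        cfg, table, fit = poisson_null_fit
        saved = fit.covariance
        try:
            fit.covariance = np.zeros_like(saved)
            est = diversity_with_errors(fit, n_draws=50, rng=np.random.default_rng(0))
            assert all(e.sd_log < 1e-12 for e in est.values())
        finally:
            fit.covariance = saved

    def test_richness_equals_total_clone_estimate(self, poisson_null_fit):
        cfg, table, fit = poisson_null_fit
        est = diversity_with_errors(fit, n_draws=50, rng=np.random.default_rng(0))
        assert est[0.0].value == pytest.approx(fit.N_total, rel=1e-12)

    def test_error_estimate_is_stable_across_runs(self, poisson_null_fit):
        """Monte-Carlo noise of the error bars stays below 10% at 1000 draws."""
        cfg, table, fit = poisson_null_fit
        a = diversity_with_errors(fit, n_draws=1000, rng=np.random.default_rng(1))
        b = diversity_with_errors(fit, n_draws=1000, rng=np.random.default_rng(2))
        for beta in (0.0, 1.0, 2.0):
            assert a[beta].sd_log == pytest.approx(b[beta].sd_log, rel=0.10)
        # diversities order as D0 >= D1 >= D2
        assert a[0.0].value >= a[1.0].value >= a[2.0].value
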