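"""Maximum-likelihood null model from same-day replicate pairs.

Two sequencing replicates of the same blood draw share the latent clone
frequencies ``f`` but have independent measurement noise.  The probability of
observing the count pair ``(n, n')`` is therefore

    P(n, n') = integral_{f_min}^{1} rho(f) P(n | f) P(n' | f) df,

and, because clones unseen in both replicates never enter the table, the fit
maximizes the likelihood conditioned on ``n + n' > 0``:

    L(theta) = prod_i P(n_i, n_i' | theta) / (1 - P(0, 0 | theta)).

The parameter vector couples the clone-size prior (nu, f_min) with the noise
model (a, gamma, M depending on kind).  Frequencies must sum to one across
the repertoire; by default this is enforced through the mean constraint
``N <f> = 1`` (with ``N = N_obs / (1 - P(0,0))``), which pins ``f_min`` given
the remaining parameters.  A realization-specific alternative imposes
``Z = 1`` on the posterior frequency budget of the observed sample instead
of the ensemble-mean condition.

Error bars come from the Hessian of the log-likelihood projected onto the
hyperplane that locally preserves the normalization constraint; diversity
uncertainties are propagated by Monte-Carlo draws from the resulting
Gaussian approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .clone_size import CloneSizePrior, FrequencyGrid, hill_diversity, solve_fmin
from .noise import NoiseModel, SampleContext, count_pmf_matrix
from .tables import PairTable

__all__ = [
    "NullFit",
    "FitError",
    "pair_likelihood",
    "joint_pair_probabilities",
    "conditioned_log_likelihood",
    "fit_null",
    "normalization_Z",
    "estimate_total_clones",
    "zero_count_probability",
    "fisher_errors",
    "numeric_hessian",
    "diversity_with_errors",
]

logger = logging.getLogger(__name__)

PARAM_NAMES = {
    "poisson": ("nu",),
    "negbin": ("nu", "a", "gamma"),
    "negbin_poisson": ("nu", "a", "gamma", "log10_M"),
}

# sanity box for the optimizer; hitting an edge signals a degenerate fit
_BOUNDS = {
    "nu": (1.05, 4.5),
    "a": (0.0, 60.0),
    "gamma": (0.55, 3.0),
    "log10_M": (1.0, 13.0),
}


class FitError(RuntimeError):
    """Raised when a likelihood fit fails to converge or is degenerate."""


def zero_count_probability(model: NoiseModel, ctx: SampleContext, f: np.ndarray) -> np.ndarray:
    """Closed-form ``P(n = 0 | f)`` for each noise kind.

    For the two-step model this is the negative-binomial probability
    generating function evaluated at ``exp(-eps)``, which avoids the
    marginalization over cell counts entirely:
    ``P(0|f) = exp(-(mbar / t) * log1p(t * (1 - exp(-eps))))`` with
    ``t = a * mbar**(gamma - 1)``.
    """
    f = np.asarray(f, dtype=float)
    if model.kind == "poisson":
        return np.exp(-f * ctx.n_reads)
    if model.kind == "negbin":
        mean = f * ctx.n_reads
        if model.a == 0.0:
            return np.exp(-mean)
        t = model.a * mean ** (model.gamma - 1.0)
        return np.exp(-mean / t * np.log1p(t))
    eps = ctx.efficiency(model)
    mbar = f * model.M
    one_minus_z = -np.expm1(-eps)
    if model.a == 0.0:
        return np.exp(-mbar * one_minus_z)
    t = model.a * mbar ** (model.gamma - 1.0)
    return np.exp(-mbar / t * np.log1p(t * one_minus_z))


def _measure(prior, grid, f_measure, grid_points):
    if f_measure is not None:
        f, w = f_measure
        return np.atleast_1d(np.asarray(f, float)), np.atleast_1d(np.asarray(w, float))
    if grid is None:
        grid = FrequencyGrid(prior, grid_points)
    return grid.f, grid.rho_w


def joint_pair_probabilities(
    pairs: np.ndarray,
    prior: CloneSizePrior,
    model: NoiseModel,
    ctx: SampleContext,
    ctx_prime: SampleContext,
    grid: FrequencyGrid | None = None,
    f_measure=None,
    grid_points: int = 800,
    f_weight: np.ndarray | None = None,
) -> np.ndarray:
    """Joint probabilities ``P(n_i, n_i')`` for an array of count pairs.

    ``f_weight`` optionally reweights the integrand by a per-node factor
    (used for posterior-mean frequencies in the normalization budget).
    """
    pairs = np.atleast_2d(np.asarray(pairs))
    f, w = _measure(prior, grid, f_measure, grid_points)
    if f_weight is not None:
        w = w * f_weight
    n_vals, ia = np.unique(pairs[:, 0], return_inverse=True)
    np_vals, ib = np.unique(pairs[:, 1], return_inverse=True)
    A = count_pmf_matrix(model, ctx, f, n_vals)
    B = count_pmf_matrix(model, ctx_prime, f, np_vals)
    probs = np.empty(len(pairs))
    chunk = max(1, int(2_000_000 // max(len(f), 1)))
    for lo in range(0, len(pairs), chunk):
        hi = min(lo + chunk, len(pairs))
        probs[lo:hi] = w @ (A[:, ia[lo:hi]] * B[:, ib[lo:hi]])
    if not np.all(np.isfinite(probs)):
        raise FloatingPointError(
            "non-finite pair likelihood; parameters "
            f"nu={prior.nu}, f_min={prior.f_min}, model={model}"
        )
    return probs


def pair_likelihood(
    n,
    n_prime,
    prior: CloneSizePrior,
    model: NoiseModel,
    ctx: SampleContext,
    ctx_prime: SampleContext | None = None,
    grid: FrequencyGrid | None = None,
    f_measure=None,
    grid_points: int = 800,
):
    """``P(n, n')`` under the replicate null model (shared latent frequency)."""
    if ctx_prime is None:
        ctx_prime = ctx
    scalar = np.isscalar(n) and np.isscalar(n_prime)
    pairs = np.column_stack([np.atleast_1d(n), np.atleast_1d(n_prime)])
    out = joint_pair_probabilities(
        pairs, prior, model, ctx, ctx_prime, grid, f_measure, grid_points
    )
    return float(out[0]) if scalar else out


def conditioned_log_likelihood(
    table: PairTable,
    prior: CloneSizePrior,
    model: NoiseModel,
    ctx: SampleContext,
    ctx_prime: SampleContext,
    grid: FrequencyGrid | None = None,
    grid_points: int = 800,
) -> float:
    """Per-clone average of ``ln P(n, n') - ln(1 - P(0, 0))``."""
    if table.n_obs == 0:
        raise ValueError("empty pair table")
    pairs = np.vstack([table.unique_pairs, [[0, 0]]])
    probs = joint_pair_probabilities(
        pairs, prior, model, ctx, ctx_prime, grid, grid_points=grid_points
    )
    p00 = probs[-1]
    if p00 >= 1.0 - 1e-12:
        raise FloatingPointError("P(0,0) ~ 1: model predicts an empty sample")
    with np.errstate(divide="ignore"):
        logs = np.log(probs[:-1])
    if np.any(~np.isfinite(logs)):
        return -np.inf
    total = float(table.pair_counts @ logs) - table.n_obs * np.log1p(-p00)
    return total / table.n_obs


def estimate_total_clones(
    table: PairTable,
    prior: CloneSizePrior,
    model: NoiseModel,
    ctx: SampleContext,
    ctx_prime: SampleContext | None = None,
    grid: FrequencyGrid | None = None,
    mode: str = "pair",
    grid_points: int = 800,
) -> float:
    """Unseen-clone extrapolation of the total clone count ``N``.

    ``mode='pair'`` uses both replicates, ``N = N_obs / (1 - P(0, 0))``;
    ``mode='single'`` uses one sample, ``N = N_obs,1 / (1 - P(0))`` with
    ``N_obs,1`` the number of clones seen in that sample.
    """
    if grid is None:
        grid = FrequencyGrid(prior, grid_points)
    if mode == "pair":
        if ctx_prime is None:
            ctx_prime = ctx
        p00 = float(
            grid.rho_w
            @ (
                zero_count_probability(model, ctx, grid.f)
                * zero_count_probability(model, ctx_prime, grid.f)
            )
        )
        return table.n_obs / (1.0 - p00)
    if mode == "single":
        n_obs_1 = int((table.df["n"] > 0).sum())
        p0 = float(grid.rho_w @ zero_count_probability(model, ctx, grid.f))
        return n_obs_1 / (1.0 - p0)
    raise ValueError(f"unknown mode {mode!r}; expected 'pair' or 'single'")


def normalization_Z(
    table: PairTable,
    prior: CloneSizePrior,
    model: NoiseModel,
    ctx: SampleContext,
    ctx_prime: SampleContext,
    grid: FrequencyGrid | None = None,
    grid_points: int = 800,
) -> float:
    """Realized normalization ``Z`` of the observed sample.

    ``Z = N P(0,0) <f | (0,0)> + sum_i <f | (n_i, n_i')>`` adds the posterior
    frequency budget of the unseen clones to that of every observed clone; at
    a well-normalized fit it is close to 1.
    """
    if grid is None:
        grid = FrequencyGrid(prior, grid_points)
    pairs = np.vstack([table.unique_pairs, [[0, 0]]])
    probs = joint_pair_probabilities(pairs, prior, model, ctx, ctx_prime, grid)
    nums = joint_pair_probabilities(
        pairs, prior, model, ctx, ctx_prime, grid, f_weight=grid.f
    )
    # pairs whose likelihood underflows at these parameters fall back to the
    # count-ratio frequency estimate so Z stays finite and informative
    naive_f = np.clip(
        pairs.sum(axis=1) / (ctx.n_reads + ctx_prime.n_reads), prior.f_min, 1.0
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        post_mean_f = np.where(probs > 0.0, nums / np.where(probs > 0, probs, 1.0), naive_f)
    p00 = probs[-1]
    N = table.n_obs / (1.0 - p00)
    return float(N * p00 * post_mean_f[-1] + table.pair_counts @ post_mean_f[:-1])


# ---------------------------------------------------------------------------
# fitting


def _unpack(kind: str, theta: np.ndarray) -> tuple[float, float, float, float | None]:
    nu = float(theta[0])
    a = gamma = 0.0
    M = None
    if kind in ("negbin", "negbin_poisson"):
        a = float(theta[1])
        gamma = float(theta[2])
    if kind == "negbin_poisson":
        M = 10.0 ** float(theta[3])
    return nu, a, gamma, M


def _in_bounds(kind: str, theta: np.ndarray, margin: float = 0.0) -> bool:
    for name, val in zip(PARAM_NAMES[kind], theta):
        lo, hi = _BOUNDS[name]
        if not lo + margin <= val <= hi - margin:
            return False
    return True


def _solve_fmin_constrained(
    kind: str,
    theta: np.ndarray,
    table: PairTable,
    ctx: SampleContext,
    ctx_prime: SampleContext,
    normalization: str,
    grid_points: int,
    hint: float | None = None,
) -> float:
    """Root-find ``f_min`` so the selected normalization constraint holds.

    ``hint`` (a log10 f_min from a previous objective evaluation) narrows the
    initial bracket; the full scan is the fallback.
    """
    nu, a, gamma, M = _unpack(kind, theta)
    model = NoiseModel(kind, a, gamma, M)

    def constraint(log10_fmin: float) -> float:
        prior = CloneSizePrior(nu, 10.0**log10_fmin)
        grid = FrequencyGrid(prior, grid_points)
        if normalization == "mean":
            p00 = float(
                grid.rho_w
                @ (
                    zero_count_probability(model, ctx, grid.f)
                    * zero_count_probability(model, ctx_prime, grid.f)
                )
            )
            N = table.n_obs / (1.0 - p00)
            return np.log(N * prior.moment(1.0))
        return normalization_Z(table, prior, model, ctx, ctx_prime, grid) - 1.0

    if hint is not None:
        a_h, b_h = hint - 0.5, hint + 0.5
        fa, fb = constraint(a_h), constraint(b_h)
        if fa * fb < 0:
            return 10.0 ** optimize.brentq(constraint, a_h, b_h, xtol=1e-10)
    lo, hi = -16.0, -1.5
    xs = np.linspace(lo, hi, 9)
    vals = [constraint(x) for x in xs]
    for i in range(len(xs) - 1):
        if vals[i] == 0.0:
            return 10.0 ** xs[i]
        if vals[i] * vals[i + 1] < 0:
            root = optimize.brentq(constraint, xs[i], xs[i + 1], xtol=1e-10)
            return 10.0**root
    raise FitError(
        f"normalization constraint has no root in f_min for theta={theta} "
        f"(values {vals[0]:.3g} .. {vals[-1]:.3g})"
    )


def _coarse_grid(kind: str, ctx: SampleContext) -> list[np.ndarray]:
    log_nr = np.log10(ctx.n_reads)
    grids = {
        "nu": np.array([1.8, 2.2]),
        "a": np.array([0.3, 0.9]),
        "gamma": np.array([1.0, 1.2]),
        "log10_M": log_nr + np.array([0.0, 0.6]),
    }
    axes = [grids[name] for name in PARAM_NAMES[kind]]
    mesh = np.meshgrid(*axes, indexing="ij")
    return [np.array(p) for p in zip(*(m.ravel() for m in mesh))]


@dataclass
class NullFit:
    """Result of a replicate-pair null-model fit."""

    kind: str
    params: dict
    prior: CloneSizePrior
    model: NoiseModel
    ctx: SampleContext
    ctx_prime: SampleContext
    avg_log_likelihood: float
    n_obs: int
    N_total: float
    Z: float
    normalization: str
    grid_points: int
    param_names: tuple = ()
    covariance: np.ndarray | None = None

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.params[name] for name in self.param_names])

    def std_errors(self) -> dict:
        if self.covariance is None:
            return {}
        se = np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))
        return dict(zip(self.param_names, se))

    def grid(self) -> FrequencyGrid:
        return FrequencyGrid(self.prior, self.grid_points)


def fit_null(
    table: PairTable,
    kind: str = "negbin_poisson",
    normalization: str = "mean",
    grid_points: int = 400,
    ctx: SampleContext | None = None,
    ctx_prime: SampleContext | None = None,
    starts: list | None = None,
    refine: bool = True,
    compute_errors: bool = True,
    maxiter: int = 400,
) -> NullFit:
    """Fit the null model (clone-size prior + noise) to a replicate pair.

    The search runs over ``(nu[, a, gamma, log10 M])`` with ``f_min``
    eliminated at every objective evaluation by the normalization constraint
    (``normalization='mean'`` for ``N<f> = 1``, ``'realized'`` for ``Z = 1``).
    A coarse grid scan chooses the start of a Nelder-Mead refinement; M and
    f_min are searched on log10 scales, the rest on linear scales.
    """
    if normalization not in ("mean", "realized"):
        raise ValueError("normalization must be 'mean' or 'realized'")
    if kind not in PARAM_NAMES:
        raise ValueError(f"unknown model kind {kind!r}")
    if ctx is None:
        ctx = SampleContext(table.n_reads[0])
    if ctx_prime is None:
        ctx_prime = SampleContext(table.n_reads[1])

    names = PARAM_NAMES[kind]
    n_eval = [0]
    last_root = [None]

    def objective(theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        if not _in_bounds(kind, theta):
            return 1e8
        try:
            f_min = _solve_fmin_constrained(
                kind, theta, table, ctx, ctx_prime, normalization, grid_points,
                hint=last_root[0],
            )
            last_root[0] = float(np.log10(f_min))
            nu, a, gamma, M = _unpack(kind, theta)
            prior = CloneSizePrior(nu, f_min)
            model = NoiseModel(kind, a, gamma, M)
            ll = conditioned_log_likelihood(
                table, prior, model, ctx, ctx_prime, grid_points=grid_points
            )
        except (FitError, FloatingPointError, ValueError):
            return 1e8
        n_eval[0] += 1
        return -ll

    if starts is None:
        starts = _coarse_grid(kind, ctx)
    scores = [objective(np.asarray(s, float)) for s in starts]
    best_idx = int(np.argmin(scores))
    best_theta = np.asarray(starts[best_idx], dtype=float)
    best_val = scores[best_idx]
    if not np.isfinite(best_val) or best_val >= 1e8:
        raise FitError("likelihood not finite anywhere on the start grid")

    if refine:
        res = optimize.minimize(
            objective,
            best_theta,
            method="Nelder-Mead",
            options={
                "maxiter": maxiter,
                "xatol": 1e-3,
                "fatol": 1e-7,
                "initial_simplex": _simplex(best_theta),
            },
        )
        if np.isfinite(res.fun) and res.fun < best_val:
            best_theta, best_val = np.asarray(res.x, float), float(res.fun)
        if not res.success and res.fun >= best_val + 1e-3:
            raise FitError(
                f"optimizer failed to converge: {res.message}; "
                f"last iterate {res.x}, objective {res.fun:.6f}"
            )
    if not _in_bounds(kind, best_theta, margin=1e-6):
        raise FitError(
            f"optimum pinned to the parameter sanity box at {dict(zip(names, best_theta))}; "
            "the likelihood is flat or the data are degenerate"
        )

    f_min = _solve_fmin_constrained(
        kind, best_theta, table, ctx, ctx_prime, normalization, grid_points
    )
    nu, a, gamma, M = _unpack(kind, best_theta)
    prior = CloneSizePrior(nu, f_min)
    model = NoiseModel(kind, a, gamma, M)
    grid = FrequencyGrid(prior, grid_points)
    avg_ll = conditioned_log_likelihood(table, prior, model, ctx, ctx_prime, grid)
    N_total = estimate_total_clones(table, prior, model, ctx, ctx_prime, grid)
    Z = normalization_Z(table, prior, model, ctx, ctx_prime, grid)
    params = dict(zip(names, (float(v) for v in best_theta)))
    params["log10_f_min"] = float(np.log10(f_min))
    full_names = names + ("log10_f_min",)

    fit = NullFit(
        kind=kind,
        params=params,
        prior=prior,
        model=model,
        ctx=ctx,
        ctx_prime=ctx_prime,
        avg_log_likelihood=avg_ll,
        n_obs=table.n_obs,
        N_total=N_total,
        Z=Z,
        normalization=normalization,
        grid_points=grid_points,
        param_names=full_names,
    )
    logger.info(
        "fit_null kind=%s ll=%.6f params=%s N=%.3g (evals=%d)",
        kind,
        avg_ll,
        params,
        N_total,
        n_eval[0],
    )
    if compute_errors:
        fit.covariance = _null_covariance(fit, table)
    return fit


def _simplex(x0: np.ndarray, scale: float = 0.15) -> np.ndarray:
    n = len(x0)
    simplex = np.tile(x0, (n + 1, 1))
    for i in range(n):
        simplex[i + 1, i] += scale if x0[i] == 0 else scale * max(abs(x0[i]), 0.5)
    return simplex


def _full_objective(fit: NullFit, table: PairTable, grid_points: int | None = None):
    """Total conditioned log-likelihood as a function of the full theta vector
    (including log10 f_min), used for Hessian-based error bars."""

    kind = fit.kind
    if grid_points is None:
        grid_points = fit.grid_points

    def total_ll(theta_full: np.ndarray) -> float:
        nu, a, gamma, M = _unpack(kind, theta_full)
        f_min = 10.0 ** float(theta_full[-1])
        prior = CloneSizePrior(nu, f_min)
        model = NoiseModel(kind, a, gamma, M)
        return fit.n_obs * conditioned_log_likelihood(
            table, prior, model, fit.ctx, fit.ctx_prime, grid_points=grid_points
        )

    def constraint(theta_full: np.ndarray) -> float:
        nu, a, gamma, M = _unpack(kind, theta_full)
        f_min = 10.0 ** float(theta_full[-1])
        prior = CloneSizePrior(nu, f_min)
        model = NoiseModel(kind, a, gamma, M)
        grid = FrequencyGrid(prior, grid_points)
        if fit.normalization == "mean":
            p00 = float(
                grid.rho_w
                @ (
                    zero_count_probability(model, fit.ctx, grid.f)
                    * zero_count_probability(model, fit.ctx_prime, grid.f)
                )
            )
            N = table.n_obs / (1.0 - p00)
            return N * prior.moment(1.0) - 1.0
        return normalization_Z(table, prior, model, fit.ctx, fit.ctx_prime, grid) - 1.0

    return total_ll, constraint


def numeric_hessian(func, x0: np.ndarray, step: float = 1e-3) -> np.ndarray:
    """Central finite-difference Hessian with per-coordinate absolute step."""
    x0 = np.asarray(x0, dtype=float)
    p = len(x0)
    H = np.empty((p, p))
    f0 = func(x0)
    steps = np.full(p, step)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = steps[i]
        H[i, i] = (func(x0 + ei) - 2.0 * f0 + func(x0 - ei)) / steps[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = steps[i]
            ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                func(x0 + ei + ej) - func(x0 + ei - ej) - func(x0 - ei + ej) + func(x0 - ei - ej)
            ) / (4.0 * steps[i] * steps[j])
    return H


def _numeric_gradient(func, x0: np.ndarray, step: float = 1e-4) -> np.ndarray:
    x0 = np.asarray(x0, dtype=float)
    g = np.empty(len(x0))
    for i in range(len(x0)):
        ei = np.zeros(len(x0))
        ei[i] = step
        g[i] = (func(x0 + ei) - func(x0 - ei)) / (2.0 * step)
    return g


def fisher_errors(hessian: np.ndarray, constraint_grad: np.ndarray | None = None):
    """Covariance at a constrained maximum from the projected Hessian.

    Projects out the direction normal to the constraint surface,
    ``H_hat = H - P H - H P + P H P`` with ``P`` the rank-one projector onto
    the unit constraint normal, and pseudo-inverts ``-H_hat``.  The returned
    covariance has exactly one zero eigenvalue (along the normal); other
    directions carry the usual inverse-Fisher uncertainty.
    """
    H = np.asarray(hessian, dtype=float)
    if constraint_grad is not None:
        nvec = np.asarray(constraint_grad, dtype=float)
        norm = np.linalg.norm(nvec)
        if norm == 0:
            raise ValueError("constraint gradient is zero")
        nvec = nvec / norm
        P = np.outer(nvec, nvec)
        H = H - P @ H - H @ P + P @ H @ P
    H = 0.5 * (H + H.T)
    eigvals, eigvecs = np.linalg.eigh(-H)
    lam_max = float(np.abs(eigvals).max())
    tol = 1e-10 * max(lam_max, 1.0)
    indefinite = eigvals < -tol
    if indefinite.any():
        logger.warning(
            "projected Hessian is not negative semi-definite on the constraint "
            "subspace (eigenvalues of -H: %s); the indefinite directions are "
            "reported with |curvature|-based (large) variances",
            eigvals,
        )
    # 1/lambda on well-curved directions; zero on the constraint null
    # direction; 1/|lambda| on indefinite directions (flat-ridge FD noise),
    # which yields large, not zero, uncertainty there
    inv = np.where(np.abs(eigvals) > tol, 1.0 / np.abs(eigvals), 0.0)
    cov = (eigvecs * inv) @ eigvecs.T
    return 0.5 * (cov + cov.T)


def _null_covariance(fit: NullFit, table: PairTable) -> np.ndarray:
    # the Hessian must be differenced on the same grid the optimum was found
    # on, or the FD curvature picks up the inter-grid offset
    total_ll, constraint = _full_objective(fit, table)
    theta_full = fit.theta
    H = numeric_hessian(total_ll, theta_full, step=1e-3)
    grad_c = _numeric_gradient(constraint, theta_full, step=1e-4)
    return fisher_errors(H, grad_c)


@dataclass
class DiversityEstimate:
    beta: float
    value: float
    sd_log: float  # standard deviation of ln D_beta

    @property
    def sd_log10(self) -> float:
        return self.sd_log / np.log(10.0)


def diversity_with_errors(
    fit: NullFit,
    betas=(0.0, 1.0, 2.0),
    n_draws: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Hill diversities with Monte-Carlo error bars.

    Parameter vectors are drawn from the Gaussian approximation
    ``N(theta*, cov)`` (cov from the projected Hessian); draws violating
    ``nu > 1`` or ``f_min`` in (0, 1) are rejected and redrawn.  The spread of
    ``ln D_beta`` over draws is reported as the uncertainty.
    """
    if fit.covariance is None:
        raise ValueError("fit carries no covariance; rerun with compute_errors=True")
    if rng is None:
        rng = np.random.default_rng(0)
    cov = np.asarray(fit.covariance, dtype=float)
    eigvals, eigvecs = np.linalg.eigh(0.5 * (cov + cov.T))
    if np.any(eigvals < -1e-8 * max(1.0, np.abs(eigvals).max())):
        raise ValueError("covariance is not positive semi-definite")
    L = eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))
    theta0 = fit.theta

    def valid(theta):
        nu, a, gamma, M = _unpack(fit.kind, theta)
        f_min = 10.0 ** theta[-1]
        if not (nu > 1.001 and 0.0 < f_min < 1.0 and a >= 0.0):
            return False
        return M is None or M > 0
    draws = []
    guard = 0
    while len(draws) < n_draws and guard < 50 * n_draws:
        guard += 1
        theta = theta0 + L @ rng.standard_normal(len(theta0))
        if valid(theta):
            draws.append(theta)
    if len(draws) < n_draws:
        raise FitError("could not draw enough valid parameter samples")

    out = {}
    log_D = {beta: np.empty(n_draws) for beta in betas}
    for k, theta in enumerate(draws):
        nu, a, gamma, M = _unpack(fit.kind, theta)
        prior = CloneSizePrior(nu, 10.0 ** theta[-1])
        model = NoiseModel(fit.kind, a, gamma, M)
        grid = FrequencyGrid(prior, fit.grid_points)
        p00 = float(
            grid.rho_w
            @ (
                zero_count_probability(model, fit.ctx, grid.f)
                * zero_count_probability(model, fit.ctx_prime, grid.f)
            )
        )
        N = fit.n_obs / (1.0 - p00)
        for beta in betas:
            log_D[beta][k] = np.log(hill_diversity(beta, prior, N))
    for beta in betas:
        point = fit.N_total if beta == 0 else hill_diversity(beta, fit.prior, fit.N_total)
        out[beta] = DiversityEstimate(beta=beta, value=point, sd_log=float(np.std(log_D[beta])))
    return out
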