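"""Empirical-Bayes inference of the clonal-expansion prior.

Between two time points a clone's frequency moves by a latent log
fold-change ``s = ln(f'/f)``.  Only a fraction ``alpha`` of clones respond to
the immune challenge; the rest keep their frequency up to a global shift
``s0`` that compensates the responders so that total frequency stays
normalized.  The prior over ``s`` is the spike-plus-tail mixture

    rho_s(s) = (1 - alpha) delta(s - s0) + alpha rho_exp(s - s0),

with ``rho_exp`` one of four families: a one-sided exponential
(``asym_exp``, scale ``sbar``), a two-sided Laplace (``sym_exp``), a centered
Gaussian, or a strictly off-centered Gaussian (offset ``s1 >= 0.1``).

Given a null model fitted from replicates at the first time point, the
likelihood of a count pair across time points marginalizes both the initial
frequency and the fold-change,

    P_exp(n, n') = int df rho(f) int ds rho_s(s) P(n | f) P(n' | f e^s),

and ``(alpha, sbar)`` are fitted by conditioned maximum likelihood with the
equal-repertoire-size constraint ``Z' = Z`` resolved through the shift
``s0 = -ln(Z'_0 / Z)`` at every objective evaluation.

The expensive double integral factorizes: the per-pair likelihood kernel
``L_i(s) = int df rho(f) P(n_i|f) P(n_i'|f e^s)`` does not depend on the
expansion prior at all, so it is tabulated once per dataset on a fixed
``s`` grid and every candidate prior is evaluated by reweighting it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .clone_size import CloneSizePrior, FrequencyGrid
from .noise import NoiseModel, SampleContext, count_pmf_matrix
from .null_inference import FitError, NullFit, numeric_hessian
from .tables import PairTable

__all__ = [
    "ExpansionPrior",
    "SGrid",
    "ExpansionKernel",
    "ExpansionFit",
    "EXPANSION_FAMILIES",
    "expansion_prior_density",
    "pair_likelihood_expansion",
    "fit_expansion",
    "solve_s0",
    "em_update_sbar",
    "em_fit_sbar",
    "compare_prior_families",
]

logger = logging.getLogger(__name__)

EXPANSION_FAMILIES = ("asym_exp", "sym_exp", "gauss_centered", "gauss_offcentered")


@dataclass(frozen=True)
class ExpansionPrior:
    """Mixture prior over the log fold-change ``s``.

    ``sbar`` is the exponential scale for the exponential families and the
    standard deviation for the Gaussian families; ``s1`` is the offset of the
    off-centered Gaussian (ignored elsewhere).
    """

    family: str
    alpha: float
    sbar: float
    s0: float = 0.0
    s1: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in EXPANSION_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {EXPANSION_FAMILIES}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"responding fraction alpha must lie in [0, 1], got {self.alpha}")
        if not self.sbar > 0.0:
            raise ValueError(f"scale sbar must be > 0, got {self.sbar}")
        if self.family == "gauss_offcentered" and self.s1 < 0.0:
            raise ValueError("offset s1 must be >= 0")


@dataclass(frozen=True)
class SGrid:
    """Uniform grid over log fold-change values."""

    nodes: np.ndarray
    step: float

    @classmethod
    def make(cls, step: float = 0.1, lo: float = -15.0, hi: float = 15.0) -> "SGrid":
        n = int(round((hi - lo) / step)) + 1
        return cls(nodes=np.linspace(lo, hi, n), step=(hi - lo) / (n - 1))

    @property
    def trap_weights(self) -> np.ndarray:
        w = np.full(len(self.nodes), self.step)
        w[0] = w[-1] = 0.5 * self.step
        return w


def _family_density(family: str, s_rel: np.ndarray, sbar: float, s1: float = 0.0) -> np.ndarray:
    """Continuous component ``rho_exp`` evaluated at ``s - s0``."""
    s_rel = np.asarray(s_rel, dtype=float)
    if family == "asym_exp":
        return np.where(s_rel > 0.0, np.exp(-s_rel / sbar) / sbar, 0.0)
    if family == "sym_exp":
        return np.exp(-np.abs(s_rel) / sbar) / (2.0 * sbar)
    if family == "gauss_centered":
        return np.exp(-(s_rel**2) / (2.0 * sbar**2)) / np.sqrt(2.0 * np.pi * sbar**2)
    if family == "gauss_offcentered":
        return np.exp(-((s_rel - s1) ** 2) / (2.0 * sbar**2)) / np.sqrt(2.0 * np.pi * sbar**2)
    raise ValueError(family)


def expansion_prior_density(s, prior: ExpansionPrior):
    """Continuous density ``alpha * rho_exp(s - s0)`` and the atom weight.

    The delta atom at ``s0`` is carried separately and never smeared onto the
    grid; the returned tuple is ``(density_values, atom_weight)``.
    """
    dens = prior.alpha * _family_density(prior.family, np.asarray(s, float) - prior.s0, prior.sbar, prior.s1)
    return dens, 1.0 - prior.alpha


def _interp_columns(X: np.ndarray, nodes: np.ndarray, s0: float) -> np.ndarray:
    """Linear interpolation of kernel columns at an off-grid shift value."""
    if s0 <= nodes[0]:
        return X[:, 0]
    if s0 >= nodes[-1]:
        return X[:, -1]
    j = int(np.searchsorted(nodes, s0))
    t = (s0 - nodes[j - 1]) / (nodes[j] - nodes[j - 1])
    return X[:, j - 1] * (1.0 - t) + X[:, j] * t


class ExpansionKernel:
    """Tabulated per-pair likelihood kernels on the ``s`` grid.

    ``L[i, j] = int df rho(f) P(n_i | f) P(n_i' | f e^{s_j})`` for every unique
    observed pair plus the unobserved pair ``(0, 0)`` (last row), and
    ``Lf`` the same integral weighted by ``f`` (posterior-mean numerators;
    the ``f'``-weighted kernel is ``Lf * e^s``).
    """

    def __init__(
        self,
        table: PairTable,
        prior: CloneSizePrior,
        model: NoiseModel,
        ctx: SampleContext,
        ctx_prime: SampleContext,
        sgrid: SGrid | None = None,
        grid: FrequencyGrid | None = None,
        grid_points: int = 500,
    ):
        if sgrid is None:
            sgrid = SGrid.make()
        if grid is None:
            grid = FrequencyGrid(prior, grid_points)
        self.sgrid = sgrid
        self.table = table
        pairs = np.vstack([table.unique_pairs, [[0, 0]]])
        self.pairs = pairs
        self.counts = table.pair_counts
        self.n_obs = table.n_obs
        self.L, self.Lf = _likelihood_kernels(
            pairs, model, ctx, ctx_prime, sgrid.nodes, grid
        )

    # -- prior evaluation ---------------------------------------------------

    def _weights(self, prior: ExpansionPrior) -> np.ndarray:
        """Discrete continuous-component weights, renormalized to ``alpha``."""
        dens = _family_density(
            prior.family, self.sgrid.nodes - prior.s0, prior.sbar, prior.s1
        )
        w = self.sgrid.trap_weights * dens
        total = w.sum()
        if prior.alpha > 0.0 and total <= 0.0:
            raise FloatingPointError("expansion prior has no mass on the s grid")
        if total > 0.0:
            w = w * (prior.alpha / total)
        return w

    def mix(self, X: np.ndarray, prior: ExpansionPrior) -> np.ndarray:
        """Marginalize a kernel over the expansion prior (atom + tail)."""
        out = X @ self._weights(prior)
        if prior.alpha < 1.0:
            out = out + (1.0 - prior.alpha) * _interp_columns(X, self.sgrid.nodes, prior.s0)
        return out

    def pair_probabilities(self, prior: ExpansionPrior) -> np.ndarray:
        return self.mix(self.L, prior)

    def conditioned_log_likelihood(self, prior: ExpansionPrior) -> float:
        probs = self.pair_probabilities(prior)
        p00 = probs[-1]
        if p00 >= 1.0 - 1e-12:
            raise FloatingPointError("P(0,0) ~ 1 under the expansion model")
        with np.errstate(divide="ignore"):
            logs = np.log(probs[:-1])
        if np.any(~np.isfinite(logs)):
            return -np.inf
        return (float(self.counts @ logs) - self.n_obs * np.log1p(-p00)) / self.n_obs

    def normalizations(self, prior: ExpansionPrior):
        """Frequency budgets ``(Z, Z')`` of the two time points.

        Both sum the posterior-mean frequency (initial ``f`` for ``Z``, final
        ``f e^s`` for ``Z'``) over observed clones plus the extrapolated
        unseen clones.
        """
        probs = self.mix(self.L, prior)
        ef_num = self.mix(self.Lf, prior)
        efp_num = self.mix(self.Lf * np.exp(self.sgrid.nodes)[None, :], prior)
        ef = ef_num / probs
        efp = efp_num / probs
        p00 = probs[-1]
        N = self.n_obs / (1.0 - p00)
        Z = float(N * p00 * ef[-1] + self.counts @ ef[:-1])
        Zp = float(N * p00 * efp[-1] + self.counts @ efp[:-1])
        return Z, Zp

    def solve_s0(self, family: str, alpha: float, sbar: float, s1: float = 0.0) -> ExpansionPrior:
        """Impose equal repertoire size through the shift identity.

        A shift ``s -> s + s0`` multiplies every term of ``Z'`` by ``e^{s0}``,
        so ``Z'(s0) = Z`` is solved in closed form by ``s0 = -ln(Z'_0 / Z)``
        with ``Z'_0`` evaluated at ``s0 = 0``.
        """
        prior0 = ExpansionPrior(family, alpha, sbar, s0=0.0, s1=s1)
        Z, Zp0 = self.normalizations(prior0)
        if not (np.isfinite(Zp0) and Zp0 > 0.0):
            raise FitError(f"Z' not finite at s0=0 for alpha={alpha}, sbar={sbar}")
        s0 = -float(np.log(Zp0 / Z))
        return replace(prior0, s0=s0)


def _likelihood_kernels(pairs, model, ctx, ctx_prime, s_nodes, grid):
    f, w = grid.f, grid.rho_w
    wf = w * f
    n_vals, ia = np.unique(pairs[:, 0], return_inverse=True)
    np_vals, ib = np.unique(pairs[:, 1], return_inverse=True)
    ia, ib = ia.ravel(), ib.ravel()
    A = count_pmf_matrix(model, ctx, f, n_vals)[:, ia]  # (K, U)
    U, S = len(pairs), len(s_nodes)
    L = np.empty((U, S))
    Lf = np.empty((U, S))
    for j, s in enumerate(s_nodes):
        B = count_pmf_matrix(model, ctx_prime, f * np.exp(s), np_vals)
        prod = A * B[:, ib]
        L[:, j] = w @ prod
        Lf[:, j] = wf @ prod
    return L, Lf


def pair_likelihood_expansion(
    n,
    n_prime,
    prior: CloneSizePrior,
    model: NoiseModel,
    ctx: SampleContext,
    ctx_prime: SampleContext,
    expansion: ExpansionPrior,
    sgrid: SGrid | None = None,
    grid: FrequencyGrid | None = None,
    f_measure=None,
    grid_points: int = 800,
):
    """``P_exp(n, n')`` marginalized over frequency and log fold-change.

    The delta atom contributes the exact term
    ``(1 - alpha) int df rho(f) P(n|f) P(n'|f e^{s0})``; the continuous part
    is integrated on the ``s`` grid.  ``f_measure`` overrides the frequency
    measure (e.g. a point mass) for validation against brute-force quadrature.
    """
    if sgrid is None:
        sgrid = SGrid.make()
    scalar = np.isscalar(n) and np.isscalar(n_prime)
    pairs = np.column_stack([np.atleast_1d(n), np.atleast_1d(n_prime)])
    if f_measure is not None:
        f, w = (np.atleast_1d(np.asarray(x, float)) for x in f_measure)

        class _PointGrid:
            pass

        g = _PointGrid()
        g.f, g.rho_w = f, w
    else:
        g = grid if grid is not None else FrequencyGrid(prior, grid_points)
    L, _ = _likelihood_kernels(pairs, model, ctx, ctx_prime, sgrid.nodes, g)

    dens = _family_density(expansion.family, sgrid.nodes - expansion.s0, expansion.sbar, expansion.s1)
    w_s = sgrid.trap_weights * dens
    total = w_s.sum()
    if total > 0.0:
        w_s = w_s * (expansion.alpha / total)
    out = L @ w_s + (1.0 - expansion.alpha) * _interp_columns(L, sgrid.nodes, expansion.s0)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# fitting


@dataclass
class ExpansionFit:
    """Fitted expansion prior with likelihood diagnostics."""

    prior: ExpansionPrior
    avg_log_likelihood: float
    covariance: np.ndarray | None  # in (ln alpha, ln sbar)
    surface: pd.DataFrame  # likelihood surface over the search grid
    kernel: ExpansionKernel
    n_obs: int

    def std_errors(self) -> dict:
        if self.covariance is None:
            return {}
        se = np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))
        return {"ln_alpha": se[0], "ln_sbar": se[1]}


def _null_components(null, table):
    """Accept either a NullFit or an explicit (prior, model, ctx, ctx')."""
    if isinstance(null, NullFit):
        # read depths of the new table columns, not of the replicate pair
        return null.prior, null.model, SampleContext(table.n_reads[0]), SampleContext(table.n_reads[1])
    prior, model, ctx, ctx_prime = null
    return prior, model, ctx, ctx_prime


def fit_expansion(
    table: PairTable,
    null,
    family: str = "sym_exp",
    kernel: ExpansionKernel | None = None,
    alpha_grid: np.ndarray | None = None,
    sbar_grid: np.ndarray | None = None,
    sgrid: SGrid | None = None,
    grid_points: int = 500,
    refine: bool = True,
    compute_errors: bool = True,
    maxiter: int = 250,
) -> ExpansionFit:
    """Fit ``(alpha, sbar)`` by conditioned maximum likelihood.

    ``null`` is a :class:`NullFit` from the reference-day replicates, or an
    explicit ``(CloneSizePrior, NoiseModel, ctx, ctx')`` tuple.  A coarse
    grid search (logarithmic in ``alpha``, log-spaced in ``sbar``) seeds a
    Nelder-Mead refinement in ``(ln alpha, ln sbar)``; the shift ``s0`` is
    re-solved from ``Z' = Z`` inside every objective evaluation, so the
    reported covariance (from the finite-difference Hessian at the optimum)
    treats ``s0`` as an implicit function of the free parameters.
    """
    prior_f, model, ctx, ctx_prime = _null_components(null, table)
    if kernel is None:
        kernel = ExpansionKernel(
            table, prior_f, model, ctx, ctx_prime, sgrid=sgrid, grid_points=grid_points
        )
    if alpha_grid is None:
        alpha_grid = np.geomspace(1e-4, 0.5, 10)
    if sbar_grid is None:
        sbar_grid = np.geomspace(0.1, 10.0, 10)
    extra_s1 = family == "gauss_offcentered"
    records = []

    def objective(u: np.ndarray) -> float:
        alpha = float(np.exp(u[0]))
        sbar = float(np.exp(u[1]))
        s1 = float(u[2]) if extra_s1 else 0.0
        if not (1e-8 <= alpha <= 0.95 and 1e-4 <= sbar <= 50.0):
            return 1e8
        if extra_s1 and not 0.1 <= s1 <= 20.0:
            return 1e8
        try:
            prior_s = kernel.solve_s0(family, alpha, sbar, s1)
            ll = kernel.conditioned_log_likelihood(prior_s)
        except (FitError, FloatingPointError):
            return 1e8
        records.append((alpha, sbar, s1, prior_s.s0, ll))
        return -ll

    s1_vals = [0.3, 1.0] if extra_s1 else [0.0]
    best_u, best_val = None, np.inf
    for alpha in alpha_grid:
        for sbar in sbar_grid:
            for s1 in s1_vals:
                u = np.array(
                    [np.log(alpha), np.log(sbar)] + ([s1] if extra_s1 else [])
                )
                val = objective(u)
                if val < best_val:
                    best_u, best_val = u, val
    if best_u is None or best_val >= 1e8:
        raise FitError("expansion likelihood not finite anywhere on the search grid")

    if refine:
        res = optimize.minimize(
            objective,
            best_u,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-8},
        )
        if np.isfinite(res.fun) and res.fun < best_val:
            best_u, best_val = np.asarray(res.x, float), float(res.fun)

    alpha = float(np.exp(best_u[0]))
    sbar = float(np.exp(best_u[1]))
    s1 = float(best_u[2]) if extra_s1 else 0.0
    prior_s = kernel.solve_s0(family, alpha, sbar, s1)
    avg_ll = kernel.conditioned_log_likelihood(prior_s)

    covariance = None
    if compute_errors:
        def total_ll(u):
            val = objective(u)
            return -val * kernel.n_obs if val < 1e8 else -np.inf

        H = numeric_hessian(total_ll, best_u[:2] if not extra_s1 else best_u, step=5e-3)
        with np.errstate(all="ignore"):
            covariance = np.linalg.pinv(-0.5 * (H + H.T), rcond=1e-10)

    surface = pd.DataFrame(
        records, columns=["alpha", "sbar", "s1", "s0", "avg_log_likelihood"]
    ).drop_duplicates(subset=["alpha", "sbar", "s1"])
    logger.info(
        "fit_expansion family=%s alpha=%.4g sbar=%.4g s0=%.4g ll=%.6f",
        family,
        alpha,
        sbar,
        prior_s.s0,
        avg_ll,
    )
    return ExpansionFit(
        prior=prior_s,
        avg_log_likelihood=avg_ll,
        covariance=covariance,
        surface=surface,
        kernel=kernel,
        n_obs=kernel.n_obs,
    )


def solve_s0(
    alpha: float,
    sbar: float,
    null,
    table: PairTable,
    family: str = "sym_exp",
    s1: float = 0.0,
    sgrid: SGrid | None = None,
    grid_points: int = 500,
) -> float:
    """Shift ``s0`` enforcing ``Z' = Z`` for the given expansion parameters."""
    prior_f, model, ctx, ctx_prime = _null_components(null, table)
    kernel = ExpansionKernel(
        table, prior_f, model, ctx, ctx_prime, sgrid=sgrid, grid_points=grid_points
    )
    return kernel.solve_s0(family, alpha, sbar, s1).s0


# ---------------------------------------------------------------------------
# expectation-maximization for the symmetric-exponential scale


def em_update_sbar(
    kernel: ExpansionKernel,
    sbar_current: float,
    alpha: float = 1.0,
) -> float:
    """One EM step for the scale of a symmetric-exponential prior (s0 = 0).

    The M-step is analytic: the updated scale is the per-clone average of the
    posterior mean absolute log fold-change,
    ``sbar* = (1/N_obs) sum_i int |s| rho(s | n_i, n_i') ds``.
    With ``alpha < 1`` the average runs over the responding component only
    (responsibility-weighted); at ``alpha = 1`` it reduces to the plain
    per-clone average.

    The EM path uses the raw discretized prior weights (no grid
    renormalization): the analytic M-step then solves the discrete objective
    exactly, preserving the EM ascent guarantee node for node.
    """
    nodes = kernel.sgrid.nodes
    w_s = kernel.sgrid.trap_weights * alpha * _family_density("sym_exp", nodes, sbar_current)
    Lobs = kernel.L[:-1]  # observed pairs only; EM targets the unconditioned likelihood
    cont = Lobs * w_s[None, :]  # (U, S) joint weight over s
    cont_mass = cont.sum(axis=1)
    abs_s = cont @ np.abs(nodes)
    if alpha < 1.0:
        atom = (1.0 - alpha) * _interp_columns(Lobs, nodes, 0.0)
        total = cont_mass + atom
        resp = cont_mass / total
        exp_abs_s = abs_s / total
        num = float(kernel.counts @ exp_abs_s)
        den = float(kernel.counts @ resp)
    else:
        exp_abs_s = abs_s / cont_mass
        num = float(kernel.counts @ exp_abs_s)
        den = float(kernel.counts.sum())
    if den <= 0.0:
        raise FloatingPointError("no responding mass in any posterior")
    return num / den


def em_fit_sbar(
    kernel: ExpansionKernel,
    sbar_init: float = 1.0,
    alpha: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 200,
):
    """Iterate EM updates of ``sbar`` to a fixed point.

    Returns the fixed point and the trajectory of the (unconditioned)
    average log-likelihood, which EM ascends monotonically.
    """
    sbar = sbar_init
    nodes = kernel.sgrid.nodes
    traj = []
    for _ in range(max_iter):
        w_s = kernel.sgrid.trap_weights * alpha * _family_density("sym_exp", nodes, sbar)
        probs = kernel.L[:-1] @ w_s
        if alpha < 1.0:
            probs = probs + (1.0 - alpha) * _interp_columns(kernel.L[:-1], nodes, 0.0)
        traj.append(float(kernel.counts @ np.log(probs)) / kernel.n_obs)
        new = em_update_sbar(kernel, sbar, alpha)
        if abs(new - sbar) < tol * max(1.0, sbar):
            sbar = new
            break
        sbar = new
    return sbar, np.array(traj)


def compare_prior_families(
    table: PairTable,
    null,
    families=EXPANSION_FAMILIES,
    kernel: ExpansionKernel | None = None,
    grid_points: int = 500,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit each prior family and rank by per-clone average data likelihood.

    All families share one likelihood kernel (it does not depend on the
    prior), so the comparison costs four cheap reweighting fits.
    """
    prior_f, model, ctx, ctx_prime = _null_components(null, table)
    if kernel is None:
        kernel = ExpansionKernel(table, prior_f, model, ctx, ctx_prime, grid_points=grid_points)
    rows = []
    for family in families:
        fit = fit_expansion(
            table, null, family=family, kernel=kernel, compute_errors=False, **fit_kwargs
        )
        rows.append(
            {
                "family": family,
                "alpha": fit.prior.alpha,
                "sbar": fit.prior.sbar,
                "s0": fit.prior.s0,
                "s1": fit.prior.s1,
                "avg_log_likelihood": fit.avg_log_likelihood,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("avg_log_likelihood", ascending=False)
        .reset_index(drop=True)
    )
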