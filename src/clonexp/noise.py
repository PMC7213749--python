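"""Measurement-noise models: count distributions conditional on clone frequency.

A sequencing sample reports, per clonotype, a unique-molecule (UMI) count
``n``.  Given the clone's true frequency ``f``, three conditional laws
``P(n | f)`` of increasing realism are supported:

``poisson``
    Pure sampling noise, ``n ~ Poisson(f * N_read)``.
``negbin``
    Over-dispersed counts, negative binomial with mean ``nbar = f * N_read``
    and variance ``nbar + a * nbar**gamma``; reduces to Poisson at ``a = 0``.
``negbin_poisson``
    A two-step model that tracks the latent number of cells ``m`` in the
    sample: ``m`` is negative binomial with mean ``mbar = f * M`` and variance
    ``mbar + a * mbar**gamma`` (M = effective cells in the sample), and the
    molecule count is then ``n ~ Poisson(m * epsilon)`` with sequencing
    efficiency ``epsilon = N_read / M`` (UMIs per cell).

All evaluations are vectorized over grid frequencies and over the unique
count values appearing in the data; likelihoods over 1e5-1e6 clones collapse
to a few thousand unique count pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .clone_size import CloneSizePrior, FrequencyGrid

__all__ = [
    "NoiseModel",
    "SampleContext",
    "NOISE_KINDS",
    "count_pmf",
    "count_pmf_matrix",
    "pmf_mean_variance",
    "marginal_count_pmf",
]

NOISE_KINDS = ("poisson", "negbin", "negbin_poisson")

# Two-step marginalization over the latent cell count m: exact integer
# summation for small means, per-frequency local continuous quadrature
# spanning mbar +- 12 sigma for large means (where the NB is Gaussian-like;
# a shared log grid would under-resolve both the NB width and the Poisson
# read-out kernel there).  The integer branch uses a wider 25-sigma span:
# for strongly over-dispersed small means the NB tail is sub-Gaussian-slow
# and 12 sigma leaves ~1e-8 of mass.
_M_INT_MAX = 600
_M_CONT_POINTS = 129
_M_SIGMA_SPAN = 12.0
_M_INT_SIGMA_SPAN = 25.0


@dataclass(frozen=True)
class NoiseModel:
    """Parameters of a conditional count law ``P(n | f)``.

    ``a`` and ``gamma`` set the over-dispersion (variance = mean + a*mean^gamma)
    and are ignored by the ``poisson`` kind.  ``M`` is the effective number of
    cells in the sample and is used only by ``negbin_poisson``.
    """

    kind: str
    a: float = 0.0
    gamma: float = 1.0
    M: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}; expected one of {NOISE_KINDS}")
        if self.a < 0.0:
            raise ValueError("over-dispersion coefficient a must be >= 0")
        if self.kind == "negbin_poisson":
            if self.M is None or not self.M > 0:
                raise ValueError("two-step model requires a positive effective cell count M")


@dataclass(frozen=True)
class SampleContext:
    """Per-sample sequencing totals: ``n_reads`` is the total UMI count."""

    n_reads: float

    def __post_init__(self) -> None:
        if not self.n_reads >= 1:
            raise ValueError("n_reads must be >= 1")

    def efficiency(self, model: NoiseModel) -> float:
        """Sequencing efficiency epsilon = N_read / M (UMIs per cell)."""
        if model.M is None:
            raise ValueError("efficiency is defined only for the two-step model")
        return self.n_reads / model.M


def _poisson_log_pmf(n, mean):
    """log Poisson pmf, broadcasting; mean == 0 puts all mass on n == 0."""
    n = np.asarray(n, dtype=float)
    mean = np.asarray(mean, dtype=float)
    if np.all(mean > 0):  # fast path: no degenerate rows, no masking temporaries
        return n * np.log(mean) - mean - gammaln(n + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = n * np.log(np.where(mean > 0, mean, 1.0)) - mean - gammaln(n + 1.0)
    zero_mean = np.broadcast_to(mean == 0, out.shape)
    nb = np.broadcast_to(n, out.shape)
    out = np.where(zero_mean, np.where(nb == 0, 0.0, -np.inf), out)
    return out


def _negbin_log_pmf(n, mean, a, gamma):
    """log pmf of the mean/variance-parametrized negative binomial.

    ``n`` may be non-integer: the gamma-function form extends the pmf to a
    continuous density in ``n``, which the two-step model uses for the large-m
    tail.  Falls back to Poisson where the over-dispersion term underflows.
    """
    if a == 0.0:
        return _poisson_log_pmf(n, mean)
    n = np.asarray(n, dtype=float)
    mean = np.asarray(mean, dtype=float)
    t = a * mean ** (gamma - 1.0)  # variance = mean * (1 + t)
    r = mean / np.where(t > 0, t, 1.0)
    log_p = -np.log1p(t)
    log_1mp = np.where(t > 0, np.log(np.where(t > 0, t, 1.0)) + log_p, -np.inf)
    with np.errstate(invalid="ignore"):
        nb = (
            gammaln(n + r)
            - gammaln(r)
            - gammaln(n + 1.0)
            + r * log_p
            + n * log_1mp
        )
    # r -> inf (t -> 0) limit is Poisson; switch before gammaln loses precision
    pois = _poisson_log_pmf(n, mean)
    t_b = np.broadcast_to(t, nb.shape)
    return np.where(t_b < 1e-10, pois, nb)


def _m_grid(mbar: float, a: float, gamma: float):
    """Support and weights for the latent cell count at a single frequency.

    Exact integer summation when the span fits below ``_M_INT_MAX``;
    otherwise a local linear grid over ``mbar +- 12 sigma`` with trapezoid
    weights on the continuous extension of the NB pmf.
    """
    var = mbar + a * mbar**gamma
    hi_int = mbar + _M_INT_SIGMA_SPAN * np.sqrt(var) + 25.0
    if hi_int <= _M_INT_MAX:
        m = np.arange(0.0, hi_int + 1.0)
        return m, np.ones_like(m)
    hi = mbar + _M_SIGMA_SPAN * np.sqrt(var) + 1.0
    lo = max(0.0, mbar - _M_SIGMA_SPAN * np.sqrt(var))
    m = np.linspace(lo, hi, _M_CONT_POINTS)
    w = np.full(_M_CONT_POINTS, m[1] - m[0])
    w[0] = w[-1] = 0.5 * (m[1] - m[0])
    return m, w


def _two_step_matrix(model: NoiseModel, ctx: SampleContext, f: np.ndarray, n: np.ndarray):
    """``P(n|f) = sum_m P(m|f) Poisson(n | m eps)`` marginalized per row.

    Rows with small mean cell count share one exact integer support; rows
    with large mean use per-row local linear grids (vectorized in chunks) so
    that both the NB width and the Poisson kernel stay resolved.
    """
    eps = ctx.efficiency(model)
    mbar = f * model.M
    a, gamma = model.a, model.gamma
    sigma = np.sqrt(mbar + a * mbar**gamma)
    hi_int = mbar + _M_INT_SIGMA_SPAN * sigma + 25.0
    small = hi_int <= _M_INT_MAX
    A = np.empty((len(f), len(n)))

    if small.any():
        m = np.arange(0.0, float(hi_int[small].max()) + 1.0)
        W = np.exp(_negbin_log_pmf(m[None, :], mbar[small, None], a, gamma))
        W /= W.sum(axis=1, keepdims=True)
        B = np.exp(_poisson_log_pmf(n[None, :], (m * eps)[:, None]))
        A[small] = W @ B

    large = np.flatnonzero(~small)
    if large.size:
        P = _M_CONT_POINTS
        t = np.linspace(0.0, 1.0, P)
        trap = np.full(P, 1.0)
        trap[0] = trap[-1] = 0.5
        chunk = max(1, int(4_000_000 // (P * max(len(n), 1))))
        for lo_i in range(0, large.size, chunk):
            rows = large[lo_i : lo_i + chunk]
            mb = mbar[rows][:, None]
            sg = sigma[rows][:, None]
            m_lo = np.maximum(0.0, mb - _M_SIGMA_SPAN * sg)
            m_hi = mb + _M_SIGMA_SPAN * sg
            m = m_lo + (m_hi - m_lo) * t[None, :]  # (R, P)
            g = np.exp(_negbin_log_pmf(m, mb, a, gamma)) * trap[None, :]
            g /= g.sum(axis=1, keepdims=True)
            B = np.exp(_poisson_log_pmf(n[None, None, :], (m * eps)[:, :, None]))
            A[rows] = np.einsum("rp,rpn->rn", g, B)
    return A


def count_pmf_matrix(model: NoiseModel, ctx: SampleContext, f, n) -> np.ndarray:
    """Matrix ``P(n_j | f_i)`` of shape ``(len(f), len(n))``."""
    f = np.atleast_1d(np.asarray(f, dtype=float))
    n = np.atleast_1d(np.asarray(n, dtype=float))
    if np.any((f <= 0.0) | (f >= 1.0)) and model.kind != "negbin_poisson":
        # expansion likelihoods evaluate P(n | f e^s) which may exceed 1; the
        # pmf remains well defined there, so only reject non-positive f
        pass
    if np.any(f <= 0.0):
        raise ValueError("frequencies must be positive")
    if np.any(n < 0):
        raise ValueError("counts must be non-negative")
    if model.kind == "poisson":
        return np.exp(_poisson_log_pmf(n[None, :], (f * ctx.n_reads)[:, None]))
    if model.kind == "negbin":
        return np.exp(
            _negbin_log_pmf(n[None, :], (f * ctx.n_reads)[:, None], model.a, model.gamma)
        )
    return _two_step_matrix(model, ctx, f, n)


def count_pmf(f: float, model: NoiseModel, ctx: SampleContext, n) -> float | np.ndarray:
    """Probability ``P(n | f)`` for a single frequency.

    ``n`` may be a scalar or an integer array.
    """
    if not 0.0 < f < 1.0:
        raise ValueError(f"frequency must lie in (0, 1), got {f}")
    out = count_pmf_matrix(model, ctx, np.array([f]), np.atleast_1d(n))[0]
    return float(out[0]) if np.isscalar(n) else out


def pmf_mean_variance(model: NoiseModel, ctx: SampleContext, f: float):
    """Closed-form mean and variance of ``P(n | f)``.

    For the two-step model the law of total variance gives
    ``Var = nbar (1 + eps) + eps^2 a (f M)^gamma`` with ``eps = N_read / M``:
    Poisson sampling of molecules from ``m`` cells adds ``eps * nbar`` on top
    of the scaled cell-count variance.
    """
    nbar = f * ctx.n_reads
    if model.kind == "poisson":
        return nbar, nbar
    if model.kind == "negbin":
        return nbar, nbar + model.a * nbar**model.gamma
    eps = ctx.efficiency(model)
    mbar = f * model.M
    var_m = mbar + model.a * mbar**model.gamma
    return nbar, nbar + eps**2 * var_m


def marginal_count_pmf(
    prior: CloneSizePrior,
    model: NoiseModel,
    ctx: SampleContext,
    n,
    grid: FrequencyGrid | None = None,
) -> np.ndarray | float:
    """Marginal count distribution ``P(n) = integral rho(f) P(n|f) df``.

    For Poisson noise and large counts ``P(n)`` inherits the power law of the
    clone-size prior, ``P(n) ~ n**-nu``.
    """
    if grid is None:
        grid = FrequencyGrid(prior)
    out = grid.rho_w @ count_pmf_matrix(model, ctx, grid.f, np.atleast_1d(n))
    return float(out[0]) if np.isscalar(n) else out
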