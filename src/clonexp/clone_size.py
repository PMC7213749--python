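"""Power-law prior over clone frequencies and Hill diversities.

The size of a T-cell clone is summarized by its frequency ``f``, the fraction
of the organism's lymphocytes carrying that receptor.  Across individuals the
distribution of clone frequencies is well described by a power law

    rho(f) = C f**(-nu),   f_min <= f < 1,

with exponent ``nu > 1`` and a lower cutoff ``f_min`` that regularizes the
divergence at zero and reflects the smallest realizable frequency (one cell
out of the whole repertoire).  The frequencies of the N clones in an organism
must sum to one; on average that is guaranteed by the mean constraint
``N * <f> = 1``, which ties ``f_min`` to ``(nu, N)`` and is used throughout
the package to eliminate ``f_min`` as a free parameter.

The same prior yields whole-repertoire Hill diversities
``D_beta = (N <f**beta>)**(1/(1-beta))``: species richness (beta=0), the
exponential Shannon entropy (beta=1) and the inverse Simpson index (beta=2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "CloneSizePrior",
    "RepertoireSize",
    "FrequencyGrid",
    "solve_fmin",
    "hill_diversity",
    "hill_diversity_from_frequencies",
]


@dataclass(frozen=True)
class CloneSizePrior:
    """Power-law clone-frequency density ``C f**-nu`` on ``[f_min, 1)``.

    Parameters
    ----------
    nu : float
        Power-law exponent; must exceed 1 (otherwise the normalization
        integral diverges at the upper end of the support for nu <= 1
        combined with the small-f divergence).
    f_min : float
        Lower edge of the support, in (0, 1).
    """

    nu: float
    f_min: float

    def __post_init__(self) -> None:
        if not self.nu > 1.0:
            raise ValueError(f"power-law exponent nu must be > 1, got {self.nu}")
        if not 0.0 < self.f_min < 1.0:
            raise ValueError(f"f_min must lie in (0, 1), got {self.f_min}")

    @property
    def C(self) -> float:
        """Normalization constant, ``(nu-1) / (f_min**(1-nu) - 1)``."""
        return (self.nu - 1.0) / (self.f_min ** (1.0 - self.nu) - 1.0)

    def density(self, f):
        """Probability density at frequency ``f``; zero outside the support."""
        f = np.asarray(f, dtype=float)
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            vals = self.C * np.power(f, -self.nu, where=f > 0.0, out=np.zeros_like(f))
        out = np.where((f >= self.f_min) & (f < 1.0), vals, 0.0)
        return out if out.ndim else float(out)

    def moment(self, beta: float) -> float:
        """Closed-form moment ``<f**beta>`` of the prior.

        Handles the logarithmic branch ``beta - nu + 1 = 0`` exactly.
        """
        p = beta - self.nu + 1.0
        if abs(p) < 1e-12:
            return self.C * np.log(1.0 / self.f_min)
        return self.C * (1.0 - self.f_min**p) / p

    def neg_f_log_f_moment(self) -> float:
        """Closed form of ``<-f ln f>``, the Shannon-entropy integrand moment."""
        q = 2.0 - self.nu
        if abs(q) < 1e-12:
            return self.C * 0.5 * np.log(self.f_min) ** 2

        def antideriv(f: float) -> float:
            return f**q * (1.0 / q**2 - np.log(f) / q)

        return self.C * (antideriv(1.0) - antideriv(self.f_min))

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Exact inverse-CDF draws from the power law."""
        u = rng.random(size)
        t = self.f_min ** (1.0 - self.nu)
        return ((1.0 - u) * t + u) ** (1.0 / (1.0 - self.nu))


@dataclass(frozen=True)
class RepertoireSize:
    """Total clone count ``N`` in the organism and observed count ``N_obs``."""

    N: float
    N_obs: int = 0

    def __post_init__(self) -> None:
        if not self.N >= self.N_obs >= 0:
            raise ValueError(f"need N >= N_obs >= 0, got N={self.N}, N_obs={self.N_obs}")


class FrequencyGrid:
    """Logarithmically spaced quadrature grid over the prior support.

    The density spans many decades, so all frequency integrals in the package
    are evaluated on a log-spaced grid with Simpson weights in ``ln f``.  The
    probability measure ``rho(f) df`` is renormalized on the grid so that the
    discrete measure sums exactly to one (the analytic value), which keeps
    joint count distributions properly normalized to grid accuracy.

    Attributes
    ----------
    f : ndarray
        Grid nodes in ``[f_min, 1]``.
    rho_w : ndarray
        Discrete probability weights approximating ``rho(f) df``; sums to 1.
    """

    def __init__(self, prior: CloneSizePrior, n_points: int = 800, f_max: float = 1.0):
        if n_points < 5:
            raise ValueError("need at least 5 grid points")
        if n_points % 2 == 0:
            n_points += 1  # Simpson weights need an odd node count
        self.prior = prior
        self.n_points = n_points
        x = np.linspace(np.log(prior.f_min), np.log(f_max), n_points)
        self.f = np.exp(x)
        h = x[1] - x[0]
        w = np.full(n_points, 2.0)
        w[1::2] = 4.0
        w[0] = w[-1] = 1.0
        w *= h / 3.0
        # rho(f) df = C f^{1-nu} d(ln f); renormalize to the exact total mass 1
        raw = w * prior.C * self.f ** (1.0 - prior.nu)
        self.rho_w = raw / raw.sum()

    def expect(self, values: np.ndarray) -> float:
        """Expectation of per-node ``values`` under the prior measure."""
        return float(self.rho_w @ values)


def solve_fmin(nu: float, N: float, tol: float = 1e-12) -> float:
    """Solve the mean constraint ``N * <f> = 1`` for ``f_min``.

    The constraint pins the lower frequency cutoff once the exponent and the
    total clone count are fixed; ``<f>`` is monotone in ``f_min`` so the root
    is unique.
    """
    if not nu > 1.0:
        raise ValueError("nu must be > 1")
    if not N > 1.0:
        raise ValueError("N must be > 1")

    def log_constraint(ln_fmin: float) -> float:
        prior = CloneSizePrior(nu, float(np.exp(ln_fmin)))
        return np.log(N * prior.moment(1.0))

    # keep both f_min and f_min**(1-nu) representable in double precision
    lo = -min(700.0 / (nu - 1.0), 690.0) + 2.0
    hi = np.log(1.0 - 1e-9)
    flo, fhi = log_constraint(lo), log_constraint(hi)
    if not (flo < 0.0 < fhi):
        raise ValueError(
            f"no f_min in (0,1) satisfies N<f>=1 for nu={nu}, N={N} "
            f"(constraint at brackets: {flo:.3g}, {fhi:.3g})"
        )
    root = optimize.brentq(log_constraint, lo, hi, xtol=tol, rtol=8.9e-16)
    return float(np.exp(root))


def hill_diversity(beta: float, prior: CloneSizePrior, N: float) -> float:
    """Hill diversity ``D_beta = (N <f**beta>)**(1/(1-beta))`` of the repertoire.

    beta=0 gives species richness ``N``; beta=1 the exponential Shannon
    entropy ``exp(N <-f ln f>)``; beta=2 the inverse Simpson index
    ``1 / (N <f^2>)``.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if beta == 0:
        return float(N)
    if abs(beta - 1.0) < 1e-12:
        return float(np.exp(N * prior.neg_f_log_f_moment()))
    return float((N * prior.moment(beta)) ** (1.0 / (1.0 - beta)))


def hill_diversity_from_frequencies(beta: float, freqs: np.ndarray) -> float:
    """Hill diversity of an explicit frequency vector (must sum to ~1)."""
    f = np.asarray(freqs, dtype=float)
    f = f[f > 0]
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if beta == 0:
        return float(f.size)
    if abs(beta - 1.0) < 1e-12:
        return float(np.exp(-np.sum(f * np.log(f))))
    return float(np.sum(f**beta) ** (1.0 / (1.0 - beta)))
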