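"""Per-clone posteriors over log fold-change and responder detection.

Once the null model and the expansion prior are fitted, Bayes' rule gives,
for each observed count pair,

    rho(s | n, n') ~ rho_s(s) * int df rho(f) P(n | f) P(n' | f e^s),

a mixture of a delta atom at the global shift ``s0`` (the non-responding
component) and a continuous density.  The atom is tracked analytically and
never binned: the cumulative distribution carries an explicit jump, which
matters exactly at the decision point of the detection criterion.

A clone is called expanded when its posterior probability of not expanding,
``P_null = P(s <= 0 | n, n')``, falls below a threshold (0.025 by default),
and contracted symmetrically when ``P(s >= 0 | n, n') < threshold``.
Posteriors are computed once per unique count pair, never per clone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .clone_size import FrequencyGrid
from .expansion import (
    ExpansionKernel,
    ExpansionPrior,
    SGrid,
    _family_density,
    _likelihood_kernels,
    _null_components,
)
from .null_inference import NullFit
from .tables import PairTable

__all__ = [
    "PosteriorGrid",
    "posterior_s",
    "p_null",
    "posterior_summaries",
    "naive_log_fold_change",
    "detect_responding",
    "list_overlap",
]

DEFAULT_THRESHOLD = 0.025


@dataclass
class PosteriorGrid:
    """Discretized posterior over ``s`` with a separate weight on the atom.

    ``density`` is the continuous component evaluated at ``s_nodes`` (uniform
    spacing); ``atom_weight`` is the posterior mass of the non-responding
    delta component at ``s0``.  The two parts together integrate to one.
    """

    s_nodes: np.ndarray
    density: np.ndarray
    atom_weight: float
    s0: float
    f_mean: float  # posterior mean initial frequency <f | n, n'>

    def __post_init__(self) -> None:
        h = self.s_nodes[1] - self.s_nodes[0]
        seg = 0.5 * (self.density[:-1] + self.density[1:]) * h
        self._cont_cdf = np.concatenate([[0.0], np.cumsum(seg)])

    def cdf(self, x) -> float | np.ndarray:
        """``F(x) = P(s <= x)``, including the jump of the atom."""
        x = np.asarray(x, dtype=float)
        cont = np.interp(x, self.s_nodes, self._cont_cdf)
        out = cont + self.atom_weight * (self.s0 <= x)
        return float(out) if out.ndim == 0 else out

    def prob_greater(self, x: float) -> float:
        """``P(s > x)`` computed from the upper tail (no 1-minus shortcut)."""
        cont_total = float(self._cont_cdf[-1])
        cont = cont_total - float(np.interp(x, self.s_nodes, self._cont_cdf))
        return cont + self.atom_weight * (self.s0 > x)

    @property
    def p_null(self) -> float:
        """Posterior probability of not expanding, ``P(s <= 0)``."""
        return min(max(self.cdf(0.0), 0.0), 1.0)

    @property
    def p_null_contract(self) -> float:
        """Posterior probability of not contracting, ``P(s >= s0)``.

        Contraction is judged relative to the global shift ``s0``: the atom
        is the non-responding component, so it always counts as "not
        contracting".  (Using 0 as the reference would mislabel every
        atom-dominated clone whenever the fitted ``s0`` is slightly
        negative.)
        """
        ref = min(self.s0, 0.0)
        cont = float(self._cont_cdf[-1]) - float(np.interp(ref, self.s_nodes, self._cont_cdf))
        return min(max(cont + self.atom_weight, 0.0), 1.0)

    @property
    def mean(self) -> float:
        h = self.s_nodes[1] - self.s_nodes[0]
        w = np.full(len(self.s_nodes), h)
        w[0] = w[-1] = 0.5 * h
        return float(w @ (self.density * self.s_nodes) + self.atom_weight * self.s0)

    @property
    def median(self) -> float:
        """Inverse-CDF median; an atom plateau crossing 0.5 maps to ``s0``."""
        lo, hi = self.s_nodes[0], self.s_nodes[-1]
        if self.cdf(lo) >= 0.5:
            return float(lo)
        if self.cdf(hi) < 0.5:
            return float(hi)
        below = float(np.interp(self.s0, self.s_nodes, self._cont_cdf))
        if self.s0 >= lo and below < 0.5 <= below + self.atom_weight * (self.s0 <= hi):
            return float(self.s0)
        return float(optimize.brentq(lambda x: self.cdf(x) - 0.5, lo, hi, xtol=1e-12))

    def summaries(self):
        return self.mean, self.median, self.f_mean


def _posterior_from_kernel_row(
    L_row: np.ndarray, Lf_row: np.ndarray, sgrid: SGrid, expansion: ExpansionPrior
) -> PosteriorGrid:
    nodes = sgrid.nodes
    dens_prior = _family_density(
        expansion.family, nodes - expansion.s0, expansion.sbar, expansion.s1
    )
    w_prior = sgrid.trap_weights * dens_prior
    total_prior = w_prior.sum()
    scale = expansion.alpha / total_prior if total_prior > 0.0 else 0.0
    cont_density = dens_prior * scale * L_row
    atom = (1.0 - expansion.alpha) * float(np.interp(expansion.s0, nodes, L_row))
    cont_mass = float(sgrid.trap_weights @ cont_density)
    total = cont_mass + atom
    if not total > 0.0:
        raise FloatingPointError("posterior has zero total mass (likelihood underflow)")
    cont_f = float(sgrid.trap_weights @ (dens_prior * scale * Lf_row))
    atom_f = (1.0 - expansion.alpha) * float(np.interp(expansion.s0, nodes, Lf_row))
    return PosteriorGrid(
        s_nodes=nodes,
        density=cont_density / total,
        atom_weight=atom / total,
        s0=expansion.s0,
        f_mean=(cont_f + atom_f) / total,
    )


def posterior_s(
    n: int,
    n_prime: int,
    null,
    expansion: ExpansionPrior,
    sgrid: SGrid | None = None,
    grid_points: int = 500,
    f_measure=None,
) -> PosteriorGrid:
    """Posterior over the log fold-change for a single count pair.

    ``null`` is a :class:`NullFit` (its own sample contexts are used) or an
    explicit ``(CloneSizePrior, NoiseModel, ctx, ctx')`` tuple; pass the
    tuple form when the two time points have different read depths.
    ``f_measure`` overrides the frequency measure for validation.
    """
    if isinstance(null, NullFit):
        prior_f, model, ctx, ctx_prime = null.prior, null.model, null.ctx, null.ctx_prime
    else:
        prior_f, model, ctx, ctx_prime = null
    if sgrid is None:
        sgrid = SGrid.make()
    if f_measure is not None:
        f, w = (np.atleast_1d(np.asarray(x, float)) for x in f_measure)
        g = type("PointMeasure", (), {})()
        g.f, g.rho_w = f, w
    else:
        g = FrequencyGrid(prior_f, grid_points)
    pairs = np.array([[n, n_prime]])
    L, Lf = _likelihood_kernels(pairs, model, ctx, ctx_prime, sgrid.nodes, g)
    return _posterior_from_kernel_row(L[0], Lf[0], sgrid, expansion)


def p_null(posterior: PosteriorGrid) -> float:
    """``P(s <= 0 | n, n')`` including the atom when ``s0 <= 0``."""
    return posterior.p_null


def posterior_summaries(posterior: PosteriorGrid):
    """``(s_mean, s_median, f_mean)`` of a posterior grid."""
    return posterior.summaries()


def naive_log_fold_change(n, n_prime):
    """``ln(n'/n)``; undefined (NaN) when either count is zero."""
    n = np.asarray(n, dtype=float)
    n_prime = np.asarray(n_prime, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((n > 0) & (n_prime > 0), np.log(n_prime / n), np.nan)
    return float(out) if out.ndim == 0 else out


def detect_responding(
    table: PairTable,
    null,
    expansion: ExpansionPrior,
    threshold: float = DEFAULT_THRESHOLD,
    kernel: ExpansionKernel | None = None,
    sgrid: SGrid | None = None,
    grid_points: int = 500,
) -> pd.DataFrame:
    """Per-clone posterior summaries and expansion/contraction calls.

    Returns one row per clone with ``s_naive``, posterior mean/median,
    ``P_null`` in both directions, the posterior mean initial frequency and
    the call (``expanded`` / ``contracted`` / ``unresolved``).  Ties at the
    threshold are conservative (not significant).
    """
    prior_f, model, ctx, ctx_prime = _null_components(null, table)
    if kernel is None:
        kernel = ExpansionKernel(
            table, prior_f, model, ctx, ctx_prime, sgrid=sgrid, grid_points=grid_points
        )
    sgrid = kernel.sgrid
    U = len(table.unique_pairs)
    cols = {
        name: np.empty(U)
        for name in ("p_null_expand", "p_null_contract", "s_mean", "s_median", "f_mean")
    }
    for u in range(U):
        post = _posterior_from_kernel_row(kernel.L[u], kernel.Lf[u], sgrid, expansion)
        cols["p_null_expand"][u] = post.p_null
        cols["p_null_contract"][u] = post.p_null_contract
        cols["s_mean"][u] = post.mean
        cols["s_median"][u] = post.median
        cols["f_mean"][u] = post.f_mean

    idx = table.pair_index
    df = table.df.copy()
    for name, vals in cols.items():
        df[name] = vals[idx]
    df["s_naive"] = naive_log_fold_change(df["n"].to_numpy(), df["n_prime"].to_numpy())
    df["call"] = np.where(
        df["p_null_expand"] < threshold,
        "expanded",
        np.where(df["p_null_contract"] < threshold, "contracted", "unresolved"),
    )
    return df[
        [
            "clone_id",
            "n",
            "n_prime",
            "s_naive",
            "s_mean",
            "s_median",
            "p_null_expand",
            "p_null_contract",
            "f_mean",
            "call",
        ]
    ]


def list_overlap(list_a, list_b) -> float:
    """Jaccard overlap ``|A & B| / |A u B|``; 0 for two empty lists."""
    a, b = set(list_a), set(list_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)
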