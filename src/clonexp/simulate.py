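"""Exact sampling of observed count tables under the null and expansion models.

Two samplers are provided:

* :func:`sample_null_pair` draws a same-day replicate pair without ever
  instantiating the vast majority of clones that are unseen in both
  replicates.  Conditioning on observation (``n + n' > 0``) splits the count
  plane into three quadrants -- seen only in replicate 1 (``q_x0``), only in
  replicate 2 (``q_0x``), or in both (``q_xx``) -- whose analytic weights sum
  to one.  Each of the ``N_obs = N (1 - P(0,0))`` observed clones is assigned
  a quadrant, a frequency from the quadrant-conditioned posterior (inverse
  CDF on the log-frequency grid), and zero-truncated counts.  For the
  two-step noise model the latent cell count is marginalized in the quadrant
  weights and sampled explicitly, conditioned on a nonzero read count, when
  counts are drawn.

* :func:`sample_expansion_pair` implements the straightforward full-
  repertoire scheme for two time points: frequencies are drawn from the
  power law until they sum exactly to one (a final remainder clone closes
  the sum), each clone receives a log fold-change from the expansion prior,
  second-day frequencies are renormalized by the empirical sum, counts are
  drawn from the noise model at both time points, and unobserved clones are
  discarded.  Here ``N_obs`` is stochastic.  Ground-truth frequencies and
  fold-changes are returned for recovery tests.

Identical configuration and seed give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clone_size import CloneSizePrior, FrequencyGrid, solve_fmin
from .expansion import ExpansionPrior, _family_density
from .noise import NoiseModel, SampleContext, count_pmf_matrix
from .null_inference import zero_count_probability
from .tables import PairTable

__all__ = [
    "SimulationConfig",
    "sample_null_pair",
    "sample_null_pair_rejection",
    "sample_expansion_pair",
    "zero_truncated_count",
    "sample_counts",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative configuration for a two-sample experiment.

    ``n_reads_1/2`` are the nominal per-sample read totals (``eps * M`` for
    the two-step model); realized totals are stochastic.  ``f_min`` is always
    derived from the mean constraint ``N <f> = 1``.
    """

    N: int
    nu: float = 2.0
    noise: str = "poisson"
    a: float = 0.0
    gamma: float = 1.0
    M: float | None = None
    n_reads_1: float = 1e4
    n_reads_2: float = 1e4
    expansion: ExpansionPrior | None = None
    grid_points: int = 800
    seed: int | None = None

    @property
    def f_min(self) -> float:
        return solve_fmin(self.nu, self.N)

    def prior(self) -> CloneSizePrior:
        return CloneSizePrior(self.nu, self.f_min)

    def model(self) -> NoiseModel:
        return NoiseModel(self.noise, self.a, self.gamma, self.M)

    def contexts(self) -> tuple[SampleContext, SampleContext]:
        return SampleContext(self.n_reads_1), SampleContext(self.n_reads_2)

    @classmethod
    def mouse(cls, **kw) -> "SimulationConfig":
        """Mouse-sized repertoire: 1e6 clones, 1e4 reads per sample."""
        kw.setdefault("N", 10**6)
        kw.setdefault("n_reads_1", 1e4)
        kw.setdefault("n_reads_2", 1e4)
        return cls(**kw)

    @classmethod
    def human(cls, **kw) -> "SimulationConfig":
        """Human-sized repertoire: 1e9 clones, 1e6 reads per sample."""
        kw.setdefault("N", 10**9)
        kw.setdefault("n_reads_1", 1e6)
        kw.setdefault("n_reads_2", 1e6)
        return cls(**kw)

    def resolved(self) -> dict:
        """Flat dict of all generative parameters including derived f_min."""
        out = {
            "N": self.N,
            "nu": self.nu,
            "noise": self.noise,
            "a": self.a,
            "gamma": self.gamma,
            "M": self.M,
            "n_reads_1": self.n_reads_1,
            "n_reads_2": self.n_reads_2,
            "f_min": self.f_min,
            "grid_points": self.grid_points,
            "seed": self.seed,
        }
        if self.expansion is not None:
            out.update(
                {
                    "expansion_family": self.expansion.family,
                    "alpha": self.expansion.alpha,
                    "sbar": self.expansion.sbar,
                    "s1": self.expansion.s1,
                }
            )
        return out


def _rng(config: SimulationConfig, rng) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(config.seed)


# ---------------------------------------------------------------------------
# count sampling helpers


def sample_counts(
    f: np.ndarray, model: NoiseModel, ctx: SampleContext, rng: np.random.Generator
) -> np.ndarray:
    """Untruncated draws ``n ~ P(n | f)``, vectorized over clones."""
    f = np.asarray(f, dtype=float)
    if model.kind == "poisson":
        return rng.poisson(f * ctx.n_reads)
    if model.kind == "negbin":
        return _negbin_draw(f * ctx.n_reads, model.a, model.gamma, rng)
    m = _negbin_draw(f * model.M, model.a, model.gamma, rng)
    return rng.poisson(m * ctx.efficiency(model))


def _negbin_draw(mean, a, gamma, rng):
    """Gamma-Poisson draw of the mean/variance-parametrized NB."""
    mean = np.asarray(mean, dtype=float)
    if a == 0.0:
        return rng.poisson(mean)
    t = a * mean ** (gamma - 1.0)
    r = mean / t
    scale = t  # (1-p)/p
    lam = rng.gamma(shape=r, scale=scale)
    return rng.poisson(lam)


def zero_truncated_count(
    f, model: NoiseModel, ctx: SampleContext, rng: np.random.Generator
) -> np.ndarray:
    """Exact draws from ``P(n | f, n > 0)``, the zero-truncated noise law.

    Poisson and negative-binomial kinds use inverse-CDF sampling on the
    renormalized domain (uniform draws above ``P(0|f)``); underflowing
    ``P(n > 0 | f)`` falls back to a deterministic count of 1, the exact
    limit of the truncated law.  The two-step kind samples the latent cell
    count from ``P(m | f, n > 0)`` and then a zero-truncated Poisson.
    """
    f = np.atleast_1d(np.asarray(f, dtype=float))
    if model.kind == "poisson":
        return _zt_poisson(f * ctx.n_reads, rng)
    if model.kind == "negbin":
        mean = f * ctx.n_reads
        if model.a == 0.0:
            return _zt_poisson(mean, rng)
        t = model.a * mean ** (model.gamma - 1.0)
        r = mean / t
        p = 1.0 / (1.0 + t)
        p0 = np.exp(r * np.log(p))
        u = p0 + (1.0 - p0) * rng.random(len(f))
        out = stats.nbinom.ppf(np.minimum(u, 1.0 - 1e-16), r, p).astype(np.int64)
        return np.maximum(out, 1)
    return _zt_two_step(f, model, ctx, rng)


def _zt_poisson(mu, rng):
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    p0 = np.exp(-mu)
    u = p0 + (1.0 - p0) * rng.random(len(mu))
    out = stats.poisson.ppf(np.minimum(u, 1.0 - 1e-16), mu).astype(np.int64)
    return np.maximum(out, 1)


def _zt_two_step(f, model, ctx, rng):
    """Sample (m, n) | n > 0 for the two-step model, grouped by frequency."""
    eps = ctx.efficiency(model)
    out = np.empty(len(f), dtype=np.int64)
    uniq, inv = np.unique(f, return_inverse=True)
    from .noise import _m_grid, _negbin_log_pmf

    for k, fk in enumerate(uniq):
        sel = np.flatnonzero(inv == k)
        mbar = fk * model.M
        m, w = _m_grid(mbar, model.a, model.gamma)
        pm = np.exp(_negbin_log_pmf(m, mbar, model.a, model.gamma)) * w
        weights = pm * (-np.expm1(-m * eps))  # P(m) P(n>0 | m)
        total = weights.sum()
        if total <= 0.0:
            out[sel] = 1  # P(n>0) underflow: the truncated law degenerates to n=1
            continue
        idx = rng.choice(len(m), size=len(sel), p=weights / total)
        out[sel] = _zt_poisson(m[idx] * eps, rng)
    return out


# ---------------------------------------------------------------------------
# null-model sampling (quadrant-conditioned, observed clones only)


def sample_null_pair(config: SimulationConfig, rng: np.random.Generator | None = None) -> PairTable:
    """Replicate pair under the null model via quadrant-conditioned sampling.

    Only the ``N_obs = round(N (1 - P(0,0)))`` observed clones are
    instantiated.  Quadrant weights and the quadrant-conditioned frequency
    posteriors are computed analytically on the log-frequency grid; counts
    are drawn from the zero-truncated conditionals.
    """
    if config.expansion is not None:
        raise ValueError("null sampling takes a config without an expansion prior")
    rng = _rng(config, rng)
    prior = config.prior()
    model = config.model()
    ctx1, ctx2 = config.contexts()
    grid = FrequencyGrid(prior, config.grid_points)
    p0 = zero_count_probability(model, ctx1, grid.f)
    p0p = zero_count_probability(model, ctx2, grid.f)

    w = grid.rho_w
    p00 = float(w @ (p0 * p0p))
    denom = 1.0 - p00
    # quadrant weights P(q | observed)
    w_x0 = w * (1.0 - p0) * p0p / denom
    w_0x = w * p0 * (1.0 - p0p) / denom
    w_xx = w * (1.0 - p0) * (1.0 - p0p) / denom
    q_probs = np.array([w_x0.sum(), w_0x.sum(), w_xx.sum()])
    n_obs = int(round(config.N * denom))
    counts_q = rng.multinomial(n_obs, q_probs / q_probs.sum())

    rows_n, rows_np = [], []
    for q, (w_q, size) in enumerate(zip((w_x0, w_0x, w_xx), counts_q)):
        if size == 0:
            continue
        idx = rng.choice(len(grid.f), size=size, p=w_q / w_q.sum())
        f_q = grid.f[idx]
        if q == 0:  # seen in replicate 1 only
            n = zero_truncated_count(f_q, model, ctx1, rng)
            np_ = np.zeros(size, dtype=np.int64)
        elif q == 1:  # seen in replicate 2 only
            n = np.zeros(size, dtype=np.int64)
            np_ = zero_truncated_count(f_q, model, ctx2, rng)
        else:  # seen in both
            n = zero_truncated_count(f_q, model, ctx1, rng)
            np_ = zero_truncated_count(f_q, model, ctx2, rng)
        rows_n.append(n)
        rows_np.append(np_)
    n = np.concatenate(rows_n)
    np_ = np.concatenate(rows_np)
    return PairTable.from_counts(n, np_)


def sample_null_pair_rejection(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> PairTable:
    """Reference null sampler: draw all ``N`` clones, discard ``(0, 0)`` rows.

    Exact but memory- and time-proportional to ``N``; used to validate the
    quadrant-conditioned scheme on small configurations.
    """
    if config.expansion is not None:
        raise ValueError("null sampling takes a config without an expansion prior")
    rng = _rng(config, rng)
    prior = config.prior()
    model = config.model()
    ctx1, ctx2 = config.contexts()
    f = prior.sample(config.N, rng)
    n = sample_counts(f, model, ctx1, rng)
    np_ = sample_counts(f, model, ctx2, rng)
    keep = n + np_ > 0
    return PairTable.from_counts(n[keep], np_[keep])


# ---------------------------------------------------------------------------
# expansion sampling (full repertoire, two time points)

_CHUNK = 2_000_000


def _draw_frequencies_to_one(prior: CloneSizePrior, rng: np.random.Generator) -> np.ndarray:
    """Draw power-law frequencies until just before their sum passes 1, then
    append the remainder so the sum is exactly 1."""
    chunks = []
    total = 0.0
    while True:
        f = prior.sample(_CHUNK, rng)
        cum = total + np.cumsum(f)
        stop = np.searchsorted(cum, 1.0)
        if stop < len(f):
            chunks.append(f[:stop])
            total = cum[stop - 1] if stop > 0 else total
            break
        chunks.append(f)
        total = cum[-1]
    freqs = np.concatenate(chunks)
    remainder = 1.0 - freqs.sum()
    if remainder > 0.0:
        freqs = np.append(freqs, remainder)
    return freqs


def _expansion_chunks(prior, expansion, freq_seed, s_seed):
    """Yield (f, s) chunks of the full repertoire, stopping at total
    frequency exactly 1.  Deterministic given the two seed sequences, so the
    stream can be replayed in a second pass without storing the repertoire."""
    gf = np.random.default_rng(freq_seed)
    gs = np.random.default_rng(s_seed)
    total = 0.0
    while True:
        f = prior.sample(_CHUNK, gf)
        cum = total + np.cumsum(f)
        stop = int(np.searchsorted(cum, 1.0))
        if stop < len(f):
            f = f[:stop]
            remainder = 1.0 - (cum[stop - 1] if stop > 0 else total)
            if remainder > 0.0:
                f = np.append(f, remainder)
            yield f, _draw_fold_changes(expansion, len(f), gs)
            return
        total = cum[-1]
        yield f, _draw_fold_changes(expansion, len(f), gs)


def _draw_fold_changes(
    expansion: ExpansionPrior, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``s`` from the mixture prior (shift handled by renormalization)."""
    responding = rng.random(size) < expansion.alpha
    s = np.zeros(size)
    k = int(responding.sum())
    if k:
        fam, sb = expansion.family, expansion.sbar
        if fam == "asym_exp":
            s[responding] = rng.exponential(sb, k)
        elif fam == "sym_exp":
            s[responding] = rng.laplace(0.0, sb, k)
        elif fam == "gauss_centered":
            s[responding] = rng.normal(0.0, sb, k)
        elif fam == "gauss_offcentered":
            s[responding] = rng.normal(expansion.s1, sb, k)
    return s


def sample_expansion_pair(
    config: SimulationConfig, rng: np.random.Generator | None = None
):
    """Two-time-point table plus ground truth under the expansion model.

    Returns ``(PairTable, truth)`` where ``truth`` is a DataFrame with the
    initial and final frequencies, the sampled and the realized (post-
    normalization) log fold-changes, and the responding flag for every
    observed clone.
    """
    if config.expansion is None:
        raise ValueError("expansion sampling requires an expansion prior in the config")
    rng = _rng(config, rng)
    prior = config.prior()
    model = config.model()
    ctx1, ctx2 = config.contexts()

    # the repertoire is streamed in chunks and never stored: pass 1
    # accumulates the growth normalization, pass 2 replays the identical
    # stream, normalizes, draws counts and keeps only observed clones
    root = np.random.SeedSequence(int(rng.integers(2**31)))
    freq_seed, s_seed, count_seed = root.spawn(3)
    growth_sum = 0.0
    for f, s in _expansion_chunks(prior, config.expansion, freq_seed, s_seed):
        growth_sum += float(np.sum(f * np.exp(s)))

    g_counts = np.random.default_rng(count_seed)
    rows = []
    offset = 0
    for f, s in _expansion_chunks(prior, config.expansion, freq_seed, s_seed):
        f_prime = f * np.exp(s) / growth_sum
        n = sample_counts(f, model, ctx1, g_counts)
        np_ = sample_counts(f_prime, model, ctx2, g_counts)
        keep = n + np_ > 0
        idx = np.flatnonzero(keep) + offset
        offset += len(f)
        rows.append(
            pd.DataFrame(
                {
                    "clone_id": [f"clone{i}" for i in idx],
                    "n": n[keep],
                    "n_prime": np_[keep],
                    "f": f[keep],
                    "f_prime": f_prime[keep],
                    "s_sampled": s[keep],
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    ids = df["clone_id"].to_numpy(object)
    table = PairTable(ids, df["n"].to_numpy(), df["n_prime"].to_numpy())
    truth = pd.DataFrame(
        {
            "clone_id": ids,
            "f": df["f"].to_numpy(),
            "f_prime": df["f_prime"].to_numpy(),
            "s_sampled": df["s_sampled"].to_numpy(),
            "s_realized": np.log(df["f_prime"].to_numpy() / df["f"].to_numpy()),
            "responding": df["s_sampled"].to_numpy() != 0.0,
        }
    )
    return table, truth
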