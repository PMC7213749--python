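import pytest

from clonexp.expansion import ExpansionKernel, ExpansionPrior
from clonexp.null_inference import fit_null
from clonexp.simulate import (
    SimulationConfig,
    sample_expansion_pair,
    sample_null_pair,
)


@pytest.fixture(scope="session")
def expansion_dataset():
    """Mouse-sized two-time-point dataset with 5% responders (sym-exp, sbar=1).

    Returns (config, table, truth, null_components, kernel); the kernel is
    shared across tests because it is independent of the expansion prior.
    """
    cfg = SimulationConfig.mouse(
        noise="poisson", expansion=ExpansionPrior("sym_exp", 0.05, 1.0), seed=3
    )
    table, truth = sample_expansion_pair(cfg)
    null = (cfg.prior(), cfg.model(), *cfg.contexts())
    kernel = ExpansionKernel(table, cfg.prior(), cfg.model(), *cfg.contexts(), grid_points=800)
    return cfg, table, truth, null, kernel


@pytest.fixture(scope="session")
def poisson_null_fit():
    """Poisson null fit (with Hessian errors) on a 1e5-clone replicate pair."""
    cfg = SimulationConfig(
        N=10**5, nu=2.0, noise="poisson", n_reads_1=5e4, n_reads_2=5e4, seed=7
    )
    table = sample_null_pair(cfg)
    ctx1, ctx2 = cfg.contexts()
    fit = fit_null(table, kind="poisson", grid_points=300, ctx=ctx1, ctx_prime=ctx2)
    return cfg, table, fit
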