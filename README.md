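# clonexp

Bayesian inference of clonal dynamics from immune-repertoire sequencing
count tables.

## The problem

High-throughput T-cell receptor sequencing (RepSeq) reports, per clonotype,
a unique-molecule count `n` in each sample. Comparing counts across time
points — say before and after a vaccination — is confounded by sampling,
library-preparation and expression noise: a clone whose reads triple may
simply have been unlucky the first day. `clonexp` disentangles true clonal
expansion from this measurement noise for researchers analysing
longitudinal repertoire data (or any paired clonotype count tables).

The method works in two inference steps and a prediction step:

1. **Null model from replicates.** Two same-day replicates share the latent
   clone frequencies `f`, so their count pairs `(n, n')` calibrate both the
   clone-size distribution and the noise. The clone-size prior is a power
   law, `rho(f) = C f^-nu` on `[f_min, 1)`, and the noise `P(n|f)` is
   Poisson, negative binomial (mean `fN_read`, variance
   `nbar + a*nbar^gamma`), or a two-step model through the latent number of
   cells in the sample. Parameters maximize the likelihood of observed
   pairs conditioned on `n + n' > 0`, with the repertoire-normalization
   constraint `N<f> = 1` pinning `f_min`. Error bars come from the Hessian
   projected onto the constraint surface; the fitted prior also yields Hill
   diversities `D_beta = (N<f^beta>)^(1/(1-beta))` (species richness,
   Shannon, Simpson) for the whole repertoire, observed or not.

2. **Expansion prior from two time points.** Between time points each clone
   carries a latent log fold-change `s = ln(f'/f)` distributed as
   `rho_s(s) = (1-alpha) delta(s - s0) + alpha rho_exp(s - s0)`: a fraction
   `alpha` of clones respond with typical effect size `sbar`, everything
   else contracts slightly by the shift `s0`, solved at every step from the
   equal-repertoire-size condition `Z' = Z`. `(alpha, sbar)` are fitted by
   empirical-Bayes maximum likelihood (grid search plus refinement; an EM
   update is available for the symmetric-exponential family).

3. **Per-clone posteriors.** Bayes' rule gives `rho(s | n, n')` per count
   pair; a clone is called expanded when the posterior probability of not
   expanding, `P_null = P(s <= 0 | n, n')`, is below 0.025. Posterior mean
   and median fold-changes replace the noisy naive estimate `ln(n'/n)`.

A synthetic-data module generates count tables under both models — including
a quadrant-conditioned sampler that never instantiates the vast unobserved
part of the repertoire — so the whole pipeline validates end to end.

## Worked example

Simulate a mouse-sized repertoire (1e6 clones, 1e4 reads per sample) in
which 1% of clones expand with typical log fold-change 1, then re-infer the
expansion prior and call responding clones:

```python
import numpy as np
from clonexp import (
    ExpansionPrior, SimulationConfig, detect_responding,
    fit_expansion, sample_expansion_pair,
)

cfg = SimulationConfig.mouse(
    noise="poisson", expansion=ExpansionPrior("asym_exp", 0.01, 1.0), seed=2,
)
table, truth = sample_expansion_pair(cfg)
print(table)

null = (cfg.prior(), cfg.model(), *cfg.contexts())
fit = fit_expansion(table, null, family="asym_exp", grid_points=800)
print(f"alpha={fit.prior.alpha:.4f} sbar={fit.prior.sbar:.3f} s0={fit.prior.s0:.4f}")

calls = detect_responding(table, null, fit.prior, kernel=fit.kernel)
print(calls.call.value_counts().to_dict())
```

Output:

```
PairTable(n_obs=9904, n_reads=(9967, 9951), unique_pairs=168)
alpha=0.0087 sbar=1.087 s0=-0.1229
{'unresolved': 9896, 'expanded': 8}
```

Of 9,904 observed clones the fit recovers the generating parameters
(`alpha` 0.0087 vs 0.01, `sbar` 1.087 vs 1.0) with the small negative shift
`s0` that balances the responders' growth, and 8 clones clear the
`P_null < 0.025` bar — few, because at 1e4 reads most responders are seen at
counts too low to distinguish from noise.

The same pipeline is available from the shell:

```bash
clonexp simulate --preset mouse --model P --alpha 0.01 --sbar 1.0 --seed 2 --out pair.tsv
clonexp infer-null pair.tsv --model P --out nullfit
clonexp infer-expansion pair.tsv --null-params nullfit.config.txt --out expfit
clonexp detect pair.tsv --null-params nullfit.config.txt --exp-params expfit.config.txt --out calls.tsv
```

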