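# Methods

This note records the models implemented in `clonexp`, their assumptions,
the numerical choices behind the implementation, and what the synthetic
validation does and does not establish.

## The generative model

**Clone sizes.** The frequency of a clonotype — the fraction of the
organism's T cells that carry it — is drawn from a power law,
`rho(f) = C f^-nu` on `[f_min, 1)`, with exponent `nu > 1` (dimensionless;
values near 2 are typical of human and mouse repertoires) and a lower
cutoff `f_min` regularizing the small-`f` divergence. Frequencies of
different clones are treated as independent; the constraint that they sum
to one is imposed on average through `N <f> = 1`, where `N` is the total
number of clones in the organism. Given `(nu, N)` this equation has a
unique root in `f_min`, so `f_min` is never a free parameter in practice.
The heavy tail matters: at `nu = 2` the identity `N f_min ln(1/f_min) = 1`
puts the *expected* largest clone near `1/ln(1/f_min)`, a few percent of
the whole repertoire, and single realizations can carry a clone holding
tens of percent. Several design decisions below exist because of this.

**Measurement noise.** A sequencing sample turns a frequency into a
unique-molecule count `n` through one of three conditional laws:

* `poisson` — `n ~ Poisson(f N_read)`; pure sampling noise, no parameters.
* `negbin` — negative binomial with mean `nbar = f N_read` and variance
  `nbar + a nbar^gamma`; `a >= 0` (dimensionless) and `gamma` (typically
  1–1.3) describe over-dispersion from expression and library-preparation
  noise; `a = 0` recovers Poisson.
* `negbin_poisson` — the cell count in the sample is
  `m ~ NB(mean = f M, variance = mbar + a mbar^gamma)` with `M` the
  effective number of cells, and the reads are `n ~ Poisson(m eps)` with
  sequencing efficiency `eps = N_read / M` (UMIs per cell). Law of total
  variance gives `Var(n) = nbar (1 + eps) + eps^2 a (f M)^gamma`: even at
  `a = 0` the compound law is over-dispersed (it is a Neyman Type-A
  mixture, *not* a thinned Poisson — thinning would require a binomial
  read-out, which is not the model).

**Dynamics.** Between two time points a clone's frequency moves by a log
fold-change `s = ln(f'/f)` with prior
`rho_s(s) = (1 - alpha) delta(s - s0) + alpha rho_exp(s - s0)`. `alpha` is
the responding fraction; `rho_exp` is one of four families — one-sided
exponential (`asym_exp`, scale `sbar`), symmetric exponential (Laplace),
centered Gaussian, or strictly off-centered Gaussian (offset `s1 >= 0.1`,
the constraint that makes it a genuinely different hypothesis from the
centered one). The global shift `s0 <= 0` contracts all non-responders so
total frequency is conserved; it is not free but solved from the
equal-budget condition `Z' = Z` (see below). Expansion is assumed
independent of clone size.

## Inference

**Null fit.** From a same-day replicate pair the likelihood of each count
pair marginalizes the shared frequency,
`P(n, n') = ∫ rho(f) P(n|f) P(n'|f) df`, and the data likelihood conditions
on observation (`n + n' > 0`) by dividing by `1 - P(0,0)`. The optimizer
works on `(nu, a, gamma, log10 M)` (subset per noise kind) with `f_min`
eliminated at every evaluation by root-finding the constraint; a coarse
grid seeds Nelder–Mead. `M` and `f_min` live on log10 scales, the rest on
linear scales. The realized-normalization alternative (`Z = 1` for the
particular dataset, with `N = N_obs / (1 - P(0,0))` and posterior-mean
frequencies summed over observed clones plus the unseen extrapolation) is
available behind `normalization="realized"`; at desk scale it is noisy
because `Z` itself fluctuates with the heavy tail (see Limitations).

**Error bars.** The covariance at the constrained optimum is the
pseudo-inverse of the log-likelihood Hessian projected onto the hyperplane
tangent to the constraint (`H_hat = H - PH - HP + PHP`, `P` the rank-one
projector on the constraint normal). The Hessian is central
finite-differenced with step 1e-3 on each parameter's scale, on the same
frequency grid the optimum was found on (mixing grids injects spurious
curvature). Eigendirections of `-H_hat` with non-positive curvature —
finite-difference noise on a flat ridge — are assigned large
(`1/|lambda|`) rather than zero variance: a flat direction means ignorance,
not certainty. Diversity uncertainties are propagated by >= 1000 draws from
the Gaussian approximation, rejecting draws with invalid parameters, and
summarizing the spread of `ln D_beta`.

**Expansion fit.** The two-time-point likelihood
`P_exp(n, n') = ∫ df rho(f) ∫ ds rho_s(s) P(n|f) P(n'|f e^s)` factorizes
through the kernel `L_i(s) = ∫ rho(f) P(n_i|f) P(n_i'|f e^s) df`, which is
independent of the expansion prior. The kernel is tabulated once per
dataset over the `s` grid and every candidate `(alpha, sbar)` is evaluated
by reweighting — this is what makes grid search plus refinement cheap. The
shift solves `Z'(s0) = Z` in closed form, `s0 = -ln(Z'_0 / Z)`, using the
identity that shifting all `s` by `s0` scales every term of `Z'` by
`e^{s0}`; it is re-solved inside every objective evaluation, so the
reported 2x2 covariance in `(ln alpha, ln sbar)` treats `s0` as an implicit
function of the free parameters. The likelihood surface carries a diagonal
ridge: the product `alpha * sbar` is well identified, the factors are not,
and single-realization estimates wander along the ridge while their
ensemble mean sits near the truth.

**EM for the symmetric-exponential scale.** For `rho_exp` symmetric
exponential with `s0 = 0` the M-step is analytic: the updated scale is the
per-clone average posterior mean `|s|`. The EM path deliberately uses the
raw discretized prior weights (no grid renormalization): then the analytic
M-step is exact for the discretized objective and ascent is monotone node
for node; with renormalized weights the update would chase a slightly
different objective through `d ln Z_grid / d sbar`.

**Posteriors and calls.** `rho(s|n,n')` is a delta atom at `s0` plus a
continuous density on the grid; the atom is never binned, the CDF carries
an explicit jump, and the median handles the atom plateau. A clone is
*expanded* when `P(s <= 0 | n, n') < 0.025` (the atom counts as
non-expanding whenever `s0 <= 0`). For *contraction* the reference point is
`s0`, not 0: the criterion is `atom + P(s >= s0) < threshold`. Using 0
would mislabel every atom-dominated clone as contracted whenever the
fitted `s0` is slightly negative, which it always is when anything
expanded. Ties at the threshold are not significant.

## Numerics

* **Frequency integrals** use a log-spaced grid over `[f_min, 1]` with
  Simpson weights in `ln f`, renormalized so the discrete measure sums to
  exactly one. Defaults: 800 points for simulation and standalone
  likelihoods, 400–500 for iterated fitting, 500–1000 for expansion
  kernels. Null-model fits on heavy-tailed data want >= 500 points: at 250
  the under-resolved likelihood peaks of the largest-count pairs bias `nu`
  upward by about +0.004 (measured against a 500–1000-point reference).
* **The `s` grid** spans [-15, 15] at step 0.1 (the method's effective
  discretization; posteriors and `P_null` move by < 1e-3 under refinement
  to 0.05). The continuous prior component is renormalized to mass `alpha`
  on the grid, so the mixture stays proper even for scales comparable to
  the range. Trapezoid integration through the prior's kink makes single
  pair likelihoods accurate to ~1e-3 relative at step 0.1 and ~1e-5 at
  0.01, verified against piecewise adaptive quadrature.
* **Two-step marginalization** over the cell count uses exact integer
  summation when `mbar + 25 sigma + 25 <= 600` (the wide span covers the
  sub-Gaussian-slow NB tail at small `r`), and otherwise a per-frequency
  local linear grid of 129 points spanning `mbar +- 12 sigma`, where the
  NB is Gaussian-like. A shared log-spaced grid is *not* usable: at
  `mbar ~ 1e5` its spacing exceeds both the NB width and the Poisson
  read-out kernel and visibly corrupts big-clone likelihoods. `P(0|f)`
  bypasses the marginalization entirely via the NB probability generating
  function at `e^{-eps}`.
* **Zero-truncated sampling** uses inverse-CDF draws above `P(0|f)`; for
  the two-step model the latent `m` is drawn from `P(m|f) P(n>0|m)` and the
  count from a zero-truncated Poisson. Likelihood evaluations and samplers
  work per unique count value / grid node, never per clone.
* **Degenerate inputs**: fits raise `FitError` when the optimizer pins a
  parameter to its sanity box (flat likelihood, e.g. a table of identical
  large counts), when no `f_min` root exists, or when `P(0,0) ~ 1`.

## What the synthetic data emulates — and what it does not

The generators implement the study conditions used throughout the tests:
mouse-sized repertoires (`N = 1e6` clones, 1e4 reads/sample) and scaled
analogues (`N = 1e5`, 5e4 reads) with `nu = 2` and `f_min` from the mean
constraint. The null sampler is quadrant-conditioned — only the
`N(1 - P(0,0))` observed clones are instantiated, with analytic quadrant
weights and inverse-CDF frequency draws on the grid — and agrees with naive
all-`N` rejection sampling in distribution. The expansion sampler draws
frequencies until they sum exactly to one, applies sampled fold-changes,
renormalizes empirically, and discards doubly-unseen clones (`N_obs`
stochastic here, fixed in the null sampler).

Two caveats delimit what passing tests show about real data. First,
synthetic-validation fits are given the generator's *nominal* read totals
(`eps * M`); real-data fits can only use the observed column sums. At
`nu ~ 2` a single giant clone can inflate the realized total by tens of
percent, and because the mean constraint pins the frequency scale, fitting
with the inflated total tilts `nu` by many standard errors (measured:
ensemble sd of `nu_hat` 0.058 with realized totals vs 0.0016 with nominal
ones, against a Fisher SE of ~0.002). Real analyses at much deeper
sequencing are less exposed, but the package cannot remove this
realization noise. Second, the generators share the model family with the
fitters; recovery tests establish the correctness of the inference
machinery, not the adequacy of power-law-plus-NB assumptions for any
particular protocol. Sequence-level artifacts (CDR3-dependent primer bias,
PCR branching) are outside the model entirely.

## Known limitations

* Realized normalization (`Z`) and realized read totals fluctuate strongly
  for `nu <= ~2.3` (infinite frequency variance); `Z ~ 1` self-consistency
  is only a sharp statement in lighter-tailed regimes.
* The two-step quadrature caps its local grid at 129 points; for strongly
  over-dispersed settings with `gamma` near 2 and very large clones the
  Poisson kernel can under-resolve. The regimes exercised here
  (`gamma <= ~1.3`) are well inside the accurate domain.
* Fisher error bars understate single-realization scatter whenever a
  handful of giant clones dominates the information (heavy-tail
  non-regularity); the recovery tests therefore run under the nominal-total
  convention above.
* Expansion fits report ridge-shaped uncertainty; `alpha` alone should not
  be quoted without `sbar` (or their product) at desk-scale read depths.
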