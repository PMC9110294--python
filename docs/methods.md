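# Methods

## Models

**Reaction network.** Two species, mRNA (`x1`) and GFP (`x2`), three
first-order reactions with mass-action propensities `theta1*x1` (mRNA
degradation), `theta2*x1` (translation), `theta3*x2` (GFP degradation);
all rates in 1/h.  The state is `(0, 0)` before the release time `t0` and
`(m0, 0)` at `t0`.  The reference stochastic description is the Markov
jump process, simulated exactly with Gillespie's direct method; there is
no closed-form solution of the corresponding master equation, which is
what motivates the two state-continuous approximations below.

**ODE model.**  The reaction-rate equations admit the closed form

    x1(t) = m0 exp(-theta1 (t - t0))
    x2(t) = theta2 m0 / (theta3 - theta1) * (e^{-theta1 (t-t0)} - e^{-theta3 (t-t0)})

with the limit `theta2 m0 (t-t0) e^{-theta3 (t-t0)}` when
`theta1 = theta3`.  The limit branch is selected when
`|theta1 - theta3| < 1e-8`; at a separation of `1e-6` the two branches
agree to better than `1e-4` relative error (tested).  `x2` is symmetric
under `theta1 <-> theta3`, and the observed signal depends on
`(theta2, m0, scale)` only through their product — the two structural
degeneracies of the deterministic model.

**SDE model.**  The chemical Langevin equation has the same drift and the
diagonal diffusion `(sqrt(theta1 x1), sqrt(theta2 x1 + theta3 x2))`.
Paths are simulated with Euler–Maruyama at `dt = 0.01 h` by default.  The
scheme does not define behaviour at the boundary, so diffusion arguments
are clamped at 0 and states floored at 0 after each step (simple
truncation).  This choice preserves the absorbing origin; reflection
would be an alternative but changes the boundary law, and the boundary is
rarely visited in the regimes studied.

**Observation model.**  `y_k = (scale * x2(t_k) + offset) * eps_k` with
iid `eps_k ~ logNormal(0, sigma^2)` on the grid `t_k = (k-1)/6 h`,
`k = 1..181` (one frame every 10 minutes over 30 h; the window is assumed
to start at 0).  Jump paths are read out by right-continuous step
interpolation, diffusion paths linearly.

**Moment surrogate.**  For the transformed process
`z = (x1/m0, scale*x2 + offset)` the first and second moments obey a
closed five-equation linear ODE system (`M10, M01, M20, M02, M11`),
integrated with LSODA at rtol 1e-8 / atol 1e-10 from
`M(t0) = (1, offset, 1, offset^2, offset)`.  `M10`/`M01` coincide with
the transformed deterministic solution (tested to integrator tolerance);
`M02 - M01^2` is the signal variance against which Euler–Maruyama
ensembles are validated.  Differential-algebra analysis of this
surrogate is out of scope; the system is hard-coded for this network.

**Quadratic variation.**  The sum of squared successive increments of the
noise-free signal `scale*x2 + offset` summarizes within-trajectory
variability.  It separates parameter regimes that share an identical
deterministic signal (fixed `scale*theta2*m0`, or swapped
`theta1 <-> theta3`), which is the simulation-based argument for why the
SDE model can identify what the ODE model cannot.

## Posteriors

Priors (deliberately diffuse): `theta_i ~ N(0, 5^2)` truncated at 0,
`m0 ~ N(300, 300^2)` truncated at 0, `scale ~ U(0, 30)`, and where
sampled `offset ~ U(0, 30)`, `sigma ~ U(0.001, 10)`, `t0 ~ U(0, 30)`.

**ODE posterior** (8 parameters).  With `k* = min{k : t_k >= t0}`,
observations at `k >= k*` are lognormal around the closed-form signal and
earlier ones around `offset`; `sigma` and `offset` are always sampled for
the ODE model (on noise-free data `sigma` absorbs the jump-process
deviations from the smooth curve, so its posterior sits above 0).  The
posterior is exactly symmetric under the rate swap when the two rate
priors are equal (asserted at random points), hence bimodal.

**SDE posterior** (latent-path data augmentation).  `t0` is fixed
beforehand at the ODE posterior mean (two-stage protocol); sampling a
regime-switching time jointly with a latent diffusion path is out of
scope.  Transition densities between consecutive frames are single
Euler–Maruyama steps: two independent normals with mean `state + drift*dt`
and variance `diffusion^2*dt`.  The 10-minute frame spacing doubles as
the inference discretization (finer imputation sub-steps were not
needed; model-consistent simulations are refit without bias, see below).
The initial factor is one EM step of length `t_{k*} - t0` from `(m0, 0)`;
if a frame falls exactly on `t0` the state there is a point mass at
`(m0, 0)` and the latent path starts one frame later.  Pre-release states
are structurally zero and never represented.

*Noise-free variant* (`sigma`, `offset` excluded): the observation
equation is exact, so `offset` is read off the first (pre-release) frame
and the GFP path is the deterministic data transform
`x2(t_k) = (y_k - offset)/scale`.  Only the mRNA path remains latent, and
the change of variables from `x2`- to `y`-space contributes `-log(scale)`
per collapsed observation.  This is the exact marginalization of the
delta observation model, not an approximation.

*With-noise variant*: both state components are latent, lognormal
observation terms apply at every frame, and `offset`/`sigma` are sampled.

**Parameterization.**  All positive parameters and latent states are
sampled on log scale, interval-supported parameters via scaled logit —
mirroring how constrained sampling is conventionally implemented.  The
latent states are sampled *centered* (log states directly) rather than as
standardized increments: the collapsed noise-free target has no
non-centered form for the GFP component, and the data constrain the path
strongly enough that the centered form mixes adequately.

## Sampling engine

A self-contained No-U-Turn sampler: leapfrog with diagonal mass matrix,
slice-variant tree doubling, divergence declared at an energy error of
1000, dual-averaging step-size adaptation (target acceptance 0.8), and
Stan-style expanding-window estimation of the diagonal metric during
warmup (initial 15% step-size-only buffer, doubling windows from 25
draws, terminal 10% buffer; the last window absorbs remainders so the
metric is never estimated from a handful of draws).  Gradients are
analytic for both targets; the hot paths are numba-compiled and verified
against pure-numpy reference implementations (to ~1e-12) and against
finite differences.  Chains are seeded independently from one
`SeedSequence`; identical configuration and data reproduce draws exactly.

Chain initialization is data-informed and jittered: `offset` near the
first frame, `t0` near the first sustained signal upswing, rates
log-uniform over a broad plausible range, latent mRNA path from the
decaying exponential implied by the initial draw.

The reference profile mirrors the study design (8 chains × 5000
iterations, first half discarded → 20 000 kept draws).  Tests and the
pipeline default to reduced profiles (2–8 chains × 600–1600 iterations,
tree depth capped at 8–10); these are Monte-Carlo-noisier but leave the
posterior location unchanged, which is what the recovery and coverage
assertions use.

**Validation of the inference machinery.**  (i) Both gradients match
finite differences at random points.  (ii) The NUTS engine recovers a
correlated Gaussian with known moments.  (iii) On a down-sampled
trajectory the NUTS posterior matches an independent affine-invariant
ensemble sampler run on the same density.  (iv) Refitting data simulated
exactly from the EM-transition model recovers every parameter (95% CIs
cover the truth, `theta2*m0*scale` posterior median within 1% of the true
138.24) — so residual discrepancies on jump-process data reflect the
jump-vs-diffusion approximation and single-trajectory randomness, not the
implementation.

## Identifiability metrics

95% credible intervals are percentile intervals (2.5%–97.5% quantiles,
linear interpolation between order statistics) — deliberately one wide
interval under bimodality.  Coverage counts a boundary hit as covered
(measure-zero rule).  The c.v. is sample sd (n−1) over sample mean.
R-hat is the classic split-chain variant and ESS the matching
autocorrelation-based (mean) estimator — the variants whose values the
reference summary tables print (split R-hat far above 2 flags the
chain-per-mode behaviour of the bimodal ODE posterior, which
rank-normalized R-hat would cap near 1.7); constant chains report R-hat 1
and ESS equal to the draw count.  Prior baselines are analytic central
95% interval lengths (11.05 for the rate priors, 884.82 for `m0`, 28.50
for `scale`, 9.50 for `sigma`), by seeded Monte Carlo (n = 10^6) for
derived products.  Replicate studies aggregate per-trajectory summaries
into median CI length, c.v. of lengths, median truth-rescaled length and
coverage counts, per parameter and model type.

## Synthetic-data generator: scope and defaults

The generator *is* the study design: exact jump-process trajectories with
`theta = (0.2, 0.32, 0.01)`, `m0 = 240`, `t0 = 0.96 h`, `scale = 1.8`,
`offset = 6.5`, observed at 181 equidistant frames over 30 h, with
multiplicative noise `sigma = 0.02` when enabled.  (The source material
states the offset inconsistently — 8.5 in the narrative, 6.50 throughout
the summary tables; 6.5 is the default here and the value is
configurable.)  Replicates use `base_seed + index`.  What it does *not*
emulate about real experiments: lipoplex uptake and multi-release events,
GFP maturation, enzymatic/ribosomal saturation, photobleaching, cell
division or segmentation artifacts, and cell-to-cell parameter
variability.  Passing tests therefore demonstrate correctness of the
method under the stated generative model, not robustness to those
effects.

## Problem sizes used in the shipped tests

Single-trajectory recovery runs 6 chains × 800 iterations (ODE); the
replicate study runs 8 trajectories × (2 × 600 ODE + 2 × 800 SDE)
iterations.  At these sizes the coverage contrast between model types
(e.g. `theta2*m0*scale` covered by most SDE fits and few ODE fits) is
directional, as are the majority-vote recovery checks; the full-scale
design (100 trajectories × 20 000 draws) sharpens the counts but does not
change their ordering.  Because ~90% of single trajectories reproduce
the headline recovery pattern, those checks are asserted as majorities
over replicates rather than on a single arbitrary realization.

## Known limitations

* The EM transition density at 10-minute steps is a first-order
  approximation of the jump process; estimates on jump-process data carry
  a small approximation bias (visible as `theta2*m0*scale` medians a few
  percent below the truth) that the credible intervals absorb.
* The noise-free SDE likelihood requires `y_k >= offset` after release;
  data violating this (possible only with measurement noise) belong to
  the with-noise variant.
* ODE-model chains each explore one of the two swap modes; between-chain
  mixing over modes is left to the multi-chain design, as in the
  reference protocol.
* No mixed-effects/multi-cell hierarchy, no particle MCMC, no joint
  sampling of `t0` for the SDE model.
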