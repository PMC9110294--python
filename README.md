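# mrnakinetics

Bayesian identifiability analysis for single-cell translation kinetics
after mRNA transfection: does replacing the deterministic (ODE) model of
a fluorescence trajectory with its chemical-Langevin (SDE) counterpart
make the kinetic parameters identifiable from a *single* cell?

## The problem

After transfection, `m0` mRNA copies are released into a cell at an
unknown time `t0` and drive the two-species reaction network

    X1 --theta1--> 0            (mRNA degradation)
    X1 --theta2--> X1 + X2      (translation)
    X2 --theta3--> 0            (GFP degradation)

Only a fluorescence signal `y_k = (scale * X2(t_k) + offset) * eps_k`,
`eps_k ~ logNormal(0, sigma^2)`, is observed every 10 minutes over ≥ 30 h.
For the reaction-rate ODE model the signal depends on `(theta2, m0,
scale)` only through their product and is symmetric in `theta1 <->
theta3`, so most parameters are structurally non-identifiable from one
trajectory.  The chemical Langevin equation

    dX = drift(X) dt + diag(sqrt(theta1 X1), sqrt(theta2 X1 + theta3 X2)) dB

breaks both degeneracies through the state-dependent noise: the
*within-trajectory* fluctuations carry information the mean cannot.

The package provides:

* `synthetic` — exact Gillespie simulation of the jump process and the
  noisy observation model (the ground-truth generator of the study);
* `models` — closed-form ODE solution, Euler–Maruyama simulation of the
  CLE, the moment-equation surrogate, quadratic-variation summaries;
* `targets` / `bayes` / `hmc` — the ODE posterior and the latent-path SDE
  posterior (Euler–Maruyama transition densities between frames, data
  augmentation over the latent states), sampled with a built-in NUTS
  engine;
* `identifiability` — percentile credible intervals, coverage, ESS/R-hat,
  prior-interval baselines, and aggregation over replicate trajectories;
* `pipeline` / `cli` — the two-stage protocol (fit ODE, fix `t0` at its
  posterior mean, fit SDE) and replicate studies, also as a command line
  tool (`mrnakinetics simulate | fit-ode | fit-sde | run-single |
  run-study | report`).

## Worked example

```python
import mrnakinetics as mk

# one noise-free benchmark trajectory: theta=(0.2, 0.32, 0.01), m0=240,
# t0=0.96 h, scale=1.8, offset=6.5, 181 frames over 30 h
kp, ep, obs = mk.benchmark_fixture(with_noise=False, seed=1)

ode = mk.fit(obs, mk.FitConfig(model="ode", n_chains=4, n_iter=800,
                               max_treedepth=8, seed=11))
t0_hat = mk.estimate_t0_from_ode(ode)
print(f"t0 = {t0_hat:.3f} h")            # t0 = 0.968 h   (truth 0.96)

sde = mk.fit(obs, mk.FitConfig(model="sde", n_chains=4, n_iter=800,
                               max_treedepth=9, seed=21, t0_fixed=t0_hat))
print(mk.summarize_fit(sde, truth={"theta1": 0.2, "theta2": 0.32,
                                   "theta3": 0.01, "m0": 240, "scale": 1.8}))
```

The ODE summary shows the signature non-identifiability: `theta1`/`theta3`
draws are bimodal across chains (here 95% CI ≈ (0.015, 0.165), missing
the truth on both sides of the swap), `sigma` is inflated to ≈ 0.013
although the data are noise-free, while `t0` (0.968 ± 0.002) and `offset`
(6.50) are pinned.  The SDE summary concentrates `theta1` and `theta3`
in single modes near the truth and identifies `scale` and `theta2*m0`
individually — the pattern that motivates the stochastic model.  Because
each run fits one random trajectory, point estimates move from
realization to realization; the replicate-study machinery
(`mk.run_study`) quantifies exactly this via coverage counts.

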