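# coopreset

Simulation and theory toolkit for **cooperative (self-organized) stochastic
resetting**: many Brownian particles in one dimension in which random *pairs*
are reset to their mutual midpoint at a distance-dependent rate. Unlike
extrinsic resetting — where the reset position and rate are imposed from
outside — both emerge here from the interactions, which lets a noisy system
constrain its fluctuations while still adapting to external forces.

The package is aimed at researchers in stochastic processes and biological
physics who want to reproduce, probe or extend this class of models: the
agent-based engine, the mean-field layer, the phase-transition and
first-passage observables, and two application models (genotype mixing in
multinucleate fungi, and vehicle dispersion in shared-mobility fleets).

## Model

`N` particles with positions `X_i` diffuse with constant `D` (optional drift
`v`). A pair at separation `δ = |X_i − X_j|` undergoes a resetting event —
both members jump to `(X_i + X_j)/2` — at a rate set by the interaction
kernel

```
μ(δ) = μ0 / (1 + (δ/δ0)^α)
```

with amplitude `μ0`, interaction length `δ0` and decay exponent `α`
(`α = 0` is the distance-independent limit). The control parameter is the
rescaled density `ϱ = 2N δ0² μ0 / D`; positions are naturally measured in
units of `δ0` (`χ = x/δ0`).

A mean-field flux-balance analysis of the stationary density `p_s(χ)` gives
the closed tail ODE `p_s′ = −√ϱ · χ^(−α/2) · p_s` for `χ > 0`, hence

* `α = 0` — exponential tails `p_s ~ exp(−√ϱ |χ|)`: localized at every density;
* `0 < α < 2` — stretched-exponential tails: still always localized;
* `α = 2` — power law `p_s ~ χ^(−√ϱ)`: a density-driven
  localization–delocalization transition (normalizable only for `√ϱ > 1`,
  refined analysis places the critical point near `√ϱ_c ≈ 2.3`);
* `α > 2` — no normalizable steady state: diffusion wins.

A general kernel admits localization only if `∫ δ μ(δ) dδ` diverges, i.e.
kernels decaying faster than `δ^(−2)` (including all exponential kernels)
cannot localize.

## Worked example

```python
import numpy as np
import coopreset as cr

n, diffusion, rho = 2000, 1.0, 21.0
kernel = cr.ResettingKernel(mu0=rho * diffusion / (2 * n), delta0=1.0, alpha=0.0)
params = cr.SimulationParams(n_particles=n, diffusion=diffusion,
                             dt=0.004, t_max=40.0, kernel=kernel, seed=11)
series = cr.simulate_cooperative(params, np.arange(0.5, 40.001, 0.5))

pooled = cr.pooled_centered_positions(series, burn_time=20.0)
fit = cr.fit_tail(pooled, "exponential")
law = cr.solve_tail(alpha=0.0, rho=rho)
print(f"fitted tail decay rate : {fit.sqrt_rho:.2f}")
print(f"flux-balance prediction: {law.sqrt_rho:.2f}")
```

prints

```
fitted tail decay rate : 4.45
flux-balance prediction: 4.58
```

— the ensemble localizes and its stationary tail decays at the predicted
rate `√ϱ = √21 ≈ 4.58` (the fit lands within 3%). Setting `α = 3` instead
produces no localization: `cr.dispersion_rate` on the same pipeline returns
a long-time variance slope near the free-diffusion value `2D`.

The `coopreset` command exposes the same machinery from the shell
(`simulate`, `theory`, `fungi`, `mobility` subcommands; YAML configs, CSV
outputs plus a JSON manifest per run), e.g.

```bash
coopreset theory --config theory.yaml --out out/   # tail law + verdict JSON
```

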