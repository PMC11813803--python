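# Methods

## Model and conventions

The engine simulates `N` particles on the line with diffusion constant `D`,
optional constant drift `v` (overdamped: a constant force enters only
through `v`), and pairwise midpoint resetting governed by the kernel
`μ(δ) = μ0 / (1 + (δ/δ0)^α)`. Free space, no boundaries; the default
initial condition is a point mass at `x0` (configurable, including explicit
initial positions).

**Pair-rate normalization.** The kernel formula is evaluated with the
convention `(δ/δ0)^0 ≡ 1`, so `ResettingKernel.rate` is the constant `μ0/2`
at `α = 0`. The event engine, however, counts each *ordered* pair as an
interaction channel at rate `μ`, giving a per-unordered-pair intensity
`ν(δ) = 2μ(δ)` for `α > 0`; the `α = 0` model is implemented as the
distance-independent process at full amplitude (`ν = 2μ0`). This
calibration is not a free choice: it is the unique normalization for which
the simulated stationary tails obey the flux-balance laws parameterized by
the rescaled density `ϱ = 2N δ0² μ0 / D` — we verify numerically that at
`α = 0, ϱ = 21` the fitted tail decay is `√ϱ` (≈ 4.58, measured ≈ 4.45)
and that the `α = 2` tail exponent is consistent with `√ϱ`. Halving the
pair intensity demonstrably halves the fitted `√ϱ`-scale and would
disconnect the engine from the theory layer. The same `ν` enters the
mean-field operator (below), so engine and PDE agree by construction.

**Event generation.** Operator splitting at fixed `dt`: an Euler–Maruyama
diffusion step (Gaussian increments of variance `2D·dt`), then Poisson
thinning of resetting events against the uniform envelope `2μ0` per pair:
the candidate count is Poisson with mean `2μ0 · N(N−1)/2 · dt`, each
candidate picks a uniformly random unordered pair and is accepted with
probability `ν(δ)/2μ0` evaluated at the pair's *current* positions;
accepted events apply sequentially in draw order. The scheme is exact as
`dt → 0`; a warning fires when the per-particle envelope
`2μ0 (N−1) dt` reaches 0.1 events per step, and all shipped experiments
stay below that bound. Extrinsic resetting uses per-particle Poisson resets
with per-step probability `1 − exp(−μ_ext dt)`.

**Mapping between schemes.** Where cooperative and extrinsic runs are
compared, the extrinsic rate is the matched `μ_ext = μ0 N` with the reset
position at `x0`. Note that with the calibration above the `α = 0`
cooperative tail decays at `√ϱ` whereas the extrinsic stationary law decays
at `√(μ_ext/D) = √(ϱ/2)`; the two schemes therefore agree in kind
(exponential localization) but not exactly in rate. The extrinsic arm keeps
its textbook normalization because its closed-form benchmarks (stationary
law, mean offset `v/μ_ext`, MFPT `(e^{l√(r/D)} − 1)/r`) are stated in it.

## Mean-field layer

With the closure `p₂(x, x′) = p(x)p(x′)`, the single-particle density obeys

```
∂t p = D ∂χχ p + (N−1) [ 2 ∫ du ν(2|u|) p(χ−u) p(χ+u)  −  p(χ) ∫ du ν(|u|) p(χ+u) ]
```

(gain places both partners at the pair midpoint; the substitution
`x₁ = χ−u, x₂ = χ+u` produces the factor 2). The `(N−1)` prefactor and the
use of `ν` are fixed by requiring the per-particle loss rate to match the
agent engine and probability to be conserved.

Numerics: uniform grid on `[−L, L]` with `L ≥ 10×` the expected stationary
spread; finite-volume no-flux Laplacian; the loss convolution is an
FFT-backed Toeplitz product and the bilinear gain a direct O(G²)
quadrature. The discrete gain is rescaled by the (O(h²)-close) ratio of the
loss and gain sums so the resetting operator conserves probability exactly
on the grid; the integrator renormalizes each step and aborts if the
logged drift exceeds 1e−6 per unit time or the density turns negative.
Explicit Euler with `dt ≤ h²/(2D)` (default a quarter of the bound).
Shipped runs use `G = 401`, `L = 4`, reaching the `ϱ = 21` steady state by
`t = 1.5` (the per-particle reset rate is ≈ ϱ per unit time, so relaxation
is fast).

The asymptotic tail ODE `p_s′ = −√ϱ χ^(−α/2) p_s` (the decaying branch for
`χ > 0`, symmetric by reflection) is exposed by `solve_tail` as an
evaluable `TailLaw` with exact inverse-CDF samplers. It is asymptotic only:
nothing is claimed near `χ = 0`, where the first-order `1/χ` expansion
behind it fails, and the `χ^(−α/2)` singularity is excluded from all
assertions.

## Observables

* **Dispersion rate (order parameter).** OLS slope of the ensemble variance
  over the trailing third of the series (the window fraction is a
  parameter; the long-time window is a design choice, and results are
  insensitive to it well away from the transition). CI by percentile
  bootstrap over snapshots, or over replicates in the density scan.
* **Tail fits.** Linear regression of the log empirical CCDF against the
  law's natural abscissa (`|χ|`, `|χ|^{1−α/2}`, or `log|χ|`), windowed by
  sample quantiles (default 0.90–0.999) because the finite-sample tail
  onset is not known a priori. Agent samples are pooled over
  post-burn-in snapshots and centered per snapshot to remove the
  center-of-mass diffusion of finite ensembles (variance `2Dt/N`), which
  the mean-field density does not contain.
* **Critical density.** Scan `√ϱ` on a grid at `α = 2`, compute the
  dispersion rate with a replicate-bootstrap CI per point, and interpolate
  the zero crossing between the largest density whose CI excludes zero and
  the smallest whose CI includes it.
* **First passage.** A marked particle (uniformly chosen per replicate)
  runs inside the full ensemble until its position first reaches
  `x0 + l`, detected at discrete steps with no bridge correction — `dt` is
  the accuracy knob, and the discretization bias (≈ `0.58 σ√dt` of target
  shift) is kept below the statistical tolerance in all shipped
  experiments. Replicates that reach the horizon are censored and excluded;
  the MFPT is only reported when censoring stays under 1%. The extrinsic
  arm exploits particle independence and simulates only the marked
  particle, vectorized across replicates. In the cooperative-vs-extrinsic
  comparison both arms share the same `dt` so the detection bias cancels in
  the ordering.

## Study conditions (problem sizes)

Chosen once as desk-scale analogues of the reference conditions:

* Localization runs: `N = 2000`, `D = 1`, `δ0 = 1`, `ϱ` set through `μ0`;
  `dt = 0.004–0.005`, horizon 40 (α = 0, relaxation rate ≈ ϱ) to 240
  (α = 2 scans, where relaxation is slow near the transition); snapshots
  every 0.5–2 time units, burn-in half the run.
* Brownian baseline: 1000 particles, 10⁴ steps, replicated 5× for an
  honest slope SE (the variance path is autocorrelated, so particle-group
  SEs understate run-to-run noise).
* `α = 3` delocalization: `ϱ = 8`, horizon 100. For strongly clustered
  starts at higher density a metastable cluster survives for a long time
  (all mass within `δ0` keeps resetting at full rate) and depresses the
  finite-time dispersion rate; the density is chosen so the cluster
  evaporates well inside the horizon, which is what the diffusion-dominated
  claim is about.
* First passage: `N = 200`, `l = 0.4`, ≥ 1000 replicates per density,
  density grid `ϱ ∈ {4, 10, 21, 32, 50, 80}` (extrinsic rates `ϱ/2`
  bracket the analytic optimum `r* ≈ 15.8`); oracle checks at
  `dt = 2.5e−5`.
* Fungi: 2000 colonies (without fusion colonies are independent, so this
  only sets the binomial resolution), spore size 20 (5 for the fixation
  benchmark), 7 division rounds, 25 generations.
* Mobility: 121×121 grid (large enough that 100 rounds of 10-street rides
  stay far from the boundary-saturated variance), 100 vehicles, biased-ride
  experiments over 400 rounds.

## Fungal generation cycle

Germination (one spore per colony) → growth by `2^7`-fold urn doublings —
each new nucleus copies a uniformly chosen existing one, so genotype
frequency is a martingale; the literal birth chain is exchangeable and its
added composition is exactly Dirichlet-multinomial, which the default
`exact` sampler draws in O(1) (the `sequential` sampler implements the
literal chain and the suite checks the two share a law) — → anastomosis
with probability `p` (pooled nuclei split hypergeometrically between the
two partners, conserving totals exactly; a deterministic-averaging switch
exists) → hypergeometric sporulation. Fusion happens after growth by
default (full colonies fuse); a config switch moves it right after
germination, which changes nothing qualitative. Reports (minor-genotype
fraction, fraction fixed, heterozygosity `1 − Σf²`) are taken on the grown,
post-fusion colonies. Both fixed-fraction and heterozygosity are reported
because the heterogeneity summary can reasonably mean either. Mutant-fate
experiments track colony-level fixation by default (population-level
extinction is the loss criterion when fusion is on), with censoring
reported at the horizon.

## Mobility model

Rides are uniform random walks of 10 street segments; demand bias teleports
a ride's drop-off to a uniform node of the target region (only drop-off
statistics matter for dispersion, so no routing is modeled). Cooperative
resetting snaps a random vehicle pair to the node nearest their coordinate
midpoint (Euclidean on node coordinates, ties to the smallest node id);
per ride taken this happens with probability 0.1, and the extrinsic variant
instead returns each vehicle to the depot node with the same per-ride
probability (read as a per-vehicle frequency since no collection schedule
is specified). The synthetic grid stands in for a real street network; the
GraphML loader accepts exports with `x`/`y` node attributes.

## What the generator does and does not emulate

The synthetic experiments cover the model's own claims: localization laws,
adaptation, search, neutral-genetics analogies, fleet dispersion. They do
not emulate heavy-tailed urban ride lengths, fitness differences between
genotypes, spatial hyphal structure, multiplicative or colored noise, or
2D/3D particle dynamics — passing tests say nothing about those regimes.

## Known limitations

* **Variance-based critical density is scale-dependent.** For `α = 2` the
  stationary law `χ^(−√ϱ)` has infinite variance anywhere below `√ϱ = 3`,
  so the dispersion-rate order parameter cannot vanish on `(2.3, 3)` at any
  finite time: the measured zero crossing at the shipped scale
  (`N = 2000`, horizon 240) lands near `√ϱ ≈ 3.2–3.5`, systematically above
  the refined analytic threshold 2.3, and the excess decays only slowly
  (roughly `t^(−1/3)` in the trailing slope) with the horizon. The package
  reports the measurement as computed.
* The refined critical constant 2.3 is used as an external reference value;
  its higher-order derivation is not re-implemented.
* Within-step ordering of multiple accepted resetting events introduces an
  O(dt) bias; all shipped runs keep multi-event steps rare.
* The near-transition power-law fit of the dispersion rate versus density
  is available through the regression tools, but no exponent is asserted:
  the fit window is not well constrained.
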