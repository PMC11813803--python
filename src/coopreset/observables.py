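"""Observables over resetting simulations.

Covers the dispersion analysis used to locate the localization transition
(ensemble variance growth and its long-time slope as an order parameter),
empirical tail characterization (CCDF and regression-based tail fits mapped
back to the rescaled density), and first-passage (search-time) experiments
for cooperative versus extrinsic resetting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .kernel import ResettingKernel
from .simulate import (
    EnsembleSeries,
    ExtrinsicParams,
    SimulationParams,
    first_passage_cooperative,
)

__all__ = [
    "VarianceSeries",
    "OrderParameter",
    "FPTResult",
    "TailFit",
    "CriticalDensityEstimate",
    "SearchComparison",
    "EstimationError",
    "CensoringError",
    "variance_trajectory",
    "dispersion_rate",
    "ccdf",
    "fit_tail",
    "estimate_critical_density",
    "first_passage_experiment",
    "extrinsic_mfpt_theory",
    "compare_search",
    "pooled_centered_positions",
]


class EstimationError(RuntimeError):
    """Raised when an estimator's preconditions are not met by the data."""


class CensoringError(RuntimeError):
    """Raised when too many first-passage replicates hit the horizon."""


@dataclass
class VarianceSeries:
    times: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if self.times.shape != self.variance.shape:
            raise ValueError("times and variance must align")
        if np.any(self.variance < 0):
            raise ValueError("variance must be non-negative")


@dataclass
class OrderParameter:
    """Long-time dispersion rate: slope of sigma^2(t) on the final window."""

    dispersion_rate: float
    ci: tuple[float, float]
    window: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.ci
        if not (lo <= self.dispersion_rate <= hi):
            raise ValueError("confidence interval must contain the estimate")

    @property
    def ci_excludes_zero(self) -> bool:
        lo, hi = self.ci
        return lo > 0 or hi < 0


@dataclass
class TailFit:
    form: str
    sqrt_rho: float
    slope: float
    n_tail: int
    window: tuple[float, float]


@dataclass
class FPTResult:
    target_distance: float
    times: np.ndarray  # uncensored passage times
    mfpt: float
    sem: float
    n_replicates: int
    n_censored: int


@dataclass
class CriticalDensityEstimate:
    sqrt_rho_c: float
    ci: tuple[float, float]
    sqrt_rho_grid: np.ndarray
    rates: np.ndarray  # per-grid-point mean dispersion rate
    rate_cis: np.ndarray  # per-grid-point (lo, hi)


@dataclass
class SearchComparison:
    rho_grid: np.ndarray
    cooperative: list[FPTResult]
    ext_rates: np.ndarray
    extrinsic: list[FPTResult]
    cooperative_min: float
    extrinsic_min: float
    cooperative_below: bool


def variance_trajectory(series: EnsembleSeries) -> VarianceSeries:
    """Per-snapshot ensemble variance (population denominator ``N``)."""
    if series.snapshots.size == 0:
        raise ValueError("empty series")
    if series.n_particles < 2:
        raise ValueError("need at least two particles per snapshot")
    return VarianceSeries(
        times=series.sample_times,
        variance=series.snapshots.var(axis=1),
    )


def dispersion_rate(
    vs: VarianceSeries,
    window_fraction: float = 1.0 / 3.0,
    n_boot: int = 2000,
    seed: int | None = None,
) -> OrderParameter:
    """OLS slope of sigma^2 versus t over the trailing window.

    The order parameter of the localization transition: zero (within CI) in
    the localized phase, positive when dispersion keeps accumulating.  The CI
    is a percentile bootstrap over snapshots.
    """
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must be in (0, 1]")
    n = vs.times.size
    start = int(math.floor(n * (1.0 - window_fraction)))
    t = vs.times[start:]
    v = vs.variance[start:]
    if t.size < 3:
        raise ValueError("need at least 3 points in the fit window")
    slope = _ols_slope(t, v)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, t.size, size=(n_boot, t.size))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        k = idx[b]
        if np.ptp(t[k]) == 0:
            boots[b] = slope
        else:
            boots[b] = _ols_slope(t[k], v[k])
    lo, hi = np.quantile(boots, [0.025, 0.975])
    lo, hi = min(lo, slope), max(hi, slope)
    return OrderParameter(
        dispersion_rate=slope, ci=(float(lo), float(hi)),
        window=(float(t[0]), float(t[-1])),
    )


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    tc = t - t.mean()
    return float(np.dot(tc, y - y.mean()) / np.dot(tc, tc))


def ccdf(samples) -> tuple[np.ndarray, np.ndarray]:
    """Right-tail empirical cumulative: fraction of samples >= x at each
    sorted unique sample point."""
    a = np.sort(np.asarray(samples, dtype=float))
    if a.size == 0:
        raise ValueError("need at least one sample")
    x = np.unique(a)
    frac = 1.0 - np.searchsorted(a, x, side="left") / a.size
    return x, frac


_ABSCISSAE: dict[str, Callable] = {
    "exponential": lambda x, alpha: x,
    "stretched_exponential": lambda x, alpha: x ** (1.0 - alpha / 2.0),
    "power_law": lambda x, alpha: np.log(x),
}


def fit_tail(
    samples,
    form: str,
    quantile_window: tuple[float, float] = (0.90, 0.999),
    alpha: float | None = None,
    min_tail: int = 200,
    value_window: tuple[float, float] | None = None,
) -> TailFit:
    """Fit the tail decay parameter by regressing the log empirical CCDF.

    ``samples`` are magnitudes (e.g. ``|chi|`` of centered positions).  The
    regression abscissa follows the law: ``|chi|`` for an exponential tail,
    ``|chi|**(1-alpha/2)`` for a stretched-exponential (requires ``alpha``),
    ``log|chi|`` for a power law.  The slope maps back to ``sqrt(rho)`` as
    ``-slope``, ``-slope*(1-alpha/2)`` and ``1-slope`` respectively.  The fit
    window is set by quantiles of the sample (default the 0.90–0.999 tail),
    or explicitly by ``value_window``.
    """
    if form not in _ABSCISSAE:
        raise ValueError(f"unknown tail form {form!r}")
    if form == "stretched_exponential" and alpha is None:
        raise ValueError("stretched-exponential fits require alpha")
    a = np.sort(np.abs(np.asarray(samples, dtype=float)))
    if value_window is not None:
        lo, hi = value_window
    else:
        lo, hi = np.quantile(a, quantile_window)
    sel = (a >= lo) & (a <= hi) & (a > 0)
    x = np.unique(a[sel])
    if x.size < min_tail:
        raise EstimationError(
            f"only {x.size} tail points in window [{lo:.3g}, {hi:.3g}]; "
            f"need >= {min_tail}"
        )
    frac = 1.0 - np.searchsorted(a, x, side="left") / a.size
    keep = frac > 0
    X = _ABSCISSAE[form](x[keep], alpha)
    slope = _ols_slope(X, np.log(frac[keep]))
    if form == "exponential":
        sqrt_rho = -slope
    elif form == "stretched_exponential":
        sqrt_rho = -slope * (1.0 - alpha / 2.0)
    else:
        sqrt_rho = 1.0 - slope
    return TailFit(form=form, sqrt_rho=sqrt_rho, slope=slope,
                   n_tail=int(x.size), window=(float(lo), float(hi)))


def estimate_critical_density(
    sim_factory: Callable[[float, int], VarianceSeries],
    sqrt_rho_grid: Sequence[float],
    n_reps: int = 3,
    window_fraction: float = 1.0 / 3.0,
    n_boot: int = 2000,
    seed: int | None = None,
) -> CriticalDensityEstimate:
    """Locate the zero crossing of the dispersion rate along a density scan.

    ``sim_factory(sqrt_rho, replicate)`` must return a
    :class:`VarianceSeries` for a run at that density.  Per grid point the
    dispersion rate is the mean of per-replicate final-window slopes with a
    bootstrap CI over replicates.  The crossing is interpolated linearly
    between the largest density whose CI excludes zero and the smallest whose
    CI includes it; a bootstrap over replicates gives the CI of the crossing.
    """
    grid = np.asarray(sqrt_rho_grid, dtype=float)
    if grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("sqrt_rho_grid must be increasing with >= 2 points")
    rng = np.random.default_rng(seed)
    slopes = np.empty((grid.size, n_reps))
    for g, sq in enumerate(grid):
        for r in range(n_reps):
            vs = sim_factory(float(sq), r)
            n = vs.times.size
            start = int(math.floor(n * (1.0 - window_fraction)))
            slopes[g, r] = _ols_slope(vs.times[start:], vs.variance[start:])
    rates = slopes.mean(axis=1)
    idx = rng.integers(0, n_reps, size=(n_boot, n_reps))
    boot_rates = slopes[:, idx].mean(axis=2)  # (grid, n_boot)
    cis = np.quantile(boot_rates, [0.025, 0.975], axis=1).T
    cis[:, 0] = np.minimum(cis[:, 0], rates)
    cis[:, 1] = np.maximum(cis[:, 1], rates)

    def _crossing(rate_vec: np.ndarray, ci_lo: np.ndarray, ci_hi: np.ndarray) -> float:
        excludes = (ci_lo > 0) | (ci_hi < 0)
        pos_excl = np.nonzero(excludes & (rate_vec > 0))[0]
        incl = np.nonzero(~excludes)[0]
        if pos_excl.size == 0 or incl.size == 0:
            raise EstimationError("dispersion rate has no zero crossing on the grid")
        k1 = int(pos_excl.max())
        after = incl[incl > k1]
        if after.size == 0:
            raise EstimationError("dispersion rate has no zero crossing on the grid")
        k2 = int(after.min())
        x1, x2 = grid[k1], grid[k2]
        r1, r2 = rate_vec[k1], rate_vec[k2]
        if r1 == r2:
            return float(0.5 * (x1 + x2))
        return float(x1 + r1 * (x2 - x1) / (r1 - r2))

    est = _crossing(rates, cis[:, 0], cis[:, 1])
    boots = []
    for b in range(min(n_boot, 500)):
        rv = boot_rates[:, b]
        try:
            boots.append(_crossing(rv, cis[:, 0], cis[:, 1]))
        except EstimationError:
            continue
    if boots:
        lo, hi = np.quantile(boots, [0.025, 0.975])
        lo, hi = min(lo, est), max(hi, est)
    else:
        lo = hi = est
    return CriticalDensityEstimate(
        sqrt_rho_c=est, ci=(float(lo), float(hi)), sqrt_rho_grid=grid,
        rates=rates, rate_cis=cis,
    )


def extrinsic_mfpt_theory(l: float, rate: float, diffusion: float) -> float:
    """Closed-form mean first-passage time of a diffusing particle with
    Poissonian resetting to the origin: ``(exp(l*sqrt(r/D)) - 1) / r``."""
    return (math.exp(l * math.sqrt(rate / diffusion)) - 1.0) / rate


def first_passage_experiment(
    mode: str,
    params: SimulationParams,
    l: float,
    n_reps: int,
    seed: int | None = None,
    ext: ExtrinsicParams | None = None,
    max_censoring: float = 0.01,
) -> FPTResult:
    """Replicated first-passage times of a marked particle to ``x0 + l``.

    In cooperative mode the marked particle is chosen uniformly per replicate
    and the full ensemble runs underneath.  In extrinsic mode particles are
    independent, so only the marked particle is simulated (vectorized across
    replicates).  Crossings are detected at discrete steps.  Replicates that
    reach ``t_max`` are censored; the MFPT is reported only when the censored
    fraction stays below ``max_censoring``.
    """
    if l <= 0:
        raise ValueError("target distance l must be positive")
    if mode not in ("cooperative", "extrinsic"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    target = params.x0 + l
    if mode == "cooperative":
        times = np.empty(n_reps)
        for r in range(n_reps):
            marked = int(rng.integers(0, params.n_particles))
            times[r] = first_passage_cooperative(params, marked, target, rng)
    else:
        if ext is None:
            raise ValueError("extrinsic mode requires ExtrinsicParams")
        times = _extrinsic_fpt_batch(params, ext, target, n_reps, rng)
    censored = int(np.isnan(times).sum())
    if censored / n_reps >= max_censoring:
        raise CensoringError(
            f"{censored}/{n_reps} replicates censored at t_max={params.t_max}"
        )
    ok = times[~np.isnan(times)]
    mfpt = float(ok.mean())
    sem = float(ok.std(ddof=1) / math.sqrt(ok.size))
    return FPTResult(target_distance=l, times=ok, mfpt=mfpt, sem=sem,
                     n_replicates=n_reps, n_censored=censored)


def _extrinsic_fpt_batch(
    params: SimulationParams,
    ext: ExtrinsicParams,
    target: float,
    n_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    dt = params.dt
    sig = math.sqrt(2.0 * params.diffusion * dt)
    vdt = params.drift_v * dt
    p_reset = -math.expm1(-ext.reset_rate * dt)
    n_steps = int(round(params.t_max / dt))
    x = np.full(n_reps, params.x0)
    out = np.full(n_reps, np.nan)
    active = np.arange(n_reps)
    for step in range(1, n_steps + 1):
        x += vdt + sig * rng.standard_normal(active.size)
        hit = rng.random(active.size) < p_reset
        x[hit] = ext.reset_position
        passed = x >= target
        if passed.any():
            out[active[passed]] = step * dt
            keep = ~passed
            x = x[keep]
            active = active[keep]
            if active.size == 0:
                break
    return out


def compare_search(
    params: SimulationParams,
    l: float,
    rho_grid: Sequence[float],
    n_reps: int,
    seed: int | None = None,
    ext_dt: float | None = None,
) -> SearchComparison:
    """Scan the rescaled density through ``mu0`` and compare the minimal MFPT
    of cooperative resetting against the extrinsic baseline at the matched
    rate ``mu_ext = mu0 * N``.

    Both arms share diffusion constant, start and target.  The extrinsic arm
    may use a finer ``ext_dt`` since it is vectorized and cheap.
    """
    rho_grid = np.asarray(rho_grid, dtype=float)
    n = params.n_particles
    d0 = params.kernel.delta0
    ss = np.random.SeedSequence(seed)
    coop_seeds, ext_seeds = ss.spawn(2)
    coop_results: list[FPTResult] = []
    ext_results: list[FPTResult] = []
    ext_rates = rho_grid * params.diffusion / (2.0 * d0**2)  # mu0*N = rho*D/(2 d0^2)
    for rho, cs, es in zip(
        rho_grid,
        coop_seeds.spawn(rho_grid.size),
        ext_seeds.spawn(rho_grid.size),
    ):
        mu0 = rho * params.diffusion / (2.0 * n * d0**2)
        p_coop = SimulationParams(
            n_particles=n, diffusion=params.diffusion, dt=params.dt,
            t_max=params.t_max, x0=params.x0, drift_v=params.drift_v,
            kernel=ResettingKernel(mu0=mu0, delta0=d0, alpha=params.kernel.alpha),
        )
        coop_results.append(
            first_passage_experiment(
                "cooperative", p_coop, l, n_reps,
                seed=cs.generate_state(1)[0] % 2**31,
            )
        )
        p_ext = SimulationParams(
            n_particles=2, diffusion=params.diffusion,
            dt=ext_dt or params.dt, t_max=params.t_max, x0=params.x0,
            drift_v=params.drift_v,
            kernel=ResettingKernel(mu0=mu0, delta0=d0, alpha=params.kernel.alpha),
        )
        ext_results.append(
            first_passage_experiment(
                "extrinsic", p_ext, l, n_reps,
                seed=es.generate_state(1)[0] % 2**31,
                ext=ExtrinsicParams(reset_rate=mu0 * n, reset_position=params.x0),
            )
        )
    coop_min = min(r.mfpt for r in coop_results)
    ext_min = min(r.mfpt for r in ext_results)
    return SearchComparison(
        rho_grid=rho_grid, cooperative=coop_results, ext_rates=ext_rates,
        extrinsic=ext_results, cooperative_min=coop_min, extrinsic_min=ext_min,
        cooperative_below=coop_min < ext_min,
    )


def pooled_centered_positions(series: EnsembleSeries, burn_time: float = 0.0) -> np.ndarray:
    """Pool snapshots after ``burn_time``, centering each on its ensemble
    mean (removes center-of-mass wander in finite ensembles)."""
    keep = series.sample_times >= burn_time
    if not keep.any():
        raise ValueError("no snapshots after burn_time")
    snaps = series.snapshots[keep]
    return (snaps - snaps.mean(axis=1, keepdims=True)).ravel()
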