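"""Agent-based engine for Brownian particles with cooperative midpoint resetting.

``N`` particles diffuse in one dimension (diffusion constant ``D``, optional
constant drift ``v``).  In addition, random pairs are reset to their mutual
midpoint at a distance-dependent intensity given by a
:class:`~coopreset.kernel.ResettingKernel`.  An extrinsic-resetting baseline
(independent Poissonian resets to a fixed position) is provided for
comparison.

Event generation uses operator splitting at a fixed time step ``dt``:
particles first take an Euler–Maruyama diffusion step, then resetting events
are generated by Poisson thinning against the uniform envelope
``2*mu0`` per pair.  Candidates are drawn one at a time and accepted with the
kernel's acceptance probability evaluated at the *current* positions, so
accepted events within one step are applied sequentially in draw order.  The
scheme is exact in the ``dt -> 0`` limit; a warning is emitted when ``dt`` is
large enough that multi-event steps become common.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kernel import ResettingKernel

__all__ = [
    "SimulationParams",
    "ExtrinsicParams",
    "EnsembleState",
    "EnsembleSeries",
    "cooperative_reset_pair",
    "simulate_cooperative",
    "simulate_extrinsic",
    "first_passage_cooperative",
]


class SimulationError(RuntimeError):
    """Raised when a run produces non-finite positions."""


@dataclass
class SimulationParams:
    """Parameters of one ensemble run.

    ``rho`` is the dimensionless rescaled density ``2*N*delta0**2*mu0/D``
    controlling the balance between resetting and diffusion; positions are
    naturally measured in units of ``delta0`` (``chi = x/delta0``).
    """

    n_particles: int
    diffusion: float
    dt: float
    t_max: float
    kernel: ResettingKernel
    x0: float = 0.0
    drift_v: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if not self.diffusion >= 0:
            raise ValueError("diffusion must be non-negative")
        if not self.dt > 0 or not self.t_max > 0:
            raise ValueError("dt and t_max must be positive")
        # Envelope on the expected accepted events per particle per step;
        # beyond ~0.1 the within-step sequential ordering starts to matter.
        per_particle = self.kernel.max_pair_intensity * (self.n_particles - 1) * self.dt
        if per_particle >= 0.1:
            warnings.warn(
                f"dt={self.dt} allows up to {per_particle:.3f} resetting events "
                "per particle per step (>= 0.1); consider reducing dt",
                RuntimeWarning,
                stacklevel=2,
            )

    @property
    def rho(self) -> float:
        """Rescaled density ``2*N*delta0**2*mu0/D``."""
        if self.diffusion == 0:
            return math.inf
        k = self.kernel
        return 2.0 * self.n_particles * k.delta0**2 * k.mu0 / self.diffusion


@dataclass
class ExtrinsicParams:
    """Extrinsic-resetting baseline: Poisson resets at rate ``reset_rate`` to
    ``reset_position``.  The matched mapping to a cooperative system is
    ``reset_rate = mu0 * N``."""

    reset_rate: float
    reset_position: float = 0.0

    def __post_init__(self) -> None:
        if not self.reset_rate > 0:
            raise ValueError("reset_rate must be positive")


@dataclass
class EnsembleState:
    """Positions of the ``N`` particles at one instant."""

    positions: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 1 or self.positions.size < 1:
            raise ValueError("positions must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")


@dataclass
class EnsembleSeries:
    """Trajectory record: snapshots at ``sample_times`` plus an optional log
    of accepted resetting events ``(time, i, j, delta)``."""

    sample_times: np.ndarray
    snapshots: np.ndarray  # shape (n_samples, n_particles)
    events: np.ndarray = field(
        default_factory=lambda: np.empty(
            0, dtype=[("time", float), ("i", int), ("j", int), ("delta", float)]
        )
    )

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        if np.any(np.diff(self.sample_times) <= 0):
            raise ValueError("sample_times must be strictly increasing")
        if self.snapshots.shape[0] != self.sample_times.size:
            raise ValueError("one snapshot per sample time required")
        if self.events.size and np.any(self.events["delta"] < 0):
            raise ValueError("event separations must be non-negative")

    @property
    def n_particles(self) -> int:
        return self.snapshots.shape[1]


def cooperative_reset_pair(state: EnsembleState, i: int, j: int) -> EnsembleState:
    """Reset particles ``i`` and ``j`` to their mutual midpoint.

    The position sum is conserved exactly and the sum of squared deviations
    from the ensemble mean drops by ``delta**2 / 2``.
    """
    n = state.positions.size
    if i == j:
        raise IndexError("cooperative reset requires two distinct particles")
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"pair ({i}, {j}) out of range for {n} particles")
    positions = state.positions.copy()
    mid = 0.5 * (positions[i] + positions[j])
    positions[i] = mid
    positions[j] = mid
    return EnsembleState(positions=positions, time=state.time)


def _sample_steps(sample_times: Sequence[float], dt: float, t_max: float) -> np.ndarray:
    times = np.asarray(sample_times, dtype=float)
    if times.size == 0:
        raise ValueError("at least one sample time is required")
    if np.any(np.diff(times) <= 0):
        raise ValueError("sample_times must be strictly increasing")
    if times[0] <= 0 or times[-1] > t_max + 1e-12:
        raise ValueError("sample_times must lie in (0, t_max]")
    return np.maximum(1, np.rint(times / dt).astype(int))


def simulate_cooperative(
    params: SimulationParams,
    sample_times: Sequence[float],
    log_events: bool = False,
    x_init: np.ndarray | None = None,
) -> EnsembleSeries:
    """Run the cooperative-resetting ensemble and record snapshots.

    Per step: all particles advance by ``v*dt`` plus a Gaussian increment of
    variance ``2*D*dt``; the number of candidate resetting events is Poisson
    with mean ``2*mu0 * N*(N-1)/2 * dt``; each candidate picks a uniformly
    random unordered pair and is accepted with the kernel's acceptance
    probability at the pair's current separation.  Deterministic given
    ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_particles
    if x_init is None:
        x = np.full(n, params.x0, dtype=float)
    else:
        x = np.asarray(x_init, dtype=float).copy()
        if x.shape != (n,):
            raise ValueError("x_init must have one position per particle")
    steps = _sample_steps(sample_times, params.dt, params.t_max)
    n_steps = int(steps[-1])

    cand_mean = params.kernel.max_pair_intensity * n * (n - 1) / 2.0 * params.dt
    sig = math.sqrt(2.0 * params.diffusion * params.dt)
    vdt = params.drift_v * params.dt
    alpha = params.kernel.alpha
    delta0 = params.kernel.delta0

    snapshots = np.empty((steps.size, n))
    events: list[tuple[float, int, int, float]] = []
    next_sample = 0

    for step in range(1, n_steps + 1):
        x += vdt + sig * rng.standard_normal(n)
        n_cand = rng.poisson(cand_mean)
        if n_cand:
            ii = rng.integers(0, n, size=n_cand)
            jj = rng.integers(0, n - 1, size=n_cand)
            jj = np.where(jj >= ii, jj + 1, jj)
            uu = rng.random(n_cand)
            t_now = step * params.dt
            for k in range(n_cand):
                i = ii[k]
                j = jj[k]
                d = abs(x[i] - x[j])
                acc = 1.0 if alpha == 0 else 1.0 / (1.0 + (d / delta0) ** alpha)
                if uu[k] < acc:
                    mid = 0.5 * (x[i] + x[j])
                    x[i] = mid
                    x[j] = mid
                    if log_events:
                        events.append((t_now, int(i), int(j), d))
        while next_sample < steps.size and steps[next_sample] == step:
            if not np.all(np.isfinite(x)):
                raise SimulationError(f"non-finite positions at t={step * params.dt}")
            snapshots[next_sample] = x
            next_sample += 1

    ev = np.array(
        events, dtype=[("time", float), ("i", int), ("j", int), ("delta", float)]
    )
    return EnsembleSeries(
        sample_times=np.asarray(sample_times, dtype=float),
        snapshots=snapshots,
        events=ev,
    )


def simulate_extrinsic(
    params: SimulationParams,
    ext: ExtrinsicParams,
    sample_times: Sequence[float],
    log_events: bool = False,
) -> EnsembleSeries:
    """Independent particles with Poissonian resets to ``ext.reset_position``.

    Each particle resets with per-step probability ``1 - exp(-rate*dt)``;
    diffusion and drift are as in :func:`simulate_cooperative`.  Logged events
    store ``j = -1`` and ``delta`` as the distance jumped back.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_particles
    x = np.full(n, params.x0, dtype=float)
    steps = _sample_steps(sample_times, params.dt, params.t_max)
    n_steps = int(steps[-1])

    p_reset = -math.expm1(-ext.reset_rate * params.dt)
    sig = math.sqrt(2.0 * params.diffusion * params.dt)
    vdt = params.drift_v * params.dt

    snapshots = np.empty((steps.size, n))
    events: list[tuple[float, int, int, float]] = []
    next_sample = 0

    for step in range(1, n_steps + 1):
        x += vdt + sig * rng.standard_normal(n)
        mask = rng.random(n) < p_reset
        if mask.any():
            if log_events:
                t_now = step * params.dt
                for i in np.nonzero(mask)[0]:
                    events.append((t_now, int(i), -1, abs(x[i] - ext.reset_position)))
            x[mask] = ext.reset_position
        while next_sample < steps.size and steps[next_sample] == step:
            if not np.all(np.isfinite(x)):
                raise SimulationError(f"non-finite positions at t={step * params.dt}")
            snapshots[next_sample] = x
            next_sample += 1

    ev = np.array(
        events, dtype=[("time", float), ("i", int), ("j", int), ("delta", float)]
    )
    return EnsembleSeries(
        sample_times=np.asarray(sample_times, dtype=float),
        snapshots=snapshots,
        events=ev,
    )


def first_passage_cooperative(
    params: SimulationParams,
    marked: int,
    target: float,
    rng: np.random.Generator,
) -> float:
    """First time the marked particle's position reaches ``>= target``.

    The full ensemble dynamics runs underneath; the marked particle keeps
    pairing with the others.  Crossings are detected at discrete steps (no
    bridge correction).  Returns ``nan`` if ``t_max`` is reached first.
    """
    n = params.n_particles
    if not 0 <= marked < n:
        raise IndexError("marked particle index out of range")
    x = np.full(n, params.x0, dtype=float)
    n_steps = int(round(params.t_max / params.dt))
    cand_mean = params.kernel.max_pair_intensity * n * (n - 1) / 2.0 * params.dt
    sig = math.sqrt(2.0 * params.diffusion * params.dt)
    vdt = params.drift_v * params.dt
    alpha = params.kernel.alpha
    delta0 = params.kernel.delta0

    for step in range(1, n_steps + 1):
        x += vdt + sig * rng.standard_normal(n)
        n_cand = rng.poisson(cand_mean)
        if n_cand:
            ii = rng.integers(0, n, size=n_cand)
            jj = rng.integers(0, n - 1, size=n_cand)
            jj = np.where(jj >= ii, jj + 1, jj)
            uu = rng.random(n_cand)
            for k in range(n_cand):
                i = ii[k]
                j = jj[k]
                d = abs(x[i] - x[j])
                acc = 1.0 if alpha == 0 else 1.0 / (1.0 + (d / delta0) ** alpha)
                if uu[k] < acc:
                    mid = 0.5 * (x[i] + x[j])
                    x[i] = mid
                    x[j] = mid
        if x[marked] >= target:
            return step * params.dt
    return math.nan
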