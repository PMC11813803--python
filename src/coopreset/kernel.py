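"""Distance-dependent pairwise resetting kernel.

A cooperative resetting system couples pairs of Brownian particles: a pair at
separation ``delta`` is reset to its midpoint at a rate that decays
algebraically beyond a characteristic interaction length ``delta0``,

    mu(delta) = mu0 / (1 + (delta / delta0)**alpha).

``alpha`` controls the interaction range.  ``alpha = 0`` is the
distance-independent limit in which every pair interacts at the full
amplitude; ``alpha > 2`` makes interactions too short-ranged to balance
diffusion and the system delocalizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ResettingKernel", "resetting_rate"]


@dataclass(frozen=True)
class ResettingKernel:
    """Interaction kernel ``mu(delta) = mu0 / (1 + (delta/delta0)**alpha)``.

    Parameters
    ----------
    mu0 : float
        Rate amplitude (1/time), > 0.
    delta0 : float
        Interaction length scale (length), > 0.
    alpha : float
        Algebraic decay exponent, >= 0.

    Notes
    -----
    Two evaluations are exposed.  :meth:`rate` is the kernel formula itself,
    with the convention ``(delta/delta0)**0 == 1`` so that ``alpha = 0``
    evaluates to the constant ``mu0/2``.  :meth:`pair_intensity` is the total
    event intensity per unordered particle pair used by the event engine:
    each *ordered* pair interacts at rate ``mu``, giving ``2*mu(delta)`` per
    pair for ``alpha > 0``, and the distance-independent model at amplitude
    ``mu0`` (intensity ``2*mu0``) for ``alpha = 0``.  This calibration is what
    reproduces the flux-balance stationary tails parameterized by the
    rescaled density ``rho = 2*N*delta0**2*mu0/D`` (see ``docs/methods.md``).
    """

    mu0: float
    delta0: float = 1.0
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if not self.mu0 >= 0:
            raise ValueError(f"mu0 must be non-negative, got {self.mu0}")
        if not self.delta0 > 0:
            raise ValueError(f"delta0 must be positive, got {self.delta0}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be non-negative, got {self.alpha}")

    def rate(self, delta):
        """Evaluate ``mu(delta)``; scalar or array, ``delta >= 0``."""
        delta = np.asarray(delta, dtype=float)
        if np.any(delta < 0):
            raise ValueError("separation delta must be non-negative")
        # numpy's 0**0 == 1 implements the alpha = 0 convention directly
        out = self.mu0 / (1.0 + (delta / self.delta0) ** self.alpha)
        return float(out) if out.ndim == 0 else out

    def acceptance(self, delta):
        """Thinning acceptance probability ``pair_intensity / (2*mu0)``."""
        delta = np.asarray(delta, dtype=float)
        if self.alpha == 0:
            out = np.ones_like(delta)
        else:
            out = 1.0 / (1.0 + (delta / self.delta0) ** self.alpha)
        return float(out) if out.ndim == 0 else out

    def pair_intensity(self, delta):
        """Total resetting intensity of an unordered pair at separation ``delta``."""
        delta = np.asarray(delta, dtype=float)
        if np.any(delta < 0):
            raise ValueError("separation delta must be non-negative")
        out = self.max_pair_intensity * np.asarray(self.acceptance(delta))
        return float(out) if out.ndim == 0 else out

    @property
    def max_pair_intensity(self) -> float:
        """Upper bound ``2*mu0`` on the pair intensity (thinning envelope)."""
        return 2.0 * self.mu0


def resetting_rate(delta, kernel: ResettingKernel):
    """Kernel value ``mu(delta)`` — functional form of :meth:`ResettingKernel.rate`."""
    return kernel.rate(delta)
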