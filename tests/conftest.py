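import numpy as np
import pytest
from hypothesis import settings

import coopreset as cr

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def alpha0_rho21_series() -> cr.EnsembleSeries:
    """Stationary cooperative run with distance-independent interactions at
    rescaled density rho = 21 (N = 2000, D = 1, delta0 = 1); shared by the
    tail-decay and mean-field cross-validation tests."""
    n, diffusion, rho = 2000, 1.0, 21.0
    kernel = cr.ResettingKernel(mu0=rho * diffusion / (2 * n), delta0=1.0, alpha=0.0)
    params = cr.SimulationParams(
        n_particles=n, diffusion=diffusion, dt=0.004, t_max=40.0,
        kernel=kernel, seed=11,
    )
    return cr.simulate_cooperative(params, np.arange(0.5, 40.001, 0.5))


@pytest.fixture(scope="session")
def alpha0_rho21_pooled(alpha0_rho21_series) -> np.ndarray:
    return cr.pooled_centered_positions(alpha0_rho21_series, burn_time=20.0)
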