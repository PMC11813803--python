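import numpy as np
import pytest

import coopreset as cr
from coopreset.meanfield import MeanFieldOperator


class TestSolveTail:
    def test_alpha0_exponential(self):
        law = cr.solve_tail(0.0, 21.0)
        assert law.form == "exponential"
        assert law.rate_or_exponent == pytest.approx(np.sqrt(21))
        # log-density slope is -sqrt(rho)
        chi = np.linspace(1, 5, 50)
        slope = np.polyfit(chi, law.log_density(chi), 1)[0]
        assert slope == pytest.approx(-np.sqrt(21), rel=1e-12)

    def test_alpha1_stretched_shape(self):
        # sqrt(rho)/(1 - alpha/2) = 2 / 0.5 = 4: shape exp(-4 sqrt(chi))
        law = cr.solve_tail(1.0, 4.0)
        assert law.form == "stretched_exponential"
        chi = np.array([1.0, 4.0, 9.0])
        expected = -4.0 * (np.sqrt(chi) - 1.0)
        assert np.allclose(law.log_density(chi), expected)

    def test_alpha2_power_law(self):
        law = cr.solve_tail(2.0, 9.0)
        assert law.form == "power_law"
        assert law.density(2.0) / law.density(1.0) == pytest.approx(2.0**-3)
        assert law.normalizable  # sqrt(rho) = 3 > 1

    def test_alpha2_below_normalizability(self):
        assert not cr.solve_tail(2.0, 0.81).normalizable

    def test_alpha3_delocalized(self):
        law = cr.solve_tail(3.0, 100.0)
        assert law.form == "delocalized"
        assert not law.normalizable
        with pytest.raises(ValueError):
            law.sample(10, np.random.default_rng(0))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cr.solve_tail(1.0, -2.0)
        with pytest.raises(ValueError):
            cr.solve_tail(-1.0, 2.0)

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0, 1.5])
    def test_log_density_linear_in_stretched_coordinate(self, alpha):
        """log p_s is linear in chi**(1-alpha/2) with slope
        -sqrt(rho)/(1-alpha/2)."""
        rho = 7.3
        law = cr.solve_tail(alpha, rho)
        chi = np.linspace(1, 20, 200)
        u = chi ** (1 - alpha / 2)
        coef = np.polyfit(u, law.log_density(chi), 1)
        assert coef[0] == pytest.approx(-np.sqrt(rho) / (1 - alpha / 2), rel=1e-10)

    @pytest.mark.parametrize("alpha,rho", [(0.0, 21.0), (1.0, 4.0), (2.0, 9.0)])
    def test_flux_balance_identity(self, alpha, rho):
        """The solution satisfies rho * p * |p/p'| * chi^-alpha = -p'
        identically for chi > 1 (to machine precision)."""
        law = cr.solve_tail(alpha, rho)
        chi = np.linspace(1.0, 10.0, 91)
        p = law.density(chi)
        p_prime = -np.sqrt(rho) * chi ** (-alpha / 2) * p  # decaying branch
        lhs = rho * p * np.abs(p / p_prime) * chi ** (-alpha)
        assert np.allclose(lhs, -p_prime, rtol=1e-12)

    def test_sampler_matches_law(self):
        rng = np.random.default_rng(7)
        law = cr.solve_tail(2.0, 25.0)
        x = law.sample(200_000, rng, chi_min=1.0)
        # CCDF of chi^-5 is chi^-4
        assert np.mean(x >= 2.0) == pytest.approx(2.0**-4, rel=0.1)


class TestClassifyLocalization:
    @pytest.mark.parametrize(
        "alpha,rho,criterion,localized",
        [
            (1.0, 0.5, "refined", True),       # any density localizes below alpha=2
            (2.0, 9.0, "normalizability", True),   # sqrt(rho)=3 > 1
            (2.0, 4.0, "refined", False),      # sqrt(rho)=2 < 2.3
            (2.0, 6.25, "refined", True),      # sqrt(rho)=2.5 > 2.3
            (3.0, 1e6, "refined", False),      # no localization above alpha=2
        ],
    )
    def test_verdicts(self, alpha, rho, criterion, localized):
        v = cr.classify_localization(alpha, rho, criterion)
        assert v.localized is localized

    def test_criterion_labels(self):
        assert cr.classify_localization(1.0, 1.0).criterion == "always"
        assert cr.classify_localization(3.0, 1.0).criterion == "never"
        v = cr.classify_localization(2.0, 2.0, "refined")
        assert v.critical_sqrt_density == pytest.approx(2.3)

    def test_unknown_criterion(self):
        with pytest.raises(ValueError):
            cr.classify_localization(2.0, 2.0, "bogus")


class TestGeneralKernel:
    def test_exponential_decay_does_not_localize(self):
        assert cr.general_kernel_localizes(lambda d: np.exp(-d)) is False

    def test_slow_algebraic_decay_localizes(self):
        assert cr.general_kernel_localizes(lambda d: 1.0 / (1.0 + d)) is True

    def test_fast_algebraic_decay_does_not_localize(self):
        assert cr.general_kernel_localizes(lambda d: 1.0 / (1.0 + d**3)) is False

    def test_marginal_quadratic_decay_localizes(self):
        assert cr.general_kernel_localizes(lambda d: 1.0 / (1.0 + d**2)) is True

    def test_negative_kernel_rejected(self):
        with pytest.raises(ValueError):
            cr.general_kernel_localizes(lambda d: -np.ones_like(d))


class TestMeanFieldPDE:
    def test_rhs_is_pure_diffusion_without_resetting(self):
        grid = cr.DensityGrid.gaussian(5.0, 401, 0.8)
        k = cr.ResettingKernel(mu0=0.0)
        rhs = cr.meanfield_rhs(grid, k, 100, diffusion=1.0)
        # analytic Laplacian of the Gaussian
        sig = 0.8
        p = grid.density
        expected = p * ((grid.chi / sig**2) ** 2 - 1.0 / sig**2)
        inner = slice(5, -5)
        assert np.allclose(rhs[inner], expected[inner], atol=1e-3 * np.abs(expected).max())

    def test_rhs_conserves_probability_and_symmetry(self):
        grid = cr.DensityGrid.gaussian(4.0, 301, 0.4)
        k = cr.ResettingKernel(mu0=0.01, alpha=1.0)
        rhs = cr.meanfield_rhs(grid, k, 500, diffusion=1.0)
        assert abs(np.trapezoid(rhs, grid.chi)) < 1e-10
        assert np.allclose(rhs, rhs[::-1], atol=1e-10 * np.abs(rhs).max())

    def test_unnormalized_grid_rejected(self):
        with pytest.raises(ValueError):
            cr.DensityGrid(chi=np.linspace(-1, 1, 11), density=np.ones(11) * 3)

    def test_zero_kernel_gaussian_spreads_diffusively(self):
        grid = cr.DensityGrid.gaussian(6.0, 301, 0.5)
        k = cr.ResettingKernel(mu0=0.0)
        out = cr.integrate_meanfield(grid, k, 100, diffusion=1.0, t_end=0.5)
        assert out.variance() == pytest.approx(0.5**2 + 2 * 1.0 * 0.5, rel=0.02)

    def test_localized_regime_variance_plateaus(self):
        n, rho = 2000, 21.0
        k = cr.ResettingKernel(mu0=rho / (2 * n))
        grid = cr.DensityGrid.gaussian(4.0, 241, 0.3)
        mid = cr.integrate_meanfield(grid, k, n, 1.0, t_end=1.0)
        late = cr.integrate_meanfield(mid, k, n, 1.0, t_end=1.0)
        assert late.variance() == pytest.approx(mid.variance(), rel=0.05)
        # steady-state tail decay agrees with the flux-balance ODE
        sel = (late.chi > 0.8) & (late.chi < 2.2)
        slope = np.polyfit(late.chi[sel], np.log(late.density[sel]), 1)[0]
        assert -slope == pytest.approx(np.sqrt(rho), rel=0.10)

    def test_normalization_preserved_per_step(self):
        n, rho = 2000, 21.0
        k = cr.ResettingKernel(mu0=rho / (2 * n))
        grid = cr.DensityGrid.gaussian(4.0, 241, 0.3)
        op = MeanFieldOperator(grid.chi, k, n, diffusion=1.0)
        p = grid.density.copy()
        dt = 0.2 * grid.spacing**2 / 2.0
        for _ in range(50):
            p = p + dt * op(p)
            assert abs(np.trapezoid(p, grid.chi) - 1.0) < 1e-8

    def test_unstable_dt_rejected(self):
        grid = cr.DensityGrid.gaussian(4.0, 241, 0.3)
        k = cr.ResettingKernel(mu0=0.001)
        with pytest.raises(ValueError):
            cr.integrate_meanfield(grid, k, 100, 1.0, t_end=0.1,
                                   dt=10 * grid.spacing**2)
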