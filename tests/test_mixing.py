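import numpy as np
import pytest

from otfe import (HarmonicPotential, boltzmann_density,
                  corrected_linear_mix, gaussian_barycenter_params,
                  gaussian_ot_mix, linear_mix, make_schedule, mvp_mix,
                  quantile_barycenter_1d)
from otfe.exceptions import ValidationError
from otfe.grids import Grid1D
from tests.conftest import K_BENCH


@pytest.fixture(scope="module")
def oscillators():
    return HarmonicPotential(K_BENCH, 0.0), HarmonicPotential(K_BENCH, 0.5)


XS = np.linspace(-0.7, 1.2, 301)


@pytest.mark.parametrize("tag", ["linear", "linearC", "mvp", "ot"])
def test_endpoint_recovery(tag, double_well, harmonic, oscillators, thermo, bench_grid):
    """Every schedule reproduces U1 at lam=0 and U2 at lam=1 pointwise."""
    u1, u2 = oscillators if tag == "ot" else (double_well, harmonic)
    factory = make_schedule(tag, u1, u2, thermo, grid=bench_grid)
    assert np.max(np.abs(factory(0.0).energy(XS) - u1.energy(XS))) < 1e-9
    assert np.max(np.abs(factory(1.0).energy(XS) - u2.energy(XS))) < 1e-9


@pytest.mark.parametrize("tag", ["linear", "mvp", "ot"])
def test_lambda_domain_enforced(tag, oscillators, thermo):
    factory = make_schedule(tag, *oscillators, thermo)
    with pytest.raises(ValidationError):
        factory(-0.1)
    with pytest.raises(ValidationError):
        factory(1.2)


class TestLinear:
    def test_equal_k_shift_identity(self, oscillators):
        """(1-l)U1 + lU2 = harmonic about the interpolated center plus the
        spurious shift (k/2) l(1-l) (x1-x2)^2."""
        u1, u2 = oscillators
        lam = 0.3
        mix = linear_mix(u1, u2, lam)
        center = (1 - lam) * u1.center + lam * u2.center
        shift = 0.5 * K_BENCH * lam * (1 - lam) * (u1.center - u2.center) ** 2
        expected = 0.5 * K_BENCH * (XS - center) ** 2 + shift
        np.testing.assert_allclose(mix.energy(XS), expected, atol=1e-10)

    def test_different_k_completing_square(self):
        u1 = HarmonicPotential(100.0, 0.0)
        u2 = HarmonicPotential(300.0, 0.5)
        lam = 0.4
        mix = linear_mix(u1, u2, lam)
        kbar = (1 - lam) * 100.0 + lam * 300.0
        center = ((1 - lam) * 100.0 * 0.0 + lam * 300.0 * 0.5) / kbar
        quad = 0.5 * kbar * (XS - center) ** 2
        resid = mix.energy(XS) - quad
        # equals the quadratic up to a constant offset
        assert np.max(np.abs(resid - resid.mean())) < 1e-9

    def test_forces_mix_linearly(self, double_well, harmonic):
        mix = linear_mix(double_well, harmonic, 0.25)
        expected = 0.75 * double_well.force(XS) + 0.25 * harmonic.force(XS)
        np.testing.assert_allclose(mix.force(XS), expected, atol=1e-12)


class TestMVP:
    def test_identical_endpoints_recover_potential(self, harmonic, thermo):
        mix = mvp_mix(harmonic, harmonic, 0.37, 1.0, thermo)
        np.testing.assert_allclose(mix.energy(XS), harmonic.energy(XS), atol=1e-10)

    def test_eds_equivalence_at_half(self, double_well, harmonic, thermo):
        """g=1, lam=0.5 equals the EDS reference potential up to a constant."""
        mix = mvp_mix(double_well, harmonic, 0.5, 1.0, thermo)
        eds = -thermo.kT * np.log(0.5 * (np.exp(-thermo.beta * double_well.energy(XS))
                                         + np.exp(-thermo.beta * harmonic.energy(XS))))
        diff = mix.energy(XS) - eds
        assert np.max(np.abs(diff - diff.mean())) < 1e-10

    def test_log_sum_exp_lower_bound(self, double_well, harmonic, thermo):
        mix = mvp_mix(double_well, harmonic, 0.5, 1.0, thermo)
        bound = np.minimum(double_well.energy(XS), harmonic.energy(XS)) + thermo.kT * np.log(2)
        assert np.all(mix.energy(XS) <= bound + 1e-10)

    def test_overflow_safe_far_from_minima(self, double_well, harmonic, thermo):
        x = np.array([-50.0, 50.0])
        assert np.all(np.isfinite(mvp_mix(double_well, harmonic, 0.5, 1.0, thermo).energy(x)))


class TestCorrectedLinear:
    def test_equal_k_shift_removed(self, oscillators, thermo):
        """With the minimum re-pinned, equal-k oscillators mix to a pure
        translated harmonic with zero minimum at every lam."""
        u1, u2 = oscillators
        for lam in (0.2, 0.5, 0.8):
            mix = corrected_linear_mix(u1, u2, lam)
            center = (1 - lam) * u1.center + lam * u2.center
            expected = 0.5 * K_BENCH * (XS - center) ** 2
            np.testing.assert_allclose(mix.energy(XS), expected, atol=1e-8)

    def test_minimum_equals_convex_combination_of_minima(self, double_well, harmonic, bench_grid):
        # both end-state minima are 0, so E(lam) = 0 for every lam
        mix = corrected_linear_mix(double_well, harmonic, 0.5, bench_grid)
        assert float(mix.energy(mix.minimum())) == pytest.approx(0.0, abs=1e-9)
        xs = np.linspace(bench_grid.x_min, bench_grid.x_max, 4001)
        scan_min = float(np.min(mix.energy(xs)))
        assert -1e-9 < scan_min < 1e-4  # scan resolution limits the upper side


class TestGaussianGeodesic:
    def test_endpoints(self):
        m, S = gaussian_barycenter_params(0.0, 1.0, 2.0, 9.0, 0.0)
        assert (m, S) == (pytest.approx(0.0), pytest.approx(1.0))
        m, S = gaussian_barycenter_params(0.0, 1.0, 2.0, 9.0, 1.0)
        assert (m, S) == (pytest.approx(2.0), pytest.approx(9.0))

    def test_equal_covariance_translates(self):
        S0 = np.array([[2.0, 0.3], [0.3, 1.0]])
        m, S = gaussian_barycenter_params([0, 0], S0, [1, 2], S0, 0.7)
        np.testing.assert_allclose(S, S0, atol=1e-12)
        np.testing.assert_allclose(m, [0.7, 1.4])

    def test_1d_sigma_interpolates_linearly(self):
        _, S = gaussian_barycenter_params(0.0, 1.0**2, 0.0, 3.0**2, 0.5)
        assert np.sqrt(S) == pytest.approx(2.0, rel=1e-12)

    def test_non_symmetric_covariance_rejected(self):
        with pytest.raises(ValidationError):
            gaussian_barycenter_params([0, 0], [[1, 0.5], [0.2, 1]], [0, 0], np.eye(2), 0.5)

    def test_matches_numeric_quantile_barycenter(self, thermo):
        """The analytic Gaussian geodesic agrees with the exact numeric 1D
        barycenter of the corresponding Boltzmann densities."""
        h1 = HarmonicPotential(K_BENCH, 0.0)
        h2 = HarmonicPotential(K_BENCH / 4, 0.5)
        grid = Grid1D(-0.8, 1.3, 600)
        p1 = boltzmann_density(h1, thermo, grid)
        p2 = boltzmann_density(h2, thermo, grid)
        lam = 0.5
        bc = quantile_barycenter_1d(p1, p2, lam)
        m, var = gaussian_barycenter_params(0.0, h1.sigma(thermo) ** 2, 0.5,
                                            h2.sigma(thermo) ** 2, lam)
        assert bc.mean() == pytest.approx(m, abs=2 * grid.bin_size)
        assert bc.variance() == pytest.approx(var, rel=0.02)


class TestGaussianOTMix:
    def test_equal_k_pure_translation(self, oscillators, thermo):
        u1, u2 = oscillators
        mix = gaussian_ot_mix(u1, u2, 0.5, thermo)
        expected = 0.5 * K_BENCH * (XS - 0.25) ** 2
        np.testing.assert_allclose(mix.energy(XS), expected, atol=1e-9)
        assert mix.energy(mix.minimum()) == pytest.approx(0.0, abs=1e-12)

    def test_unequal_k_spring_follows_sigma_path(self, thermo):
        h1 = HarmonicPotential(100.0, 0.0)
        h2 = HarmonicPotential(400.0, 0.3)
        lam = 0.6
        mix = gaussian_ot_mix(h1, h2, lam, thermo)
        s_lam = (1 - lam) * h1.sigma(thermo) + lam * h2.sigma(thermo)
        assert mix.spring_l == pytest.approx(thermo.kT / s_lam**2, rel=1e-12)

    def test_density_matches_geodesic_params(self, thermo):
        h1 = HarmonicPotential(100.0, 0.0)
        h2 = HarmonicPotential(400.0, 0.3)
        lam = 0.35
        mix = gaussian_ot_mix(h1, h2, lam, thermo)
        m, var = gaussian_barycenter_params(0.0, h1.sigma(thermo) ** 2, 0.3,
                                            h2.sigma(thermo) ** 2, lam)
        assert mix.center_l == pytest.approx(m, abs=1e-12)
        assert thermo.kT / mix.spring_l == pytest.approx(var, rel=1e-10)

    def test_rejects_non_harmonic(self, double_well, harmonic, thermo):
        with pytest.raises(TypeError):
            gaussian_ot_mix(double_well, harmonic, 0.5, thermo)

    def test_equal_k_density_matches_linear_mix(self, oscillators, thermo):
        """For equal springs the linear and OT Boltzmann densities coincide:
        the spurious term is a pure offset."""
        u1, u2 = oscillators
        grid = Grid1D(-0.5, 1.0, 500)
        for lam in (0.25, 0.5, 0.75):
            p_lin = boltzmann_density(linear_mix(u1, u2, lam), thermo, grid)
            p_ot = boltzmann_density(gaussian_ot_mix(u1, u2, lam, thermo), thermo, grid)
            assert 0.5 * np.abs(p_lin.masses - p_ot.masses).sum() < 1e-10
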