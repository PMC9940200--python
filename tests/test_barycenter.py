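import numpy as np
import pytest

from otfe import (GriddedDensity, Grid1D, boltzmann_density, build_histogram,
                  quantile_barycenter_1d, sinkhorn_debiased_barycenter,
                  w2_distance, wasserstein_potential)
from otfe.exceptions import ValidationError


def tv(p, q):
    return 0.5 * float(np.abs(p.masses - q.masses).sum())


def gauss_on(grid, mu, s):
    x = grid.centers
    m = np.exp(-((x - mu) ** 2) / (2 * s**2))
    return GriddedDensity(grid, m / m.sum())


class TestHistogram:
    def test_single_bin_delta(self):
        grid = Grid1D(0.0, 1.0, 10)
        dens = build_histogram(np.full(50, 0.55), grid)
        assert dens.masses[5] == 1.0
        assert dens.masses.sum() == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            build_histogram([], Grid1D(0, 1, 10))

    def test_outside_samples_reported_not_dropped_silently(self):
        grid = Grid1D(0.0, 1.0, 10)
        dens = build_histogram([0.5, 0.6, 5.0], grid)
        assert dens.n_outside == 1
        assert dens.masses.sum() == pytest.approx(1.0)

    def test_large_sample_matches_analytic_density(self, thermo, harmonic):
        """10^6 exact draws agree with the analytic density within 3-sigma
        multinomial bands per bin."""
        from otfe import sample_boltzmann_direct
        grid = Grid1D(0.0, 1.0, 50)
        n = 10**6
        samples = sample_boltzmann_direct(harmonic, thermo, n, seed=123, grid=grid)
        hist = build_histogram(samples, grid)
        ref = boltzmann_density(harmonic, thermo, grid)
        band = 3 * np.sqrt(ref.masses * (1 - ref.masses) / n)
        # tolerate a small number of marginal 3-sigma excursions
        assert np.sum(np.abs(hist.masses - ref.masses) > band + 1e-12) <= 2


class TestW2Distance:
    def test_identical_densities(self, gaussian_pair):
        p, _ = gaussian_pair
        assert w2_distance(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_translation(self):
        grid = Grid1D(0.0, 1.0, 100)
        a = np.zeros(100); a[10] = 1.0
        b = np.zeros(100); b[60] = 1.0
        d = w2_distance(GriddedDensity(grid, a), GriddedDensity(grid, b))
        assert d == pytest.approx(0.5, abs=grid.bin_size)

    def test_gaussian_closed_form(self, bench_grid):
        p = gauss_on(bench_grid, 0.0, 0.08)
        q = gauss_on(bench_grid, 0.6, 0.15)
        expected = np.hypot(0.6, 0.15 - 0.08)
        assert w2_distance(p, q) == pytest.approx(expected, abs=2 * bench_grid.bin_size)

    def test_unnormalized_rejected(self, bench_grid):
        masses = np.full(bench_grid.n_bins, 1.0 / bench_grid.n_bins)
        good = GriddedDensity(bench_grid, masses)
        bad = GriddedDensity(bench_grid, masses)
        object.__setattr__(bad, "masses", masses * 2)
        with pytest.raises(ValidationError):
            w2_distance(good, bad)


class TestQuantileBarycenter:
    def test_endpoint_recovery(self, gaussian_pair):
        p1, p2 = gaussian_pair
        assert tv(quantile_barycenter_1d(p1, p2, 0.0), p1) < 5e-3

    def test_equal_sigma_gaussians_translate(self, bench_grid):
        p1 = gauss_on(bench_grid, 0.0, 0.1)
        p2 = gauss_on(bench_grid, 0.6, 0.1)
        bc = quantile_barycenter_1d(p1, p2, 0.4)
        ref = gauss_on(bench_grid, 0.24, 0.1)
        assert tv(bc, ref) < 5e-3

    @pytest.mark.parametrize("lam", [0.2, 0.5, 0.8])
    def test_geodesic_proportionality(self, gaussian_pair, lam):
        p1, p2 = gaussian_pair
        bc = quantile_barycenter_1d(p1, p2, lam)
        assert w2_distance(p1, bc) / w2_distance(p1, p2) == pytest.approx(lam, abs=1e-3)

    def test_mean_displacement_interpolates(self, gaussian_pair):
        p1, p2 = gaussian_pair
        lam = 0.3
        bc = quantile_barycenter_1d(p1, p2, lam)
        expected = (1 - lam) * p1.mean() + lam * p2.mean()
        assert bc.mean() == pytest.approx(expected, abs=2 * p1.grid.bin_size)


class TestSinkhornDebiased:
    def test_endpoint_close_to_input(self, gaussian_pair):
        p1, p2 = gaussian_pair
        assert tv(sinkhorn_debiased_barycenter(p1, p2, 0.0), p1) < 0.01

    def test_matches_quantile_oracle_at_half(self, gaussian_pair):
        p1, p2 = gaussian_pair
        sb = sinkhorn_debiased_barycenter(p1, p2, 0.5, reg=0.03)
        qb = quantile_barycenter_1d(p1, p2, 0.5)
        assert tv(sb, qb) < 0.02

    def test_symmetric_inputs_give_symmetric_output(self):
        grid = Grid1D(-1.0, 1.0, 200)
        p1 = gauss_on(grid, -0.4, 0.1)
        p2 = gauss_on(grid, 0.4, 0.1)
        sb = sinkhorn_debiased_barycenter(p1, p2, 0.5)
        np.testing.assert_allclose(sb.masses, sb.masses[::-1], atol=1e-6)

    def test_mass_conserved(self, gaussian_pair):
        p1, p2 = gaussian_pair
        for lam in (0.1, 0.5, 0.9):
            sb = sinkhorn_debiased_barycenter(p1, p2, lam)
            assert abs(sb.masses.sum() - 1.0) < 1e-9

    def test_mean_displacement_interpolates(self, gaussian_pair):
        p1, p2 = gaussian_pair
        lam = 0.7
        sb = sinkhorn_debiased_barycenter(p1, p2, lam)
        expected = (1 - lam) * p1.mean() + lam * p2.mean()
        assert sb.mean() == pytest.approx(expected, abs=3 * p1.grid.bin_size)

    def test_invalid_regularization_rejected(self, gaussian_pair):
        with pytest.raises(ValidationError):
            sinkhorn_debiased_barycenter(*gaussian_pair, 0.5, reg=-1.0)

    def test_oracle_equivalence_randomized(self, bench_grid):
        """Debiased Sinkhorn tracks the exact quantile barycenter over random
        endpoint pairs shaped like the study's densities: a Gaussian or
        bimodal source and a thermal-width Gaussian target. (Features much
        narrower than sqrt(reg) ~ 0.17 nm are below the entropic resolution
        and are out of scope for the default regularization.)"""
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(20):
            p1 = gauss_on(bench_grid, rng.uniform(-0.15, 0.15), rng.uniform(0.08, 0.15))
            p2 = gauss_on(bench_grid, rng.uniform(0.35, 0.75), rng.uniform(0.10, 0.20))
            for lam in np.linspace(0.1, 0.9, 9):
                d = tv(sinkhorn_debiased_barycenter(p1, p2, lam, reg=0.03),
                       quantile_barycenter_1d(p1, p2, lam))
                worst = max(worst, d)
        assert worst < 0.03

    def test_oracle_equivalence_on_study_densities(self, double_well, harmonic,
                                                   thermo, bench_grid):
        """On the benchmark end-state Boltzmann densities themselves the
        debiased barycenter stays within TV 0.03 of the oracle at every
        interior lambda of the 21-window schedule."""
        p1 = boltzmann_density(double_well, thermo, bench_grid)
        p2 = boltzmann_density(harmonic, thermo, bench_grid)
        worst = max(tv(sinkhorn_debiased_barycenter(p1, p2, lam, reg=0.03),
                       quantile_barycenter_1d(p1, p2, lam))
                    for lam in np.linspace(0.05, 0.95, 19))
        assert worst < 0.03


class TestWassersteinPotential:
    def test_gaussian_density_gives_quadratic(self, thermo, bench_grid):
        sigma = 0.12
        p = gauss_on(bench_grid, 0.4, sigma)
        pot = wasserstein_potential(p, thermo)
        x = pot.x
        core = np.abs(x - 0.4) < 2 * sigma
        k_fit = np.polyfit(x[core] - 0.4, pot.values[core], 2)[0] * 2
        assert k_fit == pytest.approx(thermo.kT / sigma**2, rel=0.01)

    def test_uniform_density_gives_constant(self, thermo):
        grid = Grid1D(0, 1, 50)
        p = GriddedDensity(grid, np.full(50, 0.02))
        pot = wasserstein_potential(p, thermo)
        assert np.ptp(pot.values) < 1e-12

    def test_floor_clamps_empty_bins(self, thermo, bench_grid):
        masses = np.zeros(bench_grid.n_bins)
        masses[:10] = 0.1
        p = GriddedDensity(bench_grid, masses)
        pot = wasserstein_potential(p, thermo, floor=1e-12, offset=0.0)
        ceiling = -thermo.kT * np.log(1e-12)
        assert pot.values.max() == pytest.approx(ceiling, rel=1e-9)
        assert np.all(np.isfinite(pot.values))

    def test_offset_rule_pins_minimum(self, thermo, gaussian_pair):
        pot = wasserstein_potential(gaussian_pair[0], thermo, offset=1.25)
        assert pot.values.min() == pytest.approx(1.25, abs=1e-12)

    def test_invalid_floor_rejected(self, thermo, gaussian_pair):
        with pytest.raises(ValidationError):
            wasserstein_potential(gaussian_pair[0], thermo, floor=0.0)
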