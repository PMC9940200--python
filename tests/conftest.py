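import numpy as np
import pytest

from otfe import (DoubleWellPotential, HarmonicPotential, ThermoState,
                  boltzmann_density, default_grid)

#: spring constant of the unit-mass nu = 2.0 ps^-1 oscillator
K_BENCH = HarmonicPotential.from_frequency(2.0).spring_constant


@pytest.fixture(scope="session")
def thermo():
    return ThermoState(300.0)


@pytest.fixture(scope="session")
def double_well():
    return DoubleWellPotential(barrier=1.0, well_position=0.1)


@pytest.fixture(scope="session")
def harmonic():
    return HarmonicPotential.from_frequency(2.0, center=0.5, mass=1.0)


@pytest.fixture(scope="session")
def bench_grid(double_well, harmonic, thermo):
    return default_grid(double_well, harmonic, thermo, n_bins=200)


@pytest.fixture(scope="session")
def gaussian_pair(bench_grid):
    """Two analytic Gaussian densities on the benchmark grid."""
    x = bench_grid.centers

    def gauss(mu, s):
        m = np.exp(-((x - mu) ** 2) / (2 * s**2))
        from otfe import GriddedDensity
        return GriddedDensity(bench_grid, m / m.sum())

    return gauss(0.0, 0.08), gauss(0.6, 0.15)
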