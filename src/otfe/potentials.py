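"""Analytic 1D end-state potentials, forces, Boltzmann densities and exact
free energies.

These potentials are the ground truth of the whole package: every mixing
schedule, sampler and estimator is ultimately validated against adaptive
quadrature of ``exp(-beta U)`` for one of them.

Units are kJ/mol over nm throughout; masses in amu; frequencies in ps^-1.
The spring constant of a harmonic oscillator follows ``k = m (2 pi nu)^2``,
so a unit-mass oscillator at nu = 2.0 ps^-1 has k = 157.91 kJ/(mol nm^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
from scipy import integrate

from .exceptions import ConfigurationError, NumericError, ValidationError
from .grids import Grid1D, GriddedDensity
from .thermo import ThermoState

__all__ = [
    "Potential1D",
    "HarmonicPotential",
    "DoubleWellPotential",
    "MultiParticlePotential",
    "boltzmann_density",
    "partition_function",
    "exact_free_energy_difference",
    "default_grid",
    "potential_from_dict",
]


@runtime_checkable
class Potential1D(Protocol):
    """Anything with a vectorized energy/force over 1D coordinates."""

    def energy(self, x): ...

    def force(self, x): ...

    def minimum(self) -> float:
        """Location (nm) of a global minimum."""
        ...

    def thermal_width(self, thermo: ThermoState) -> float:
        """Characteristic spread (nm) of the Boltzmann density, used to pick
        quadrature bounds and default grids."""
        ...


@dataclass(frozen=True)
class HarmonicPotential:
    """U(x) = (k/2)(x - x0)^2.

    Either ``spring_constant`` is given directly, or derived from a frequency
    via k = m (2 pi nu)^2.
    """

    spring_constant: float
    center: float = 0.0
    mass: float = 1.0

    @classmethod
    def from_frequency(cls, nu: float, center: float = 0.0, mass: float = 1.0) -> "HarmonicPotential":
        if nu <= 0:
            raise ConfigurationError("frequency must be positive")
        return cls(spring_constant=mass * (2.0 * math.pi * nu) ** 2, center=center, mass=mass)

    def __post_init__(self) -> None:
        if self.spring_constant <= 0:
            raise ConfigurationError("spring constant must be positive")

    @property
    def frequency(self) -> float:
        """nu in ps^-1 consistent with k = m (2 pi nu)^2."""
        return math.sqrt(self.spring_constant / self.mass) / (2.0 * math.pi)

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return 0.5 * self.spring_constant * (x - self.center) ** 2

    def force(self, x):
        x = np.asarray(x, dtype=float)
        return -self.spring_constant * (x - self.center)

    def minimum(self) -> float:
        return self.center

    def thermal_width(self, thermo: ThermoState) -> float:
        return math.sqrt(thermo.kT / self.spring_constant)

    def sigma(self, thermo: ThermoState) -> float:
        """Standard deviation of the Boltzmann density, sqrt(kT/k)."""
        return self.thermal_width(thermo)

    def support(self, thermo: ThermoState, n_widths: float = 6.0) -> tuple[float, float]:
        w = n_widths * self.thermal_width(thermo)
        return self.center - w, self.center + w

    def to_dict(self) -> dict:
        return {
            "type": "harmonic",
            "spring_constant": self.spring_constant,
            "center": self.center,
            "mass": self.mass,
        }


@dataclass(frozen=True)
class DoubleWellPotential:
    """Zero-centered quartic double well U(x) = V_max ((x^2 - b^2)/b^2)^2.

    Minima at x = +-b with U = 0, barrier U(0) = V_max.
    """

    barrier: float = 1.0
    well_position: float = 0.1
    mass: float = 1.0

    def __post_init__(self) -> None:
        if self.barrier <= 0 or self.well_position <= 0:
            raise ConfigurationError("barrier and well position must be positive")

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        b2 = self.well_position**2
        return self.barrier * ((x**2 - b2) / b2) ** 2

    def force(self, x):
        x = np.asarray(x, dtype=float)
        b2 = self.well_position**2
        return -4.0 * self.barrier * x * (x**2 - b2) / b2**2

    def minimum(self) -> float:
        return self.well_position

    def curvature_at_minimum(self) -> float:
        # U'' at +-b = 8 V_max / b^2
        return 8.0 * self.barrier / self.well_position**2

    def thermal_width(self, thermo: ThermoState) -> float:
        # in-well thermal spread; see support() for the two-well extent
        return math.sqrt(thermo.kT / self.curvature_at_minimum())

    def support(self, thermo: ThermoState, n_widths: float = 6.0) -> tuple[float, float]:
        w = self.well_position + n_widths * self.thermal_width(thermo)
        return -w, w

    def to_dict(self) -> dict:
        return {
            "type": "double_well",
            "barrier": self.barrier,
            "well_position": self.well_position,
            "mass": self.mass,
        }


@dataclass(frozen=True)
class MultiParticlePotential:
    """Sum of N identical non-interacting 1D potentials.

    ``energy`` accepts arrays whose last axis is the particle index and sums
    over it; free energies are exactly N times the single-particle value.
    """

    base: Potential1D
    n_particles: int

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ConfigurationError("n_particles must be >= 1")

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        if x.shape == () or x.shape[-1] != self.n_particles:
            raise ValidationError(
                f"last axis must index {self.n_particles} particles, got shape {x.shape}"
            )
        return np.asarray(self.base.energy(x)).sum(axis=-1)

    def force(self, x):
        return self.base.force(np.asarray(x, dtype=float))

    def minimum(self) -> float:
        return self.base.minimum()

    def thermal_width(self, thermo: ThermoState) -> float:
        return self.base.thermal_width(thermo)

    def support(self, thermo: ThermoState, n_widths: float = 6.0) -> tuple[float, float]:
        return potential_support(self.base, thermo, n_widths)

    def to_dict(self) -> dict:
        return {"type": "multi_particle", "n_particles": self.n_particles, "base": self.base.to_dict()}


def potential_from_dict(d: dict) -> Potential1D:
    """Rebuild a potential from its plain key-value serialization."""
    tag = d.get("type")
    if tag == "harmonic":
        return HarmonicPotential(d["spring_constant"], d.get("center", 0.0), d.get("mass", 1.0))
    if tag == "double_well":
        return DoubleWellPotential(d["barrier"], d["well_position"], d.get("mass", 1.0))
    if tag == "multi_particle":
        return MultiParticlePotential(potential_from_dict(d["base"]), d["n_particles"])
    raise ConfigurationError(f"unknown potential type {tag!r}")


def _scalar_base(spec: Potential1D) -> Potential1D:
    return spec.base if isinstance(spec, MultiParticlePotential) else spec


def potential_support(spec: Potential1D, thermo: ThermoState,
                      n_widths: float = 6.0) -> tuple[float, float]:
    """Interval outside which exp(-beta U) is negligible at n_widths sigmas."""
    base = _scalar_base(spec)
    if hasattr(base, "support"):
        return base.support(thermo, n_widths)
    w = n_widths * base.thermal_width(thermo)
    return base.minimum() - w, base.minimum() + w


def default_grid(u1: Potential1D, u2: Potential1D, thermo: ThermoState,
                 n_bins: int = 200, n_widths: float = 6.0) -> Grid1D:
    """Grid spanning the union of both end states' +-n_widths supports."""
    lo1, hi1 = potential_support(u1, thermo, n_widths)
    lo2, hi2 = potential_support(u2, thermo, n_widths)
    return Grid1D(min(lo1, lo2), max(hi1, hi2), n_bins)


def boltzmann_density(spec: Potential1D, thermo: ThermoState, grid: Grid1D) -> GriddedDensity:
    """Discretized Boltzmann distribution: masses ~ exp(-beta U) at bin centers."""
    base = _scalar_base(spec)
    u = np.asarray(base.energy(grid.centers), dtype=float)
    # even the best bin must carry representable weight, else the grid has
    # missed the support entirely
    if thermo.beta * u.min() > 700.0:
        raise ValidationError("Boltzmann weights underflow on this grid (degenerate grid)")
    w = np.exp(-thermo.beta * (u - u.min()))
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValidationError("Boltzmann weights underflow on this grid (degenerate grid)")
    return GriddedDensity(grid, w / total)


def partition_function(spec: Potential1D, thermo: ThermoState,
                       bounds: tuple[float, float] | None = None) -> float:
    """Configurational partition function ∫ exp(-beta U) dx by adaptive
    quadrature; for N non-interacting particles, the single-particle integral
    to the power N (units nm^N)."""
    base = _scalar_base(spec)
    n = spec.n_particles if isinstance(spec, MultiParticlePotential) else 1
    if bounds is None:
        lo, hi = potential_support(base, thermo, n_widths=12.0)
    else:
        lo, hi = bounds

    def integrand(x: float) -> float:
        return math.exp(-thermo.beta * float(base.energy(x)))

    z, err = integrate.quad(integrand, lo, hi, epsabs=0.0, epsrel=1e-10, limit=200)
    if not math.isfinite(z) or z <= 0 or err > 1e-6 * z:
        raise NumericError(f"partition function quadrature unreliable: Z={z}, err={err}")
    return z**n


def exact_free_energy_difference(spec_a: Potential1D, spec_b: Potential1D,
                                 thermo: ThermoState) -> float:
    """Delta F = -kT ln(Z_B / Z_A) (kJ/mol), A the lambda=0 state and B the
    lambda=1 state, by adaptive quadrature of both partition functions."""
    za = partition_function(spec_a, thermo)
    zb = partition_function(spec_b, thermo)
    return -thermo.kT * math.log(zb / za)
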