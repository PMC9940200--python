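"""Seeded Langevin dynamics for 1D (or non-interacting N-particle) potentials.

The integrator is the BAOAB splitting of underdamped Langevin dynamics:
velocity half-kick, half-drift, exact Ornstein-Uhlenbeck velocity update,
half-drift, velocity half-kick. At a 10 fs time step this splitting samples
the configurational Boltzmann distribution of the potentials used here with
negligible discretization bias.

Randomness is strictly per particle: particle ``i`` draws its initial
velocity and its whole noise sequence from a generator seeded by
``derive_particle_seed(seed, i)``. A run with N particles is therefore
bit-identical to N single-particle runs with the corresponding seeds, which
is what makes the non-interacting free energy factorization exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import SimulationError, ValidationError
from .grids import Grid1D, GriddedDensity
from .potentials import Potential1D, boltzmann_density
from .thermo import ThermoState

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "run_langevin",
    "sample_boltzmann_direct",
    "derive_particle_seed",
]


def derive_particle_seed(seed: int, particle: int) -> int:
    """Stated seed-splitting rule: child seed for one particle of a run."""
    return int(np.random.SeedSequence([int(seed), int(particle)]).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class SimulationConfig:
    """Langevin run settings (times in ps, temperature in K, mass in amu)."""

    dt: float = 0.01
    n_steps: int = 10000
    temperature: float = 300.0
    friction: float = 1.0
    mass: float = 1.0
    seed: int = 0
    initial_positions: tuple[float, ...] = (0.0,)
    equilibration_steps: int | None = None  # default: 10% of n_steps
    sample_stride: int = 10
    walls: tuple[float, float] | None = None
    particle_seed_offset: int = 0  # particle i draws from derive_particle_seed(seed, i+offset)
    particle_seeds: tuple[int, ...] | None = None  # explicit per-particle seeds (overrides)

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.friction <= 0 or self.mass <= 0:
            raise ValidationError("dt, friction and mass must be positive")
        eq = self.n_steps // 10 if self.equilibration_steps is None else self.equilibration_steps
        if not (self.n_steps > eq >= 0):
            raise ValidationError("need n_steps > equilibration_steps >= 0")
        object.__setattr__(self, "equilibration_steps", eq)
        object.__setattr__(self, "initial_positions", tuple(float(x) for x in self.initial_positions))
        if self.particle_seeds is not None:
            if len(self.particle_seeds) != len(self.initial_positions):
                raise ValidationError("particle_seeds must match initial_positions in length")
            object.__setattr__(self, "particle_seeds", tuple(int(s) for s in self.particle_seeds))
        if self.walls is not None and not np.all(np.asarray(self.walls[0]) < np.asarray(self.walls[1])):
            raise ValidationError("walls must satisfy x_min < x_max")

    @property
    def n_particles(self) -> int:
        return len(self.initial_positions)

    @property
    def thermo(self) -> ThermoState:
        return ThermoState(self.temperature)


@dataclass(frozen=True)
class Trajectory:
    """Strided post-equilibration positions, shape (n_samples, n_particles)."""

    positions: np.ndarray
    velocities: np.ndarray
    seed: int
    config: SimulationConfig

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]

    def flat(self) -> np.ndarray:
        return self.positions.ravel()


def _reflect(x: np.ndarray, v: np.ndarray, lo, hi) -> tuple[np.ndarray, np.ndarray]:
    # reflecting walls (scalar or per-particle); width >> per-step displacement
    below = x < lo
    above = x > hi
    x = np.where(below, 2.0 * lo - x, np.where(above, 2.0 * hi - x, x))
    v = np.where(below | above, -v, v)
    return x, v


def run_langevin(potential: Potential1D, config: SimulationConfig) -> Trajectory:
    """Integrate Langevin dynamics and return strided positions.

    ``potential.force`` is applied elementwise to the particle coordinate
    vector (particles are non-interacting by construction).
    """
    p = config.n_particles
    kT = config.thermo.kT
    dt, m = config.dt, config.mass
    c1 = math.exp(-config.friction * dt)
    c2 = math.sqrt((1.0 - c1 * c1) * kT / m)

    # one generator per particle: the noise stream of particle i depends only
    # on its seed, never on how many particles share the run
    if config.particle_seeds is not None:
        seeds = config.particle_seeds
    else:
        off = config.particle_seed_offset
        seeds = [derive_particle_seed(config.seed, i + off) for i in range(p)]
    gens = [np.random.Generator(np.random.PCG64(s)) for s in seeds]
    v0 = np.array([g.normal(0.0, math.sqrt(kT / m)) for g in gens])

    x = np.array(config.initial_positions, dtype=float)
    v = v0
    f = np.asarray(potential.force(x), dtype=float)
    n_rec = (config.n_steps - config.equilibration_steps) // config.sample_stride
    xs = np.empty((n_rec, p))
    vs = np.empty((n_rec, p))
    walls = config.walls
    k_rec = 0
    half = 0.5 * dt
    block = 16384  # noise drawn per particle in blocks to bound memory
    noise = None
    for step in range(config.n_steps):
        j = step % block
        if j == 0:
            bl = min(block, config.n_steps - step)
            noise = np.column_stack([g.normal(size=bl) for g in gens])
        v = v + half * f / m
        x = x + half * v
        v = c1 * v + c2 * noise[j]
        x = x + half * v
        if walls is not None:
            x, v = _reflect(x, v, walls[0], walls[1])
        f = np.asarray(potential.force(x), dtype=float)
        if not np.all(np.isfinite(f)):
            raise SimulationError(f"non-finite force at step {step}, x={x}")
        v = v + half * f / m
        s = step + 1 - config.equilibration_steps
        if s > 0 and s % config.sample_stride == 0 and k_rec < n_rec:
            xs[k_rec] = x
            vs[k_rec] = v
            k_rec += 1
    return Trajectory(xs[:k_rec], vs[:k_rec], config.seed, config)


def sample_boltzmann_direct(potential: Potential1D, thermo: ThermoState, n: int,
                            seed: int, grid: Grid1D) -> np.ndarray:
    """Exact i.i.d. Boltzmann positions by inverse-CDF sampling on the grid.

    Distribution-wise equivalent to an infinitely long, well-decorrelated MD
    run on the same potential; used as the fast fixture generator for every
    downstream stage.
    """
    if n < 1:
        raise ValidationError("need at least one sample")
    dens = boltzmann_density(potential, thermo, grid)
    return sample_from_density(dens, n, seed)


def sample_from_density(dens: GriddedDensity, n: int, seed: int) -> np.ndarray:
    """Inverse-CDF draws from a gridded density (uniform within bins)."""
    rng = np.random.Generator(np.random.PCG64(int(seed)))
    u = rng.random(n)
    edges = dens.grid.edges
    cdf = dens.cdf_at_edges()
    keep = np.concatenate([[True], np.diff(cdf) > 0])
    return np.interp(u, cdf[keep], edges[keep])
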