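"""Plain-text serialization for every protocol artifact.

All formats are line-oriented text with ``#``-prefixed headers and full
double precision (``%.17g``), so artifacts round-trip bit-exactly:

* densities and gridded potentials: two columns ``x value``;
* kernel models: header carrying gamma/theta/domain plus ``center coefficient``
  columns;
* trajectories: one column per particle plus a JSON sidecar with the
  simulation config and seed;
* potential specs and protocol configs: JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .exceptions import ValidationError
from .grids import Grid1D, GriddedDensity, GriddedPotential
from .kernel import KernelPotentialModel
from .md import SimulationConfig, Trajectory

__all__ = [
    "write_density", "read_density",
    "write_gridded_potential", "read_gridded_potential",
    "write_kernel_model", "read_kernel_model",
    "write_trajectory", "read_trajectory",
    "write_potential_spec", "read_potential_spec",
]

_F = "%.17g"


def _grid_header(grid: Grid1D) -> str:
    return f"# grid {_F % grid.x_min} {_F % grid.x_max} {grid.n_bins}"


def _parse_grid(line: str) -> Grid1D:
    parts = line.split()
    if parts[:2] != ["#", "grid"]:
        raise ValidationError(f"expected grid header, got {line!r}")
    return Grid1D(float(parts[2]), float(parts[3]), int(parts[4]))


def write_density(path, dens: GriddedDensity) -> None:
    with open(path, "w") as fh:
        fh.write(_grid_header(dens.grid) + "\n# x mass\n")
        for x, m in zip(dens.x, dens.masses):
            fh.write(f"{_F % x} {_F % m}\n")


def read_density(path) -> GriddedDensity:
    lines = Path(path).read_text().splitlines()
    grid = _parse_grid(lines[0])
    masses = np.array([float(l.split()[1]) for l in lines[2:]])
    return GriddedDensity(grid, masses)


def write_gridded_potential(path, pot: GriddedPotential) -> None:
    with open(path, "w") as fh:
        fh.write(_grid_header(pot.grid) + f"\n# offset_reference {_F % pot.offset_reference}\n# x energy\n")
        for x, u in zip(pot.x, pot.values):
            fh.write(f"{_F % x} {_F % u}\n")


def read_gridded_potential(path) -> GriddedPotential:
    lines = Path(path).read_text().splitlines()
    grid = _parse_grid(lines[0])
    offset = float(lines[1].split()[2])
    values = np.array([float(l.split()[1]) for l in lines[3:]])
    return GriddedPotential(grid, values, offset)


def write_kernel_model(path, model: KernelPotentialModel) -> None:
    with open(path, "w") as fh:
        dom = model.domain if model.domain is not None else (np.nan, np.nan)
        fh.write(f"# kernel_model gamma {_F % model.gamma} theta {_F % model.theta} "
                 f"n {model.n} domain {_F % dom[0]} {_F % dom[1]}\n# center coefficient\n")
        for c, a in zip(model.centers, model.coefficients):
            fh.write(f"{_F % c} {_F % a}\n")


def read_kernel_model(path) -> KernelPotentialModel:
    lines = Path(path).read_text().splitlines()
    h = lines[0].split()
    if h[:2] != ["#", "kernel_model"]:
        raise ValidationError(f"expected kernel model header, got {lines[0]!r}")
    gamma, theta = float(h[3]), float(h[5])
    lo, hi = float(h[9]), float(h[10])
    domain = None if np.isnan(lo) else (lo, hi)
    pairs = np.array([[float(v) for v in l.split()] for l in lines[2:]])
    return KernelPotentialModel(pairs[:, 0], pairs[:, 1], gamma, theta, domain)


def write_trajectory(path, traj: Trajectory) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# trajectory n_samples {traj.n_samples} n_particles {traj.positions.shape[1]}\n")
        for row in traj.positions:
            fh.write(" ".join(_F % v for v in row) + "\n")
    sidecar = asdict(traj.config)  # includes the seed
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    lines = path.read_text().splitlines()
    pos = np.array([[float(v) for v in l.split()] for l in lines[1:]])
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    meta["initial_positions"] = tuple(meta["initial_positions"])
    if meta.get("walls") is not None:
        meta["walls"] = tuple(meta["walls"])
    if meta.get("particle_seeds") is not None:
        meta["particle_seeds"] = tuple(meta["particle_seeds"])
    cfg = SimulationConfig(**meta)
    return Trajectory(pos, np.full_like(pos, np.nan), cfg.seed, cfg)


def write_potential_spec(path, spec) -> None:
    Path(path).write_text(json.dumps(spec.to_dict(), indent=1))


def read_potential_spec(path):
    from .potentials import potential_from_dict
    return potential_from_dict(json.loads(Path(path).read_text()))
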