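"""Uniform 1D grids and gridded densities/potentials.

The gridded density is the working currency of the optimal-transport stage:
probability mass per bin, attached to bin centers of a uniform grid in nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

_MASS_TOL = 1e-9


@dataclass(frozen=True)
class Grid1D:
    """Uniform grid of ``n_bins`` bins on [x_min, x_max]."""

    x_min: float
    x_max: float
    n_bins: int

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValidationError(f"need at least 2 bins, got {self.n_bins}")
        if not self.x_max > self.x_min:
            raise ValidationError("x_max must exceed x_min")

    @property
    def bin_size(self) -> float:
        return (self.x_max - self.x_min) / self.n_bins

    @property
    def centers(self) -> np.ndarray:
        s = self.bin_size
        return self.x_min + s * (np.arange(self.n_bins) + 0.5)

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.n_bins + 1)


@dataclass(frozen=True)
class GriddedDensity:
    """Normalized probability masses on a uniform grid (sum of masses == 1)."""

    grid: Grid1D
    masses: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.masses, dtype=float)
        if m.shape != (self.grid.n_bins,):
            raise ValidationError(
                f"masses shape {m.shape} does not match grid ({self.grid.n_bins} bins)"
            )
        if np.any(m < 0):
            raise ValidationError("masses must be non-negative")
        total = m.sum()
        if not np.isfinite(total) or abs(total - 1.0) > _MASS_TOL:
            raise ValidationError(f"masses must sum to 1 within {_MASS_TOL}, got {total}")
        object.__setattr__(self, "masses", m)

    @property
    def x(self) -> np.ndarray:
        return self.grid.centers

    def mean(self) -> float:
        return float(self.masses @ self.x)

    def variance(self) -> float:
        mu = self.mean()
        return float(self.masses @ (self.x - mu) ** 2)

    def cdf_at_edges(self) -> np.ndarray:
        """CDF evaluated at the n_bins+1 bin edges (mass uniform within a bin)."""
        return np.concatenate([[0.0], np.cumsum(self.masses)])


@dataclass(frozen=True)
class GriddedPotential:
    """Potential energy values (kJ/mol) at the bin centers of a uniform grid."""

    grid: Grid1D
    values: np.ndarray
    offset_reference: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.n_bins,):
            raise ValidationError("values shape does not match grid")
        if not np.all(np.isfinite(v)):
            raise ValidationError("gridded potential values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def x(self) -> np.ndarray:
        return self.grid.centers
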