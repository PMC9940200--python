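"""Smooth out-of-sample potentials from gridded Wasserstein potentials.

A gridded potential only defines energies at bin centers; to run dynamics on
it we fit a kernel regularized least-squares model,

    U(x) = sum_i alpha_i exp(-gamma (x - x_i)^2),

with the histogram bin centers as basis centers, gamma = 1/(2 s^2) for bin
size s, and ridge coefficient theta (default 1e-5). The coefficients solve
the symmetric positive-definite system (K + theta n I) alpha = y. Both the
energy and its analytic gradient are available everywhere on the real line;
the expansion decays to zero far outside the training support, so simulations
on fitted models should be confined by reflecting walls at the training-grid
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .exceptions import NumericError, ValidationError
from .grids import GriddedPotential
from .thermo import ThermoState

__all__ = ["KernelPotentialModel", "fit_kernel_potential"]


@dataclass(frozen=True)
class KernelPotentialModel:
    """Gaussian-basis expansion of a 1D potential (energies in kJ/mol)."""

    centers: np.ndarray
    coefficients: np.ndarray
    gamma: float
    theta: float
    domain: tuple[float, float] | None = None  # training-grid bounds, for walls

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        a = np.asarray(self.coefficients, dtype=float)
        if c.ndim != 1 or c.shape != a.shape:
            raise ValidationError("centers and coefficients must be matching 1D arrays")
        if self.gamma <= 0 or self.theta < 0:
            raise ValidationError("gamma must be positive and theta non-negative")
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "coefficients", a)

    @property
    def n(self) -> int:
        return self.centers.size

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        d = x[..., None] - self.centers
        return np.exp(-self.gamma * d * d) @ self.coefficients

    def gradient(self, x):
        """dU/dx, analytically: sum_i alpha_i (-2 gamma (x-x_i)) e^{-gamma (x-x_i)^2}."""
        x = np.asarray(x, dtype=float)
        d = x[..., None] - self.centers
        return (np.exp(-self.gamma * d * d) * (-2.0 * self.gamma * d)) @ self.coefficients

    def force(self, x):
        return -self.gradient(x)

    def minimum(self) -> float:
        if self.domain is None:
            lo, hi = float(self.centers.min()), float(self.centers.max())
        else:
            lo, hi = self.domain
        xs = np.linspace(lo, hi, 4 * self.n + 1)
        return float(xs[int(np.argmin(self.energy(xs)))])

    def thermal_width(self, thermo: ThermoState) -> float:
        # crude but sufficient for bracketing: spacing-scale of the basis
        return float(self.centers.max() - self.centers.min()) / 6.0

    def predict(self, x):
        return self.energy(x)

    def predict_gradient(self, x):
        return self.gradient(x)


def fit_kernel_potential(gridded: GriddedPotential, theta: float = 1e-5,
                         gamma: float | None = None) -> KernelPotentialModel:
    """Fit the Gaussian-basis model to a gridded potential.

    ``gamma`` defaults to 1/(2 s^2) for the grid bin size s. The linear
    system (K + theta n I) alpha = y is solved by Cholesky factorization;
    theta=0 is allowed (pure interpolation) and falls back to a symmetric
    indefinite solve if the Cholesky fails.
    """
    x = gridded.x
    y = np.asarray(gridded.values, dtype=float)
    n = x.size
    if n < 2:
        raise ValidationError("need at least 2 training points")
    if not np.all(np.isfinite(y)):
        raise ValidationError("training targets must be finite")
    if gamma is None:
        gamma = 1.0 / (2.0 * gridded.grid.bin_size**2)
    d = x[:, None] - x[None, :]
    K = np.exp(-gamma * d * d)
    A = K + theta * n * np.eye(n)
    try:
        cho = linalg.cho_factor(A, lower=True)
        alpha = linalg.cho_solve(cho, y)
    except linalg.LinAlgError:
        alpha, *_ = linalg.lstsq(A, y)
    resid = A @ alpha - y
    if not np.all(np.isfinite(alpha)) or np.max(np.abs(resid)) > 1e-6 * max(1.0, np.max(np.abs(y))):
        raise NumericError(
            f"kernel system solve unreliable (cond~{np.linalg.cond(A):.2e}, "
            f"max residual {np.max(np.abs(resid)):.2e})"
        )
    return KernelPotentialModel(x, alpha, gamma, theta,
                                domain=(gridded.grid.x_min, gridded.grid.x_max))
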