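"""Lambda-parameterized mixing potentials connecting two end states.

Four schedules are provided:

* ``linear`` — the usual convex combination ``(1-l) U1 + l U2``;
* ``linearC`` — the same with the minimum re-pinned to the convex
  combination of the end-state minima, ``E(l) = (1-l) min U1 + l min U2``,
  which removes the spurious additive shift the plain combination produces;
* ``mvp`` — the minimum-variance path, a convex combination of the
  un-normalized Boltzmann factors,
  ``U = -(1/(g beta)) ln[(1-l) exp(-g beta U1) + l exp(-g beta U2)]``
  (g=1 coincides with envelope distribution sampling at l=0.5 up to a
  constant);
* ``ot`` (Gaussian geodesic) — for harmonic end states, the harmonic
  potential whose Boltzmann density is the 2-Wasserstein displacement
  interpolation between the two end-state Gaussians: the center moves
  linearly and (in 1D) the standard deviation interpolates linearly.

Every mixed potential exposes ``energy``, ``force`` and, where it exists in
closed form, ``dudl`` (the thermodynamic-integration integrand before
averaging).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .exceptions import ConfigurationError, ValidationError
from .grids import Grid1D
from .potentials import HarmonicPotential, Potential1D
from .thermo import ThermoState

__all__ = [
    "linear_mix",
    "corrected_linear_mix",
    "mvp_mix",
    "gaussian_ot_mix",
    "gaussian_barycenter_params",
    "make_schedule",
]


def _check_lambda(lam: float) -> float:
    if not 0.0 <= lam <= 1.0:
        raise ValidationError(f"lambda must lie in [0, 1], got {lam}")
    return float(lam)


@dataclass(frozen=True)
class LinearMixedPotential:
    u1: Potential1D
    u2: Potential1D
    lam: float
    offset: float = 0.0  # subtracted from the raw combination (linearC)

    def energy(self, x):
        l = self.lam
        return (1.0 - l) * np.asarray(self.u1.energy(x)) + l * np.asarray(self.u2.energy(x)) - self.offset

    def force(self, x):
        l = self.lam
        return (1.0 - l) * np.asarray(self.u1.force(x)) + l * np.asarray(self.u2.force(x))

    def dudl(self, x):
        """d/dl at fixed offset: U2 - U1 (the linear TI integrand)."""
        return np.asarray(self.u2.energy(x)) - np.asarray(self.u1.energy(x))

    def thermal_width(self, thermo: ThermoState) -> float:
        return max(self.u1.thermal_width(thermo), self.u2.thermal_width(thermo))

    def minimum(self) -> float:
        lo, hi, _ = _bracket(self.u1, self.u2)
        return _argmin_on_interval(self, lo, hi)


def linear_mix(u1: Potential1D, u2: Potential1D, lam: float) -> LinearMixedPotential:
    """Convex combination of the two end-state potentials."""
    return LinearMixedPotential(u1, u2, _check_lambda(lam))


def _bracket(u1: Potential1D, u2: Potential1D, n_widths: float = 8.0) -> tuple[float, float, float]:
    w = max(u1.thermal_width(ThermoState(300.0)), u2.thermal_width(ThermoState(300.0)))
    centers = [u1.minimum(), u2.minimum(), -u1.minimum(), -u2.minimum()]
    return min(centers) - n_widths * w, max(centers) + n_widths * w, w


def _argmin_on_interval(pot, lo: float, hi: float, n_scan: int = 2001) -> float:
    """Grid scan followed by local refinement of the potential minimum."""
    xs = np.linspace(lo, hi, n_scan)
    us = np.asarray(pot.energy(xs))
    if not np.all(np.isfinite(us)):
        raise ValidationError("potential not finite on the scan interval")
    i = int(np.argmin(us))
    a = xs[max(i - 1, 0)]
    b = xs[min(i + 1, n_scan - 1)]
    res = optimize.minimize_scalar(lambda x: float(pot.energy(x)), bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-12})
    return float(res.x) if res.fun <= us[i] else float(xs[i])


@dataclass(frozen=True)
class CorrectedLinearMixedPotential(LinearMixedPotential):
    """Linear mix shifted so its minimum value equals E(l)."""

    def minimum(self) -> float:
        cached = getattr(self, "_xstar", None)
        if cached is None:
            cached = super().minimum()
            object.__setattr__(self, "_xstar", cached)
        return cached

    def dudl(self, x):
        # envelope theorem: d/dl min_x U_m(x;l) = (U2-U1)(x*) at the argmin
        xstar = self.minimum()
        du_min = float(self.u2.energy(xstar) - self.u1.energy(xstar))
        e_slope = float(self.u2.energy(self.u2.minimum()) - self.u1.energy(self.u1.minimum()))
        return np.asarray(self.u2.energy(x)) - np.asarray(self.u1.energy(x)) - du_min + e_slope


def corrected_linear_mix(u1: Potential1D, u2: Potential1D, lam: float,
                         grid: Grid1D | None = None) -> CorrectedLinearMixedPotential:
    """Linear mix with the minimum pinned to E(l) = (1-l) min U1 + l min U2."""
    lam = _check_lambda(lam)
    raw = LinearMixedPotential(u1, u2, lam)
    if grid is not None:
        lo, hi = grid.x_min, grid.x_max
    else:
        lo, hi, _ = _bracket(u1, u2)
    m = float(raw.energy(_argmin_on_interval(raw, lo, hi)))
    e_lam = (1.0 - lam) * float(u1.energy(u1.minimum())) + lam * float(u2.energy(u2.minimum()))
    return CorrectedLinearMixedPotential(u1, u2, lam, offset=m - e_lam)


@dataclass(frozen=True)
class MVPMixedPotential:
    u1: Potential1D
    u2: Potential1D
    lam: float
    g: float
    thermo: ThermoState

    def _log_terms(self, x):
        gb = self.g * self.thermo.beta
        a1 = np.log1p(-self.lam) - gb * np.asarray(self.u1.energy(x)) if self.lam < 1 else None
        a2 = math.log(self.lam) - gb * np.asarray(self.u2.energy(x)) if self.lam > 0 else None
        return a1, a2, gb

    def energy(self, x):
        a1, a2, gb = self._log_terms(x)
        if a1 is None:
            return np.asarray(self.u2.energy(x))
        if a2 is None:
            return np.asarray(self.u1.energy(x))
        m = np.maximum(a1, a2)
        return -(m + np.log(np.exp(a1 - m) + np.exp(a2 - m))) / gb

    def _weights(self, x):
        """Softmax weights of the two end states at each x."""
        a1, a2, _ = self._log_terms(x)
        if a1 is None:
            return 0.0, 1.0
        if a2 is None:
            return 1.0, 0.0
        m = np.maximum(a1, a2)
        e1, e2 = np.exp(a1 - m), np.exp(a2 - m)
        z = e1 + e2
        return e1 / z, e2 / z

    def force(self, x):
        w1, w2 = self._weights(x)
        return w1 * np.asarray(self.u1.force(x)) + w2 * np.asarray(self.u2.force(x))

    def dudl(self, x):
        if not 0.0 < self.lam < 1.0:
            raise ValidationError("MVP dU/dl defined for interior lambda only")
        a1, a2, gb = self._log_terms(x)
        # d/dl of -ln[(1-l)e^{-gbU1} + l e^{-gbU2}] / gb
        m = np.maximum(a1, a2)
        e1, e2 = np.exp(a1 - m), np.exp(a2 - m)
        return -(e2 / self.lam - e1 / (1.0 - self.lam)) / (gb * (e1 + e2))

    def thermal_width(self, thermo: ThermoState) -> float:
        return max(self.u1.thermal_width(thermo), self.u2.thermal_width(thermo))

    def minimum(self) -> float:
        lo, hi, _ = _bracket(self.u1, self.u2)
        return _argmin_on_interval(self, lo, hi)


def mvp_mix(u1: Potential1D, u2: Potential1D, lam: float, g: float = 1.0,
            thermo: ThermoState = ThermoState(300.0)) -> MVPMixedPotential:
    """Minimum-variance path mixing (overflow-safe log-sum-exp form)."""
    if g <= 0:
        raise ValidationError("MVP exponent g must be positive")
    return MVPMixedPotential(u1, u2, _check_lambda(lam), float(g), thermo)


def gaussian_barycenter_params(m1, s1, m2, s2, lam: float):
    """Displacement-interpolation mean and covariance between two Gaussians.

    Means interpolate linearly; the covariance follows the Wasserstein
    geodesic ``((1-l) I + l A) S1 ((1-l) I + l A)^T`` with ``A`` the optimal
    transport map matrix between the two Gaussians. Scalars are accepted as
    1x1 covariances (standard deviations squared are the caller's business:
    here ``s1``/``s2`` ARE covariance matrices or variances).
    """
    lam = _check_lambda(lam)
    m1 = np.atleast_1d(np.asarray(m1, dtype=float))
    m2 = np.atleast_1d(np.asarray(m2, dtype=float))
    S1 = np.atleast_2d(np.asarray(s1, dtype=float))
    S2 = np.atleast_2d(np.asarray(s2, dtype=float))
    for S in (S1, S2):
        if not np.allclose(S, S.T, atol=1e-12):
            raise ValidationError("covariance must be symmetric")
    d = S1.shape[0]
    # A = S1^{-1/2} (S1^{1/2} S2 S1^{1/2})^{1/2} S1^{-1/2}, with pseudoinverse
    # square roots when (near-)singular
    r1 = _psd_sqrt(S1)
    r1_inv = _psd_pinv_sqrt(S1)
    mid = _psd_sqrt(r1 @ S2 @ r1)
    A = r1_inv @ mid @ r1_inv
    T = (1.0 - lam) * np.eye(d) + lam * A
    S_lam = T @ S1 @ T.T
    m_lam = (1.0 - lam) * m1 + lam * m2
    if m_lam.size == 1:
        return float(m_lam[0]), S_lam if d > 1 else float(S_lam[0, 0])
    return m_lam, S_lam


def _psd_sqrt(S: np.ndarray) -> np.ndarray:
    w, v = linalg.eigh(S)
    w = np.clip(w, 0.0, None)
    return (v * np.sqrt(w)) @ v.T


def _psd_pinv_sqrt(S: np.ndarray, rcond: float = 1e-10) -> np.ndarray:
    w, v = linalg.eigh(S)
    w = np.clip(w, 0.0, None)
    cutoff = rcond * w.max() if w.max() > 0 else 0.0
    inv = np.where(w > cutoff, 1.0 / np.sqrt(np.where(w > 0, w, 1.0)), 0.0)
    return (v * inv) @ v.T


@dataclass(frozen=True)
class GaussianOTMixedPotential:
    """Harmonic potential tracing the Gaussian Wasserstein geodesic.

    In 1D: center m_l = (1-l) x1 + l x2, sigma_l = (1-l) s1 + l s2, spring
    k_l = kT / sigma_l^2. Equal-spring end states reduce to translating the
    center, with no additive shift.
    """

    h1: HarmonicPotential
    h2: HarmonicPotential
    lam: float
    thermo: ThermoState
    center_l: float = field(init=False)
    spring_l: float = field(init=False)

    def __post_init__(self) -> None:
        l = self.lam
        s1, s2 = self.h1.sigma(self.thermo), self.h2.sigma(self.thermo)
        s_l = (1.0 - l) * s1 + l * s2
        object.__setattr__(self, "center_l", (1.0 - l) * self.h1.center + l * self.h2.center)
        object.__setattr__(self, "spring_l", self.thermo.kT / s_l**2)

    def energy(self, x):
        return 0.5 * self.spring_l * (np.asarray(x, dtype=float) - self.center_l) ** 2

    def force(self, x):
        return -self.spring_l * (np.asarray(x, dtype=float) - self.center_l)

    def dudl(self, x):
        x = np.asarray(x, dtype=float)
        s1, s2 = self.h1.sigma(self.thermo), self.h2.sigma(self.thermo)
        s_l = (1.0 - self.lam) * s1 + self.lam * s2
        dk = -2.0 * self.thermo.kT * (s2 - s1) / s_l**3
        dm = self.h2.center - self.h1.center
        return 0.5 * dk * (x - self.center_l) ** 2 - self.spring_l * (x - self.center_l) * dm

    def thermal_width(self, thermo: ThermoState) -> float:
        return math.sqrt(thermo.kT / self.spring_l)

    def minimum(self) -> float:
        return self.center_l

    def as_harmonic(self) -> HarmonicPotential:
        return HarmonicPotential(self.spring_l, self.center_l)


def gaussian_ot_mix(h1: Potential1D, h2: Potential1D, lam: float,
                    thermo: ThermoState = ThermoState(300.0)) -> GaussianOTMixedPotential:
    """Analytic optimal-transport mixing of two harmonic oscillators."""
    if not isinstance(h1, HarmonicPotential) or not isinstance(h2, HarmonicPotential):
        raise TypeError("gaussian_ot_mix requires harmonic end states")
    return GaussianOTMixedPotential(h1, h2, _check_lambda(lam), thermo)


_SCHEDULES = ("linear", "linearC", "mvp", "ot")


def make_schedule(tag: str, u1: Potential1D, u2: Potential1D,
                  thermo: ThermoState = ThermoState(300.0), g: float = 1.0,
                  grid: Grid1D | None = None):
    """Return a callable lam -> mixed potential for one of the analytic
    schedules ('linear', 'linearC', 'mvp', 'ot')."""
    if tag == "linear":
        return lambda lam: linear_mix(u1, u2, lam)
    if tag == "linearC":
        return lambda lam: corrected_linear_mix(u1, u2, lam, grid)
    if tag == "mvp":
        return lambda lam: mvp_mix(u1, u2, lam, g, thermo)
    if tag == "ot":
        return lambda lam: gaussian_ot_mix(u1, u2, lam, thermo)
    raise ConfigurationError(f"unknown schedule {tag!r}; expected one of {_SCHEDULES}")
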