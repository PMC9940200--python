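"""Free energy estimators: thermodynamic integration, the Bennett acceptance
ratio, cumulative lambda-profiles and repeat-based confidence intervals.

TI integrates the ensemble average of dU/dlambda over the coupling
parameter; expectations can come either from samples or from adaptive
quadrature against the exact Boltzmann density of each window (the
quadrature route is the deterministic oracle used throughout the tests).

BAR solves Bennett's implicit equation for the free energy difference of a
window pair from forward and reverse potential-energy differences; it is the
estimator of record for the simulated pipeline, since the numeric
optimal-transport schedule has no analytic dU/dlambda.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, stats

from .exceptions import NumericError, ValidationError
from .potentials import potential_support
from .thermo import ThermoState

__all__ = [
    "WindowEnergies",
    "FreeEnergyResult",
    "ti_free_energy",
    "ti_integrand_quadrature",
    "analytic_linear_ti_integrand",
    "linear_path_barrier",
    "bar_estimate",
    "profile_along_lambda",
    "repeat_ci",
]


# ---------------------------------------------------------------------------
# thermodynamic integration


def _dudl(pot, lam_factory, lam: float, x, dlam: float = 1e-4):
    """dU/dlambda at positions x: analytic if the mixed potential provides
    it, otherwise central difference across neighbouring lambda values."""
    if hasattr(pot, "dudl"):
        try:
            return np.asarray(pot.dudl(x))
        except ValidationError:
            pass  # schedules without an endpoint derivative fall through
    lo = max(0.0, lam - dlam)
    hi = min(1.0, lam + dlam)
    return (np.asarray(lam_factory(hi).energy(x)) - np.asarray(lam_factory(lo).energy(x))) / (hi - lo)


def ti_integrand_quadrature(lam_factory, lam: float, thermo: ThermoState,
                            bounds: tuple[float, float] | None = None) -> float:
    """Exact Boltzmann expectation of dU/dlambda at one lambda, by adaptive
    quadrature over the window's own equilibrium density."""
    pot = lam_factory(lam)
    if bounds is None:
        bounds = potential_support(pot, thermo, n_widths=12.0)
    lo, hi = bounds
    xref = pot.minimum()
    uref = float(pot.energy(xref))

    def weight(x: float) -> float:
        return math.exp(-thermo.beta * (float(pot.energy(x)) - uref))

    def numer(x: float) -> float:
        return float(_dudl(pot, lam_factory, lam, x)) * weight(x)

    z, _ = integrate.quad(weight, lo, hi, epsabs=0.0, epsrel=1e-10, limit=200)
    top, _ = integrate.quad(numer, lo, hi, epsabs=1e-13, epsrel=1e-10, limit=200)
    if z <= 0 or not math.isfinite(top):
        raise NumericError(f"TI bracket quadrature failed at lambda={lam}")
    return top / z


def ti_free_energy(lam_factory, lambdas, thermo: ThermoState,
                   sampler: str | dict = "quadrature") -> tuple[float, np.ndarray]:
    """Trapezoidal TI of <dU/dlambda> over the lambda grid.

    ``sampler`` is either the string ``"quadrature"`` (exact expectations) or
    a mapping lambda -> 1D position samples drawn from that window.
    Returns (total Delta F, per-lambda integrand values).
    """
    lambdas = np.asarray(lambdas, dtype=float)
    vals = np.empty_like(lambdas)
    for i, lam in enumerate(lambdas):
        if isinstance(sampler, str) and sampler == "quadrature":
            vals[i] = ti_integrand_quadrature(lam_factory, lam, thermo)
        else:
            x = np.ravel(np.asarray(sampler[lam]))
            vals[i] = float(np.mean(_dudl(lam_factory(lam), lam_factory, lam, x)))
        if not math.isfinite(vals[i]):
            raise NumericError(f"non-finite TI bracket at lambda={lam}")
    return float(np.trapezoid(vals, lambdas)), vals


def ti_free_energy_adaptive(lam_factory, thermo: ThermoState,
                            epsrel: float = 1e-6) -> float:
    """TI with adaptive quadrature over lambda as well as over x.

    Needed when the integrand varies sharply in lambda (e.g. mixing two
    potentials of very different stiffness), where a fixed trapezoid grid
    underresolves the path.
    """
    val, err = integrate.quad(
        lambda lam: ti_integrand_quadrature(lam_factory, lam, thermo),
        0.0, 1.0, epsabs=1e-10, epsrel=epsrel, limit=400)
    if not math.isfinite(val):
        raise NumericError("adaptive TI over lambda failed")
    return float(val)


def analytic_linear_ti_integrand(k: float, x1: float, x2: float, lam: float,
                                 thermo: ThermoState | None = None) -> float:
    """Closed-form linear-schedule TI integrand for equal-spring oscillators:
    (k/2)(1 - 2 lambda)(x1 - x2)^2. Integrates to zero over [0, 1]; its value
    is temperature independent."""
    return 0.5 * k * (1.0 - 2.0 * lam) * (x1 - x2) ** 2


def linear_path_barrier(k1: float, k2: float, x1: float, x2: float) -> float:
    """Free-energy excursion at lambda=0.5 of the linear schedule for two
    equal-spring oscillators: k (x1-x2)^2 / 8; grows without bound in the
    center gap."""
    if not math.isclose(k1, k2, rel_tol=1e-12):
        raise ValidationError("closed form requires equal spring constants")
    return k1 * (x1 - x2) ** 2 / 8.0


# ---------------------------------------------------------------------------
# Bennett acceptance ratio


@dataclass(frozen=True)
class WindowEnergies:
    """Forward/reverse potential-energy differences for one window pair.

    ``forward`` holds U_{i+1}-U_i evaluated on samples of window i;
    ``reverse`` holds U_{i+1}-U_i evaluated on samples of window i+1 (note:
    same difference, opposite ensemble).
    """

    forward: np.ndarray
    reverse: np.ndarray
    beta: float

    def __post_init__(self) -> None:
        f = np.ravel(np.asarray(self.forward, dtype=float))
        r = np.ravel(np.asarray(self.reverse, dtype=float))
        if f.size == 0 or r.size == 0:
            raise ValidationError("both sample sets must be non-empty")
        if not (np.all(np.isfinite(f)) and np.all(np.isfinite(r))):
            raise ValidationError("energy differences must be finite")
        object.__setattr__(self, "forward", f)
        object.__setattr__(self, "reverse", r)


def _fermi(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = np.exp(-x[pos]) / (1.0 + np.exp(-x[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(x[~pos]))
    return out


def bar_estimate(w: WindowEnergies, tol: float = 1e-8, max_iter: int = 200
                 ) -> tuple[float, float]:
    """Solve Bennett's implicit equation for Delta F (kJ/mol) and return the
    asymptotic standard error.

    The root of
        sum_F fermi(M + beta dU_F - beta dF) - sum_R fermi(-M - beta dU_R + beta dF) = 0,
    with M = ln(n_F/n_R), is bracketed by expanding around the exponential-
    averaging estimates and found with Brent's method.
    """
    beta = w.beta
    wf, wr = w.forward, w.reverse
    nf, nr = wf.size, wr.size
    M = math.log(nf / nr)

    def g(dF: float) -> float:
        return float(_fermi(M + beta * (wf - dF)).sum() - _fermi(-M - beta * (wr - dF)).sum())

    # g is monotone increasing in dF; expand a bracket around a rough guess
    guess = 0.5 * (float(np.mean(wf)) + float(np.mean(wr)))
    width = max(1.0, 4.0 * float(np.std(np.concatenate([wf, wr]))))
    lo, hi = guess - width, guess + width
    for _ in range(80):
        if g(lo) < 0.0:
            break
        lo -= width
        width *= 2.0
    else:
        raise NumericError("BAR bracketing failed on the low side")
    width = max(1.0, 4.0 * float(np.std(np.concatenate([wf, wr]))))
    for _ in range(80):
        if g(hi) > 0.0:
            break
        hi += width
        width *= 2.0
    else:
        raise NumericError("BAR bracketing failed on the high side")
    dF = float(optimize.brentq(g, lo, hi, xtol=tol, maxiter=max_iter))

    # asymptotic variance (Bennett 1976): overlap-weighted second moments
    ff = _fermi(M + beta * (wf - dF))
    fr = _fermi(-M - beta * (wr - dF))
    with np.errstate(divide="ignore"):
        var = (np.mean(ff**2) / np.mean(ff) ** 2 - 1.0) / nf + \
              (np.mean(fr**2) / np.mean(fr) ** 2 - 1.0) / nr
    stderr = math.sqrt(max(var, 0.0)) / beta
    return dF, stderr


def overlap_measure(w: WindowEnergies, dF: float) -> float:
    """Mean acceptance-function overlap of the two work distributions."""
    beta = w.beta
    M = math.log(w.forward.size / w.reverse.size)
    return float(min(np.mean(_fermi(M + beta * (w.forward - dF))),
                     np.mean(_fermi(-M - beta * (w.reverse - dF)))))


# ---------------------------------------------------------------------------
# aggregation


def profile_along_lambda(per_window: np.ndarray) -> np.ndarray:
    """Cumulative free energy profile: prefix sums anchored at 0 for lambda=0."""
    per_window = np.asarray(per_window, dtype=float)
    return np.concatenate([[0.0], np.cumsum(per_window)])


def repeat_ci(totals, level: float = 0.95) -> tuple[float, float]:
    """Mean and Student-t half-width over independent repeats.

    With 3 repeats at the 95% level the multiplier is t_{0.975,2} = 4.3027.
    """
    totals = np.asarray(list(totals), dtype=float)
    n = totals.size
    if n < 2:
        raise ValidationError("need at least 2 repeats for a confidence interval")
    mean = float(np.mean(totals))
    if level <= 0:
        return mean, 0.0
    tmult = float(stats.t.ppf(0.5 * (1.0 + level), n - 1))
    half = tmult * float(np.std(totals, ddof=1)) / math.sqrt(n)
    return mean, half


@dataclass(frozen=True)
class FreeEnergyResult:
    """Aggregate of one schedule's protocol run."""

    schedule: str
    lambdas: np.ndarray
    per_window: np.ndarray        # mean over repeats, one entry per window pair
    profile: np.ndarray           # cumulative, len(lambdas)
    total: float
    repeat_totals: np.ndarray
    ci_halfwidth: float

    @property
    def max_excursion(self) -> float:
        """Largest |cumulative profile| along the path."""
        return float(np.max(np.abs(self.profile)))
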