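"""The end-to-end window protocol and the schedule-comparison benchmark.

For the numeric optimal-transport schedule the five stages are:

1. sample the two end-state potentials (plain Langevin MD, or exact
   inverse-CDF Boltzmann draws for cheap runs);
2. histogram both sample sets on a common grid;
3. for each interior lambda, compute the debiased Sinkhorn barycenter and
   its Wasserstein potential (offset-aligned to the end-state minima);
4. fit a Gaussian-basis kernel model to each Wasserstein potential so the
   window has a smooth, differentiable out-of-sample energy;
5. run Langevin dynamics in every window, cross-evaluate neighbouring
   window energies, and estimate each window pair's free energy with BAR;
   the window sum is the total free energy difference.

The analytic schedules (linear, linearC, mvp) skip stages 2-4 and simulate
the mixed potential directly. Endpoint windows (lambda = 0, 1) always use
the original end-state potentials. Repeats re-run everything (including the
end-state sampling and barycenters) with fresh seeds; the headline
uncertainty is the Student-t interval over repeat totals.

Everything is reproducible from the master seed: window ``w`` of repeat
``r`` under schedule index ``s`` uses the seed stream
``SeedSequence([master, s, r, w])``, split further per particle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .barycenter import build_histogram, sinkhorn_debiased_barycenter, wasserstein_potential
from .estimators import (FreeEnergyResult, WindowEnergies, bar_estimate,
                         profile_along_lambda, repeat_ci)
from .exceptions import ConfigurationError, OTFEError
from .kernel import fit_kernel_potential
from .md import (SimulationConfig, derive_particle_seed, run_langevin,
                 sample_boltzmann_direct)
from .mixing import make_schedule
from .potentials import (MultiParticlePotential, Potential1D, default_grid,
                         exact_free_energy_difference)
from .thermo import ThermoState

__all__ = ["ProtocolConfig", "run_protocol", "reproduce_table", "barrier_report",
           "stream_seed"]

#: schedule tags in canonical order (index feeds the seed stream)
SCHEDULES = ("linear", "linearC", "mvp", "ot")


def stream_seed(master: int, *path: int) -> int:
    """Deterministic child seed (< 2^31) for one node of the seed tree."""
    ss = np.random.SeedSequence([int(master), *[int(p) for p in path]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class ProtocolConfig:
    """Benchmark/protocol settings.

    ``u1``/``u2`` are the scalar (single-coordinate) end-state potentials;
    ``n_particles`` replicates them as a non-interacting sum. Times in ns,
    time step in ps.
    """

    u1: Potential1D
    u2: Potential1D
    n_particles: int = 1
    n_lambdas: int = 21
    window_time_ns: float = 0.1
    endpoint_time_ns: float = 2.0
    schedules: tuple[str, ...] = SCHEDULES
    n_repeats: int = 3
    seed: int = 0
    temperature: float = 300.0
    dt_ps: float = 0.01
    friction: float = 1.0
    sample_stride: int = 10
    equilibration_fraction: float = 0.1
    n_bins: int = 200
    reg: float = 0.03
    theta: float = 1e-5
    mvp_g: float = 1.0
    endpoint_sampler: str = "md"          # "md" or "exact"
    exact_endpoint_samples: int = 20000

    def __post_init__(self) -> None:
        if self.n_lambdas < 2:
            raise ConfigurationError("need at least 2 lambda windows")
        if self.n_repeats < 1:
            raise ConfigurationError("need at least 1 repeat")
        unknown = set(self.schedules) - set(SCHEDULES)
        if unknown:
            raise ConfigurationError(f"unknown schedules {sorted(unknown)}; choose from {SCHEDULES}")
        if self.endpoint_sampler not in ("md", "exact"):
            raise ConfigurationError("endpoint_sampler must be 'md' or 'exact'")

    @property
    def thermo(self) -> ThermoState:
        return ThermoState(self.temperature)

    @property
    def lambdas(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_lambdas)

    def steps(self, time_ns: float) -> int:
        return int(round(time_ns * 1000.0 / self.dt_ps))


def _total_delta(pot_hi, pot_lo, x: np.ndarray) -> np.ndarray:
    """U_hi - U_lo summed over the particle axis, one value per frame."""
    d = np.asarray(pot_hi.energy(x)) - np.asarray(pot_lo.energy(x))
    return d.sum(axis=-1) if d.ndim > 1 else d


def _endpoint_samples(cfg: ProtocolConfig, pot, grid, seed: int) -> np.ndarray:
    if cfg.endpoint_sampler == "exact":
        return sample_boltzmann_direct(pot, cfg.thermo, cfg.exact_endpoint_samples, seed, grid)
    n_steps = cfg.steps(cfg.endpoint_time_ns)
    sim = SimulationConfig(dt=cfg.dt_ps, n_steps=n_steps, temperature=cfg.temperature,
                           friction=cfg.friction, seed=seed,
                           initial_positions=(pot.minimum(),),
                           equilibration_steps=int(cfg.equilibration_fraction * n_steps),
                           sample_stride=cfg.sample_stride)
    return run_langevin(pot, sim).flat()


def _ot_window_potentials(cfg: ProtocolConfig, grid, repeat: int) -> list:
    """Stages 1-4 for one repeat of the numeric OT schedule."""
    thermo = cfg.thermo
    s_idx = SCHEDULES.index("ot")
    x1 = _endpoint_samples(cfg, cfg.u1, grid, stream_seed(cfg.seed, s_idx, repeat, 1000))
    x2 = _endpoint_samples(cfg, cfg.u2, grid, stream_seed(cfg.seed, s_idx, repeat, 1001))
    p1 = build_histogram(x1, grid)
    p2 = build_histogram(x2, grid)
    e1 = float(cfg.u1.energy(cfg.u1.minimum()))
    e2 = float(cfg.u2.energy(cfg.u2.minimum()))
    windows: list = []
    for lam in cfg.lambdas:
        if lam == 0.0:
            windows.append(cfg.u1)
        elif lam == 1.0:
            windows.append(cfg.u2)
        else:
            p_lam = sinkhorn_debiased_barycenter(p1, p2, lam, reg=cfg.reg)
            u_lam = wasserstein_potential(p_lam, thermo,
                                          offset=(1.0 - lam) * e1 + lam * e2)
            windows.append(fit_kernel_potential(u_lam, theta=cfg.theta))
    return windows


def _analytic_window_potentials(cfg: ProtocolConfig, tag: str, grid) -> list:
    factory = make_schedule(tag, cfg.u1, cfg.u2, cfg.thermo, g=cfg.mvp_g, grid=grid)
    windows: list = []
    for lam in cfg.lambdas:
        if lam == 0.0:
            windows.append(cfg.u1)
        elif lam == 1.0:
            windows.append(cfg.u2)
        else:
            windows.append(factory(lam))
    return windows


class _BatchedWindows:
    """Vectorized force over a flat batch of (repeat, window, particle).

    Every coordinate of every window and repeat of a schedule evolves
    independently, so stage 5 runs them as one Langevin batch. Per-element
    seed streams make the result bit-identical to simulating each window
    separately with the documented seed tree.
    """

    def __init__(self, cfg: ProtocolConfig, windows_per_repeat: list[list],
                 tag: str):
        self.cfg = cfg
        self.tag = tag
        self.u1, self.u2 = cfg.u1, cfg.u2
        n = cfg.n_particles
        lam = np.repeat(np.tile(cfg.lambdas, cfg.n_repeats), n)
        self.lam = lam
        self.is_first = lam == 0.0
        self.is_last = lam == 1.0
        kern_rows = []
        any_kernel = any(hasattr(p, "coefficients")
                         for ws in windows_per_repeat for p in ws)
        if any_kernel:
            coeffs, gamma, centers = [], None, None
            for ws in windows_per_repeat:
                for pot in ws:
                    if hasattr(pot, "coefficients"):
                        coeffs.append(pot.coefficients)
                        gamma, centers = pot.gamma, pot.centers
                        kern_rows.extend([len(coeffs) - 1] * n)
                    else:
                        kern_rows.extend([-1] * n)
            self.gamma = gamma
            self.centers = centers
            self.A = np.vstack(coeffs)
            self.rows = np.asarray(kern_rows)
            self.Arows = np.where((self.rows >= 0)[:, None],
                                  self.A[np.maximum(self.rows, 0)], 0.0)
        else:
            self.Arows = None

    def force(self, x):
        x = np.asarray(x, dtype=float)
        f1 = np.asarray(self.u1.force(x))
        f2 = np.asarray(self.u2.force(x))
        if self.Arows is not None:   # numeric OT: kernel rows + analytic ends
            d = x[:, None] - self.centers
            g = np.exp(-self.gamma * d * d)
            fk = 2.0 * self.gamma * np.einsum("ij,ij->i", g * d, self.Arows)
            return np.where(self.is_first, f1, np.where(self.is_last, f2, fk))
        tag = self.tag
        lam = self.lam
        if tag == "ot":  # degenerate: only endpoint windows
            return np.where(self.is_first, f1, f2)
        if tag in ("linear", "linearC"):
            return (1.0 - lam) * f1 + lam * f2
        # mvp: Boltzmann-factor softmax weights, overflow-safe
        gb = self.cfg.mvp_g * self.cfg.thermo.beta
        with np.errstate(divide="ignore"):
            a1 = np.log(1.0 - lam) - gb * np.asarray(self.u1.energy(x))
            a2 = np.log(lam) - gb * np.asarray(self.u2.energy(x))
        m = np.maximum(a1, a2)
        e1, e2 = np.exp(a1 - m), np.exp(a2 - m)
        z = e1 + e2
        return (e1 * f1 + e2 * f2) / z


def _simulate_schedule(cfg: ProtocolConfig, tag: str,
                       windows_per_repeat: list[list], grid, s_idx: int
                       ) -> list[list[np.ndarray]]:
    """Stage 5 sampling for one schedule: a single batched Langevin run
    covering every (repeat, window, particle); returns per-repeat lists of
    per-window sample arrays of shape (n_samples, n_particles)."""
    n_steps = cfg.steps(cfg.window_time_ns)
    n = cfg.n_particles
    seeds, x0, lo, hi = [], [], [], []
    for r, windows in enumerate(windows_per_repeat):
        for w, pot in enumerate(windows):
            xm = float(pot.minimum())
            kern = hasattr(pot, "coefficients")
            for p_idx in range(n):
                seeds.append(derive_particle_seed(stream_seed(cfg.seed, s_idx, r, w), p_idx))
                x0.append(xm)
                lo.append(grid.x_min if kern else -np.inf)
                hi.append(grid.x_max if kern else np.inf)
    batch = _BatchedWindows(cfg, windows_per_repeat, tag)
    sim = SimulationConfig(
        dt=cfg.dt_ps, n_steps=n_steps, temperature=cfg.temperature,
        friction=cfg.friction, seed=cfg.seed,
        initial_positions=tuple(x0), particle_seeds=tuple(seeds),
        equilibration_steps=int(cfg.equilibration_fraction * n_steps),
        sample_stride=cfg.sample_stride,
        walls=(np.asarray(lo), np.asarray(hi)))
    pos = run_langevin(batch, sim).positions  # (n_rec, R*W*N)
    w_count = cfg.n_lambdas
    out = []
    for r in range(cfg.n_repeats):
        base = r * w_count * n
        out.append([pos[:, base + w * n: base + (w + 1) * n] for w in range(w_count)])
    return out


def _bar_totals(cfg: ProtocolConfig, windows: list, trajs: list[np.ndarray]
                ) -> np.ndarray:
    beta = cfg.thermo.beta
    per_window = np.empty(len(windows) - 1)
    for i in range(len(windows) - 1):
        fwd = _total_delta(windows[i + 1], windows[i], trajs[i])
        rev = _total_delta(windows[i + 1], windows[i], trajs[i + 1])
        per_window[i], _ = bar_estimate(WindowEnergies(fwd, rev, beta))
    return per_window


def run_protocol(cfg: ProtocolConfig) -> dict[str, FreeEnergyResult]:
    """Run every requested schedule; returns one FreeEnergyResult per tag."""
    grid = default_grid(cfg.u1, cfg.u2, cfg.thermo, cfg.n_bins)
    results: dict[str, FreeEnergyResult] = {}
    for tag in cfg.schedules:
        s_idx = SCHEDULES.index(tag)
        try:
            if tag == "ot":
                windows_per_repeat = [_ot_window_potentials(cfg, grid, r)
                                      for r in range(cfg.n_repeats)]
            else:
                shared = _analytic_window_potentials(cfg, tag, grid)
                windows_per_repeat = [shared] * cfg.n_repeats
            trajs = _simulate_schedule(cfg, tag, windows_per_repeat, grid, s_idx)
            window_sums = [_bar_totals(cfg, windows_per_repeat[r], trajs[r])
                           for r in range(cfg.n_repeats)]
        except OTFEError as exc:
            raise type(exc)(f"schedule={tag}: {exc}") from exc
        per_window = np.mean(window_sums, axis=0)
        totals = np.array([ws.sum() for ws in window_sums])
        if cfg.n_repeats >= 2:
            mean, half = repeat_ci(totals)
        else:
            mean, half = float(totals[0]), 0.0
        results[tag] = FreeEnergyResult(
            schedule=tag, lambdas=cfg.lambdas, per_window=per_window,
            profile=profile_along_lambda(per_window), total=mean,
            repeat_totals=totals, ci_halfwidth=half)
    return results


def reproduce_table(cfg: ProtocolConfig, n_particles=(1,), window_times_ns=(0.1,)
                    ) -> pd.DataFrame:
    """Benchmark table: one row per (N, window time, schedule), with the
    quadrature-converged reference in the last column."""
    rows = []
    for n in n_particles:
        ref = exact_free_energy_difference(
            MultiParticlePotential(cfg.u1, n), MultiParticlePotential(cfg.u2, n), cfg.thermo)
        for dt_ns in window_times_ns:
            sub = replace(cfg, n_particles=n, window_time_ns=dt_ns)
            res = run_protocol(sub)
            for tag in cfg.schedules:
                rows.append({"N": n, "dt_ns": dt_ns, "schedule": tag,
                             "dF": res[tag].total, "halfwidth": res[tag].ci_halfwidth,
                             "converged": ref})
    return pd.DataFrame(rows)


def barrier_report(results: dict[str, FreeEnergyResult]) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-lambda cumulative profiles plus the max-|excursion| summary."""
    if not results:
        raise ConfigurationError("no schedule results given")
    first = next(iter(results.values()))
    table = pd.DataFrame({"lambda": first.lambdas})
    summary = {}
    for tag, res in results.items():
        table[tag] = res.profile
        summary[tag] = res.max_excursion
    return table, summary
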