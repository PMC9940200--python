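# Methods

This note documents the models, algorithms and numerical choices behind
`otfe`, and what its synthetic benchmarks do and do not demonstrate.

## Problem and unit system

The package computes alchemical free energy differences between two 1D
end-state potentials `U1` (coupling parameter λ = 0) and `U2` (λ = 1) in the
canonical ensemble. Kinetic terms factor out, so everything is expressed
through configurational Boltzmann densities `p(x) ∝ exp(−βU(x))`.

Units are GROMACS-style: energies in kJ/mol, lengths in nm, times in ps,
masses in amu, with `k_B = 0.00831446 kJ/(mol·K)`. In this system a harmonic
oscillator obeys `k = m (2πν)²` directly; the benchmark oscillator (unit
mass, ν = 2.0 ps⁻¹) has `k = 157.91 kJ/(mol·nm²)` and thermal width
`σ = sqrt(kT/k) = 0.126 nm` at 300 K.

The benchmark transformation morphs a zero-centered quartic double well

    U_dw(x) = V_max ((x² − b²)/b²)²,   b = 0.1 nm, V_max = 1.0 kJ/mol,

into that oscillator shifted to `x₀ = 0.5 nm`, so the two equilibrium
densities share essentially no support. Adaptive quadrature of both
partition functions gives the reference ΔF = −0.390 kJ/mol at 300 K
(−0.40 within the benchmark's printed precision); non-interacting N-particle
copies scale it exactly by N.

## Mixing schedules

Four λ-paths connect the end states:

* **linear** — `(1−λ)U1 + λU2`. For equal-spring oscillators this is again a
  harmonic well about the interpolated center *plus* a spurious additive
  shift `(k/2)λ(1−λ)(x1−x2)²`; the TI integrand is the straight line
  `(k/2)(1−2λ)(x1−x2)²`, which integrates to zero but forces each window to
  climb a barrier of `k(x1−x2)²/8` at mid-path.
* **linearC** — the linear mix with its minimum re-pinned to
  `E(λ) = (1−λ)min U1 + λ min U2`, removing the shift. The minimum is found
  by a grid scan plus bounded local refinement; the TI derivative uses the
  envelope theorem (the λ-derivative of the running minimum is the
  end-state energy gap at the argmin).
* **mvp** — the minimum-variance path
  `−(1/gβ) ln[(1−λ)e^{−gβU1} + λe^{−gβU2}]`, evaluated with log-sum-exp
  throughout; `g = 1` everywhere in the benchmarks, where the λ = 0.5 member
  coincides with the envelope-distribution-sampling reference potential up
  to a constant.
* **ot** — the displacement interpolation. For Gaussian end states the
  Wasserstein-2 geodesic is available in closed form: means interpolate
  linearly and, in 1D, so do standard deviations, giving a harmonic window
  `k_λ = kT/σ_λ²` about `m_λ`. Its TI integrand vanishes identically for
  equal springs — the transformation simply translates the well. For general
  end states the geodesic is built numerically (below).

λ outside [0, 1] is rejected; the geodesic is only defined on the interval.

## The numeric optimal-transport stack

Intermediate distributions are Wasserstein barycenters of the end-state
densities with weights (1−λ, λ). Two routes are implemented:

1. an **exact 1D oracle**: the barycenter's quantile function is the convex
   combination of the end-point quantile functions. Quantile functions are
   piecewise linear (mass uniform within histogram bins, zero-mass bins
   collapsing to jumps); the barycenter is re-binned from 2×10⁵ quantile
   points. The same construction yields the exact 1D W2 distance.
2. the **debiased Sinkhorn barycenter**, the route that generalizes beyond
   1D: iterative Bregman projections under the Gibbs kernel
   `K = exp(−(x−y)²/ε)` with the self-consistent debiasing update
   `d ← sqrt(d·μ/(Kd))` that removes most of the entropic blur.

The ground cost is the raw squared distance in nm, so the regularization
ε = 0.03 carries units of nm². The entropic blur length `sqrt(ε) ≈ 0.17 nm`
sets a resolution floor: the stack reproduces the oracle to total-variation
distance ≲ 0.02 for the benchmark densities and for unimodal densities with
σ ≳ 0.08 nm, but *over-sharpens* substantially narrower modes — the debiased
fixed point is not the W2 barycenter, and for sub-resolution features the
discrepancy grows with iteration count even as the iterate converges.
Convergence is therefore declared when the L1 change per iteration falls
below 1e−5 or stops improving (the coupled iteration settles into a ~1/t
tail); a change still above 1e−3 at 10,000 iterations raises an error.
Applications needing finer structure should lower ε.

The **Wasserstein potential** of a barycenter is `−kT ln p_λ(x)`, clamped at
a relative density floor of 1e−12 of the peak (yielding a finite plateau far
from the support) and offset so its minimum equals `E(λ)`, aligning windows
with the end states whose minima are both zero in the benchmark.

Since a gridded potential cannot be simulated directly, each window is fit
by kernel regularized least squares: `U(x) = Σ αᵢ exp(−γ(x−xᵢ)²)` with the
bin centers as basis centers, `γ = 1/(2s²)` for bin size `s`, and ridge
system `(K + θnI)α = y`, θ = 1e−5, solved by Cholesky factorization. The
analytic gradient of the expansion supplies forces. Two caveats, both
verified by tests: the ridge biases the fit by up to ~0.1 kJ/mol at the grid
boundary where the target is tens of kT (thermally irrelevant); and the
expansion decays to zero outside the training grid, which would let
particles escape outward, so simulations on fitted models are confined by
reflecting walls at the training-grid boundary.

## Sampling

Langevin dynamics uses the BAOAB splitting (half-kick, half-drift, exact
Ornstein–Uhlenbeck velocity refresh, half-drift, half-kick) at dt = 10 fs,
300 K, friction 1 ps⁻¹ and unit mass. Any symmetric Langevin–Verlet
splitting would do; BAOAB is chosen for its configurational accuracy, and
the suite checks sampled positions against quadrature Boltzmann CDFs by
Kolmogorov–Smirnov tests at α = 0.01 as well as velocity variances against
equipartition.

Randomness is strictly per particle: particle i of a run draws its initial
velocity and noise stream from a generator seeded by
`SeedSequence([seed, i])`. An N-particle run is therefore bit-identical to N
single-particle runs holding those seeds, which makes the non-interacting
factorization testable exactly at the trajectory level. (The free energy
*estimate* factorizes only in distribution — BAR is nonlinear in the per-
particle energy differences.)

Because every window, repeat and particle is an independent 1D coordinate,
the protocol simulates them as one vectorized batch; per-element seed
streams keep the result identical to window-by-window simulation. An exact
inverse-CDF Boltzmann sampler doubles as a fast, distribution-identical
substitute for long end-state MD in tests and scaled-down runs.

Each window run starts at the window potential's own minimum (grid argmin
with local refinement) rather than at an end-state minimum: kernel windows
clamp to a flat plateau outside the barycenter support, where an end-state
minimum may sit and waste the equilibration budget. The first 10% of steps
are discarded and positions are recorded every 10 steps by default.

## Estimation

Per-window free energies come from the Bennett acceptance ratio: the unique
root of the implicit equation in ΔF (monotone in ΔF, solved by bracketed
Brent iteration to 1e−8 kJ/mol) using forward and reverse energy differences
cross-evaluated between neighbouring windows; endpoint windows always
evaluate the original analytic potentials, so intermediate potential offsets
cancel telescopically in the total. The asymptotic BAR variance is reported
per window, but headline uncertainties are Student-t intervals over three
full protocol repeats (t₀.₉₇₅,₂ = 4.3027), as in the benchmark protocol.

Thermodynamic integration is used where ∂U/∂λ exists analytically (all
analytic schedules), with expectations either from samples or from adaptive
quadrature against each window's exact Boltzmann density — the deterministic
oracle for the estimator suite. The 21-point trapezoid matches the linear
schedule's linear integrand exactly; for stiff paths (double-well to
harmonic) the integrand varies sharply near λ = 1 and path-independence
checks integrate adaptively in λ instead. TI is *not* applied across fitted
kernel models: model-to-model fitting noise makes a finite-difference ∂U/∂λ
unreliable, so BAR is the estimator of record for the numeric OT schedule.

## Scaled-down benchmark profiles

The full benchmark uses 21 equally spaced λ windows, 2 ns of end-state
sampling, up to 10 ns per window, and 3 repeats. The package's test profile
keeps the 21 windows and 3 repeats but samples 0.1 ns per window with exact
Boltzmann end-state draws (20,000 points), which reproduces the reference
ΔF within the benchmark's own short-sampling uncertainty in ~30 s. The
acceptance script uses 2 ns windows for the N = 1 OT run, 1 ns for N = 4,
and 10 ns for MVP — the schedule that genuinely needs long sampling, since
its windows are bimodal and converge by rare well-hopping.

## The free energy profile along the path

The cumulative window sums trace how far each schedule wanders from the end
states. On the benchmark the linear path climbs several kJ/mol (the shift
term), linearC removes most of it, and the OT path stays nearly flat.
"Flat" has a caveat the tests quantify rather than hide: the free energy
along the exact Wasserstein geodesic of this system genuinely dips to about
−0.5 kJ/mol near mid-path (merging two narrow wells into one broader one
transiently lowers −kT ln Z), so the OT excursion hovers at the 0.5 kJ/mol
mark rather than strictly below it.

## What the synthetic benchmarks do not show

All systems are 1D or non-interacting sums, so histograms, barycenters and
kernel fits are cheap and exact sampling is available; none of this probes
the scalability of Sinkhorn barycenters, histogram estimation or kernel
fitting in high-dimensional configuration spaces, nor force-field realism,
constraints, or pressure coupling. Passing tests demonstrate correctness of
the machinery and reproduction of the 1D benchmark, not feasibility for
molecular systems.
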