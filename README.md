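# otfe — optimal transport for alchemical free energy estimation

`otfe` is a research toolkit that studies how the choice of λ-mixing path
affects alchemical free energy calculations, using optimal transport to
build the best possible path. It is aimed at method developers in molecular
simulation who want a fully controlled, analytically solvable testbed: every
system is a 1D potential (or a non-interacting sum of them) whose exact free
energy is available by quadrature, so every stage of the pipeline can be
validated against ground truth.

## The idea

An alchemical transformation morphs a potential `U1` into `U2` through
intermediate windows `U(x; λ)`, λ ∈ [0, 1], and accumulates the free energy
difference ΔF = −kT ln(Z₂/Z₁) window by window (thermodynamic integration
or the Bennett acceptance ratio, BAR). The usual choice, the convex
combination `(1−λ)U1 + λU2`, mixes *potentials* — but the real task is
morphing *distributions*. Optimal transport does precisely that: the
intermediate distributions live on the Wasserstein-2 geodesic,

  p_λ = argmin_p [(1−λ) W₂²(p, p₁) + λ W₂²(p, p₂)],

the barycenter of the two end-state Boltzmann distributions. The
corresponding "Wasserstein potential" is its negative thermal log-density,
`U_λ(x) = −kT ln p_λ(x)` (offset-aligned to the end-state minima). For two
harmonic wells with equal springs the geodesic just translates the well —
the TI integrand vanishes identically — while linear mixing makes each
window climb a spurious barrier `k(x₁−x₂)²/8` even though ΔF = 0.

For general end states the package implements the five-stage numeric
protocol: sample both end states → histogram → debiased Sinkhorn barycenter
per window (entropic regularization 0.03 nm²) → fit a Gaussian-basis kernel
model so each window has a smooth, differentiable potential → Langevin
dynamics (BAOAB, 10 fs, 300 K) plus BAR per window pair. Competing paths
(linear, minimum-corrected linear, and the minimum-variance path / MVP) run
through the same machinery. Headline uncertainties are Student-t intervals
over three independent repeats.

## Worked example

The benchmark morphs a zero-centered quartic double well (minima ±0.1 nm,
1 kJ/mol barrier) into a harmonic oscillator at 0.5 nm (ν = 2 ps⁻¹, k =
157.91 kJ/mol·nm⁻²) — two states with essentially no configurational
overlap. `examples/04_full_protocol.py` runs all four schedules at a
scaled-down profile (21 windows × 0.1 ns, 3 repeats) and prints:

```
quadrature reference: -0.3905 kJ/mol

schedule   dF (kJ/mol)      max |profile| (kJ/mol)
linear    -0.185 +- 0.789        9.14
linearC   -0.574 +- 0.153        1.79
mvp       -0.266 +- 1.858        0.27
ot        -0.396 +- 0.100        0.49
```

Read this as: all schedules estimate the same ΔF, but at equal (short)
sampling the optimal-transport path is both accurate and far more precise,
and its cumulative free-energy profile stays essentially flat along the
path, while the linear path climbs ~9 kJ/mol away (the spurious shift)
before coming back and pays for it in variance. MVP's profile is flat on
average but its estimate is wildly imprecise — its bimodal windows converge
only through rare well-hopping. The other examples isolate individual
stages:
the quadrature ground truth (`01`), the vanishing OT integrand for shifted
oscillators (`02`), and the barycenter/kernel stack (`03`).

A thin CLI mirrors the stages (`otfe simulate | histogram | barycenter |
fit | bar | protocol | table | report`); every artifact is plain text and
round-trips bit-exactly.

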