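"""The five-step protocol end-to-end at a scaled-down profile.

Runs all four schedules (linear, corrected linear, MVP, numeric OT) on the
double-well -> harmonic benchmark with 21 windows of 0.1 ns each and three
repeats, then prints totals, Student-t uncertainties and the path
excursions. Takes about a minute.
"""

from otfe import (DoubleWellPotential, HarmonicPotential, ProtocolConfig,
                  barrier_report, exact_free_energy_difference, run_protocol)

cfg = ProtocolConfig(
    u1=DoubleWellPotential(1.0, 0.1),
    u2=HarmonicPotential.from_frequency(2.0, center=0.5),
    n_lambdas=21, window_time_ns=0.1, n_repeats=3, seed=7,
    endpoint_sampler="exact",
    schedules=("linear", "linearC", "mvp", "ot"))

results = run_protocol(cfg)
ref = exact_free_energy_difference(cfg.u1, cfg.u2, cfg.thermo)
print(f"quadrature reference: {ref:+.4f} kJ/mol\n")
print("schedule   dF (kJ/mol)      max |profile| (kJ/mol)")
_, excursions = barrier_report(results)
for tag, res in results.items():
    print(f"{tag:9s} {res.total:+.3f} +- {res.ci_halfwidth:.3f}      "
          f"{excursions[tag]:6.2f}")

print("\nOT combines an almost flat path with by far the tightest "
      "uncertainty; the linear path wanders several kJ/mol away before "
      "returning (the spurious shift), and MVP pays for its bimodal "
      "windows with slow, imprecise convergence.")
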