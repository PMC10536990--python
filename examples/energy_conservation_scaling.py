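"""Timestep scaling of the energy-conservation criterion.

The criterion (eps(t) - eps(0))^2 is averaged over a W-weighted ensemble
for timesteps differing by a factor of ten.  For a second-order integrator
the energy fluctuation amplitude scales as dt^2, so the squared criterion
drops by ~1e4; the degenerate-eigenvalue approximation breaks this,
leaving the DE criterion unchanged however small the step.
"""

from mmstdyn import StepPlan, build_model, ensemble_diagnostics, \
    sample_initial

model = build_model(1)
ens = sample_initial(model, n=200, seed=11)
T = 20.0

print(f"{'algorithm':>10} {'crit dt=0.1':>13} {'crit dt=0.01':>14} "
      f"{'ratio':>10}")
for alg in ("mint", "sl", "de"):
    crit = {}
    for dt in (0.1, 0.01):
        series = ensemble_diagnostics(ens.states, model, StepPlan(alg, dt),
                                      int(round(T / dt)),
                                      weights=ens.weights)
        crit[dt] = series.energy_criterion.mean()
    print(f"{alg:>10} {crit[0.1]:13.3e} {crit[0.01]:14.3e} "
          f"{crit[0.1] / crit[0.01]:10.3g}")

print()
print("MInt and SL gain ~1e4 from the tenfold smaller step (second order);")
print("the DE ratio stays near 1 because its error comes from the")
print("degenerate-eigenvalue approximation, not from the finite timestep.")
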