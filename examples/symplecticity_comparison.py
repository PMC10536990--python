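"""Compare the symplecticity and Liouville diagnostics of MInt, SL and DE.

A W-weighted equilibrium ensemble of model-1 initial conditions is
propagated with each integrator while the monodromy matrix is accumulated
from its analytic per-step factors.  The Frobenius norm ||M^T J M - J||_F
measures symplecticity; (det M - 1)^2 measures phase-space volume
conservation.
"""

import numpy as np

from mmstdyn import StepPlan, build_model, ensemble_diagnostics, \
    sample_initial

model = build_model(1)
ens = sample_initial(model, n=500, seed=7)
print(f"ensemble of {len(ens)} trajectories, effective sample size "
      f"{ens.ess:.0f}")

print(f"{'algorithm':>10} {'sympl err (t=5)':>16} {'sympl err (t=20)':>17} "
      f"{'max |det M - 1|':>16}")
for alg in ("mint", "sl", "de"):
    series = ensemble_diagnostics(ens.states, model, StepPlan(alg, 0.1),
                                  200, weights=ens.weights)
    det_dev = np.sqrt(series.liouville_error.max())
    print(f"{alg:>10} {series.sympl_error[50]:16.3e} "
          f"{series.sympl_error[200]:17.3e} {det_dev:16.3e}")

print()
print("MInt stays at floating-point noise (symplectic); SL grows to the")
print("1e-2..1e-1 scale (second-order violation); DE reaches order unity")
print("(zero-order violation). All three keep det M = 1: Liouville's")
print("theorem holds even for the non-symplectic maps.")
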