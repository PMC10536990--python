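"""Propagate one MMST mapping trajectory and check its conservation laws.

A single phase-space point of the strongly coupled model (preset 1) is
advanced with the symplectic MInt integrator and compared against a
high-accuracy adaptive reference integration of the same equations of
motion.
"""

import numpy as np

from mmstdyn import (
    PhaseSpacePoint,
    StepPlan,
    build_model,
    mmst_energy,
    propagate,
    reference_propagate,
)

model = build_model(1)          # alpha=0, delta=4: adiabatic limit
state = PhaseSpacePoint(x=0.4, p=-0.3, X=[1.0, 0.2], P=[-0.1, 0.8])

traj = propagate(state, model, StepPlan("mint", dt=0.1), nsteps=100)
drift = np.abs(traj.energies - traj.energies[0]).max()
prob = [np.sum(s.X**2 + s.P**2) / 2 for s in traj.states]

ref = reference_propagate(state, model, t=10.0, tol=1e-12)
err = np.abs(traj.states[-1].z - ref.z).max()

print(f"initial MMST energy      : {mmst_energy(model, state):+.6f}")
print(f"max energy fluctuation   : {drift:.2e}   (bounded, ~dt^2)")
print(f"electronic-probability drift: {np.ptp(prob):.2e} (conserved)")
print(f"deviation from reference at t=10: {err:.2e}  (global O(dt^2))")
print("The energy oscillates but never drifts: the MInt step is the exact")
print("flow of each sub-Hamiltonian, so the map stays symplectic.")
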