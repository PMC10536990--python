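"""Sample the single-bead mapping distribution and estimate populations.

Initial conditions carry the nonnegative weight W = (X^T M P)^2 with
M = exp(-beta Vt(x)/2).  Two estimators of the equilibrium diabatic
populations are compared: the t = 0 thermal estimator and the
mapping-variable estimator (X_n^2 + P_n^2 - 1)/2, which must agree.
"""

from mmstdyn import build_model, initial_population, population_at_t, \
    sample_initial

for preset, label in ((1, "symmetric, strong coupling"),
                      (2, "biased (inverted Marcus)"),
                      (3, "symmetric, intermediate")):
    model = build_model(preset)
    ens = sample_initial(model, n=50000, seed=19)
    p1, p2 = initial_population(ens, 1), initial_population(ens, 2)
    w = ens.weights
    m1 = float((w * population_at_t(ens.states, 1)).sum() / w.sum())
    print(f"model {preset} ({label}):")
    print(f"  equilibrium estimator: pop1 = {p1:.4f}, pop2 = {p2:.4f}, "
          f"sum = {p1 + p2:.6f}")
    print(f"  mapping estimator at t=0: pop1 = {m1:.4f}")
    print(f"  effective sample size: {ens.ess:.0f} of {len(ens)}")

print()
print("Populations sum to one exactly (the per-sample numerators telescope")
print("to W). The biased model concentrates population in the lower diabat;")
print("the symmetric models split it evenly within Monte-Carlo error.")
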