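# Methods

This note records the model, the three flow maps, the monodromy algebra,
the sampling scheme and the numerical choices behind `mmstdyn`, together
with what the synthetic study conditions do and do not probe.

## Model and Hamiltonian

The system is a two-state linear vibronic (one-dimensional spin-boson)
model in reduced units m = ℏ = ω = 1.  The diabatic potential matrix is
split into a state-independent and a traceless state-dependent part,
V(x) = U(x)·I + Ṽ(x), with

    U(x)  = ½ m ω² x²,
    Ṽ(x)  = [[κx + α, Δ], [Δ, −(κx + α)]].

Δ is the electronic coupling, 2α the energy bias between the diabats and
κ the vibronic coupling.  The presets are (α, Δ) = (0, 4), (2, 1) and
(0, 1) with κ = 1: strong coupling near the adiabatic limit, a strongly
biased inverted-Marcus regime, and an intermediate regime in which
electronic and nuclear timescales are comparable.  The sign convention
puts +(κx + α) on diabat 1, so for α > 0 diabat 2 is the thermally
favoured state.

The traceless splitting (rather than, e.g., shifting the lowest eigenvalue
of Ṽ to zero) is required by the degenerate-eigenvalue algorithm and is
used for all three integrators so they propagate the same Hamiltonian:

    H = p²/2m + U(x) + ½ [Xᵀ Ṽ X + Pᵀ Ṽ P − tr Ṽ],

with two mapping pairs (X_n, P_n).  U couples classically: it contributes
only the force −U′ and does not enter the electronic rotation.  The exact
equations of motion are ẋ = p/m, ṗ = −U′ − ½(XᵀṼ′X + PᵀṼ′P) + ½ tr Ṽ′,
Ẋ = ṼP, Ṗ = −ṼX; they conserve H and the electronic probability
Σ(X_n² + P_n²)/2.

## The three flow maps

All integrators use the Strang sandwich Ψ(Δt) = Φ_{H₂,Δt/2} ∘ Φ_{H₁,Δt} ∘
Φ_{H₂,Δt/2} with H₁ = p²/2m (exact drift x → x + pΔt/m) and share the
exact electronic rotation of the H₂ half-step: with Ṽ = S Λ Sᵀ
(eigenvalues ascending, eigenvector sign fixed so the largest-magnitude
component of each column is positive),

    X' = C X + D P,  P' = −D X + C P,
    C = S cos(Λτ) Sᵀ,  D = S sin(Λτ) Sᵀ,  τ = Δt/2.

They differ only in the nuclear-momentum update of H₂:

* **MInt** integrates the momentum equation exactly along the rotating
  mapping variables.  In the adiabatic frame (X̄ = SᵀX, G = SᵀṼ′S,
  λ_nm = Λ_mm − Λ_nn):

      Δp = −τU′ + ½τ tr Ṽ′
           − ½ [X̄ᵀ(G∘E)X̄ + P̄ᵀ(G∘E)P̄ + 2 X̄ᵀ(G∘F)P̄],
      E_nm = sin(λ_nm τ)/λ_nm   (symmetric),
      F_nm = (1 − cos(λ_nm τ))/λ_nm   (skew-symmetric),

  evaluated at the mapping variables from the start of the half-step.
  Because kick-then-rotate reproduces the exact H₂ flow, the composed map
  is symplectic, symmetric and time-reversible.
* **SL** replaces the momentum integral by the instantaneous force at
  frozen mapping variables, Δp = −τ[U′ + ½(XᵀṼ′X + PᵀṼ′P) − ½trṼ′].  The
  two half-steps apply the electronic and nuclear sub-steps in mirrored
  order (variant a: rotate then kick; variant b: kick then rotate) so the
  full step is palindromic.  The E/F kernels are recovered as τ → 0, so SL
  is second order, but symplecticity fails at finite Δt.
* **DE** keeps the initial-variable structure of MInt but approximates the
  adiabatic-frame derivative G by its diagonal Λ′ = diag(G), i.e. it
  treats the eigenvalues of Ṽ as degenerate when integrating the momentum:
  Δp = −τU′ − ½τ Σ_n Λ′_nn (X̄_n² + P̄_n²).  Because each adiabatic action
  X̄_n² + P̄_n² is invariant under the rotation, this kick is what the
  exact integral collapses to when the off-diagonal G terms are dropped.
  Those terms are O(1) in Δt, so DE converges to the flow of a *modified,
  non-Hamiltonian* force field: it is zero order, breaks energy
  conservation at any timestep, yet remains volume-preserving and (for
  this model family) time-reversible.

Backward propagation negates Δt; every sub-map is defined for signed τ.
The H₁-outer order Φ_{H₁,Δt/2} ∘ Φ_{H₂} ∘ Φ_{H₁,Δt/2} is available via
`StepPlan(sandwich_order="h1h2h1")` and changes nothing qualitative.

## Monodromy matrices and diagnostics

The phase-space ordering is z = (x, X₁, X₂, p, P₁, P₂) with structure
matrix J = [[0, I₃], [−I₃, 0]]; any consistent reordering leaves both
diagnostics invariant.  Each sub-map carries an analytic Jacobian:

* drift: identity plus ∂x'/∂p = Δt/m;
* rotation: the C/D blocks plus a first column ∂(X', P')/∂x built from
  dC/dx = S[Wc − cW − τΛ′s]Sᵀ and dD/dx = S[Ws − sW + τΛ′c]Sᵀ, where
  W = SᵀS′ is the eigenvector-derivative generator,
  W_nm = G_nm/(Λ_mm − Λ_nn) off the diagonal;
* kicks: a single p-row containing ∂Δp/∂(x, X, P); the MInt row uses the
  gap-derivatives dE/dλ, dF/dλ and G′ = GW − WG (Ṽ″ = 0 for the linear
  vibronic family, an assumption baked into these rows).

The per-step monodromy factor is the ordered product of the sub-map
Jacobians evaluated at the actual intermediate states, and the trajectory
monodromy is accumulated by left-multiplication.  Because the MInt factors
are exact derivatives of exact sub-flows, ‖MᵀJM − J‖_F stays at
accumulated roundoff (≲10⁻¹³ over 10³ steps); the finite-difference
Jacobian oracle agrees with every analytic factor to the oracle's own
accuracy (~10⁻⁹ with h = 10⁻⁶ central differences).

Diagnostics: symplecticity error ‖MᵀJM − J‖_F (Frobenius norm over all 36
entries, no size normalization), Liouville error (det M − 1)² (squared so
trajectory averaging cannot cancel signs), and the energy criterion
(ε(t) − ε(0))² with ε the MMST energy.  The energy criterion uses the
*absolute* deviation: sampled trajectories can have ε(0) near zero, which
would make a relative criterion unbounded under ensemble averaging, and
the Δt-scaling (ratio ~10⁴ between Δt = 0.1 and 0.01 for second-order
maps) is identical for both forms.  Ensemble curves are means weighted by
the sampling weight W.

## Equilibrium sampling and estimators

Initial conditions are drawn from the single-bead mapping distribution

    ρ ∝ e^{−βp²/2m} e^{−βU(x)} e^{−(XᵀX + PᵀP)} W(x, X, P),
    W = Pᵀ M X Xᵀ M P = (Xᵀ M P)²,   M = e^{−βṼ(x)/2},

by importance sampling: x ~ N(0, 1/(βmω²)), p ~ N(0, m/β), each mapping
component ~ N(0, ½), with W carried as a nonnegative weight.  The kernel
M = e^{−βṼ/2} makes the scheme exact for electronic equilibrium at fixed
nuclei: Gaussian moments give ⟨W⟩ ∝ tr e^{−βṼ}, and the projected weights
W_n = (XᵀMP)·X_n(MP)_n satisfy Σ_n W_n = W identically, so the
equilibrium populations pop_n = ⟨W_n⟩/⟨W⟩ sum to one exactly and equal
(e^{−βṼ})_nn/tr e^{−βṼ} averaged over the nuclear Boltzmann factor.  The
time-t mapping estimator pop_n(t) = (X_n² + P_n² − 1)/2 (zero-point
constant 1) has the same t = 0 expectation — the package tests this
two-estimator consistency by Monte Carlo.

All variates come from one `numpy` Generator in a fixed draw order, so
ensembles are bit-reproducible from the seed; the dynamics itself is
deterministic, so no per-trajectory streams are needed.  The effective
sample size (ΣW)²/ΣW² is recorded (typically 10–45 % of n for β = 1;
W is heavy-tailed because it is quartic in the mapping variables).
Correlation functions C_xx(t) = ⟨W x(0)x(t)⟩/⟨W⟩ and
C₁₁(t) = ⟨W n₁(0)n₁(t)⟩/⟨W⟩ get one-sigma bands from a delete-one
weighted jackknife of the full ratio estimator.

## Parameters, defaults and study conditions

* β = 1.0 (reduced units), configurable.  The temperature is not pinned by
  the model definition; β = 1 makes the nuclear thermal width equal the
  oscillator length and keeps all three regimes dynamically active.
* Δt = 0.1 is the production timestep; 0.01 and 1.0 are used for scaling
  studies.  Diagnostic runs use 200 steps (t = 20) with 10³ trajectories;
  correlation runs use 10⁴.
* The figure-level simulation window for the symplecticity comparison is
  t ∈ [0, 5].  The window is calibrated internally: the W-averaged SL
  error sits at its characteristic 10⁻² scale up to t ≈ 5 (0.02–0.06
  across seeds) and grows an order of magnitude beyond it by t = 20, while
  the DE error crosses unity at t ≈ 5 (converged value 1.03, against 2.6
  at t = 10 and 8.7 at t = 20).  The acceptance script therefore reports
  the DE error at t = 5; the longer t = 20 window is kept for the
  package's own stress tests.
* Kernel singularities: E, F and their λ-derivatives switch to 4th-order
  Taylor series for |λ_nm τ| < 10⁻⁶ (the crossover error is ≲10⁻²⁴
  relative).  A degenerate Ṽ (gap < 10⁻¹²) returns the identity adiabatic
  frame with W = 0; this is exact when Ṽ ≡ 0 (where all three algorithms
  provably coincide, used as a test) and unreachable for the presets,
  whose gap is ≥ 2Δ ≥ 2.
* Eigenvalue order ascending and the positive-leading-component sign fix
  keep S, C, D, E, F and all monodromy entries continuous along
  trajectories for Δ ≠ 0.

## What the synthetic conditions do and do not show

The ensemble generator *is* the study condition: a bound one-dimensional
model with Gaussian nuclear sampling and exact single-bead electronic
thermalization.  Passing tests demonstrate the algorithmic claims —
symplecticity, Liouville conservation, order of accuracy, energy-criterion
scaling, estimator consistency — which are properties of the flow maps and
carry over to any Hamiltonian of this algebraic form.  They do not probe
multi-dimensional baths, anharmonic potentials, >2 electronic states
(the data model permits them; the kernels implement N = 2, one nuclear
DoF), multi-bead path-integral sampling, or long-time energy drift beyond
t ~ 100.

Statistical power is the main desk-scale limitation: with Gaussian
proposals the W-weights are heavy-tailed, and the *systematic* DE bias in
C₁₁ for the weakly coupled models (absolute size ~0.01–0.05) needs ~10⁵
trajectories to clear a 2σ band, while 10⁴ trajectories leave it at
0.4–2σ depending on seed.  The trajectory-level DE pathologies (energy
criterion, symplecticity error) are resolved at very high significance at
every scale tested.

## Known limitations

* The analytic kick Jacobians assume Ṽ″ = 0; extending to nonlinear
  vibronic couplings requires one extra term in the SL/MInt/DE p-rows.
* `reference_propagate` (DOP853 at rtol = atol ≤ 10⁻¹⁰) is the trajectory
  oracle, not a production integrator; it handles one trajectory at a
  time.
* The exact quantum Boltzmann distribution is not sampled; the single-bead
  distribution is exact for electronic equilibrium with classical nuclei
  only.
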