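"""Time propagation of the MMST mapping Hamiltonian.

Three second-kind splitting integrators are implemented for the two-state,
one-nuclear-DoF mapping Hamiltonian

    H = H1 + H2,
    H1 = p^2 / 2m,
    H2 = U(x) + (1/2)[X^T Vt(x) X + P^T Vt(x) P - tr Vt(x)],

composed in the Strang sandwich  Psi(dt) = H2(dt/2) o H1(dt) o H2(dt/2)
(the H1-outer order is available through :class:`StepPlan`).  All three
algorithms share the exact H1 drift and the exact electronic rotation
generated by Vt; they differ only in the nuclear-momentum update of H2:

``mint``
    The Momentum Integral algorithm.  The momentum integral over the
    rotating mapping variables is evaluated in closed form with the
    sinc-like kernels E (symmetric) and F (skew-symmetric) built from the
    adiabatic gaps, making the H2 half-step the *exact* flow of H2 and the
    full step symplectic.
``sl``
    The Split-Liouvillian algorithm.  H2 is further split into an electronic
    rotation and a momentum kick at frozen mapping variables; the symmetric
    a/b ordering of the two sub-steps makes the full step palindromic and
    second-order, but not symplectic at finite dt.
``de``
    The Degenerate-Eigenvalue algorithm.  The momentum update replaces the
    adiabatic-frame potential derivative G = S^T Vt' S by its diagonal
    eigenvalue-derivative part Lam' (the degenerate-eigenvalue
    approximation), evaluated at the mapping variables from the start of
    each half-step.  The discarded off-diagonal terms do not vanish with dt,
    so the algorithm is not exact even in the dt -> 0 limit.

The phase-space ordering used everywhere (states, monodromy matrices, the
structure matrix) is ``z = (x, X1, X2, p, P1, P2)`` with
``J = [[0, I3], [-I3, 0]]``.

Analytic single-step Jacobians (monodromy factors) are produced alongside
propagation on request; the algebra assumes the linear vibronic family
(Vt'' = 0), which is the only family constructed by
:mod:`mmstdyn.vibronic_model`.

All kernels broadcast over a leading batch axis, so an ensemble of
trajectories propagates as one set of array operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .vibronic_model import (
    AdiabaticFrame,
    DiabaticMatrices,
    ModelParams,
    adiabatize,
    mmst_energy,
    potential,
)

__all__ = [
    "PhaseSpacePoint",
    "StepPlan",
    "Trajectory",
    "step_h1",
    "electronic_halfstep",
    "nuclear_halfstep_mint",
    "sl_h2_halfstep",
    "de_h2_halfstep",
    "propagate",
    "reference_propagate",
    "structure_matrix",
]

_ALGORITHMS = ("mint", "sl", "de")
_ORDERS = ("h2h1h2", "h1h2h1")

# Taylor-series switch for the removable singularities of the E/F kernels
_KERNEL_SERIES_CUTOFF = 1e-6


def structure_matrix() -> np.ndarray:
    """The symplectic structure matrix J in the (x, X1, X2, p, P1, P2) ordering."""
    J = np.zeros((6, 6))
    J[:3, 3:] = np.eye(3)
    J[3:, :3] = -np.eye(3)
    return J


@dataclass
class PhaseSpacePoint:
    """Full phase-space point z = (x, p; X, P) at one time.

    ``x`` and ``p`` are the nuclear position and momentum, ``X`` and ``P``
    the two mapping (electronic) positions and momenta.  Entries may carry a
    leading batch shape; ``X``/``P`` then have trailing length-2 axes.
    The flattened ordering is z = (x, X1, X2, p, P1, P2).
    """

    x: np.ndarray
    p: np.ndarray
    X: np.ndarray
    P: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if self.X.shape[-1:] != (2,) or self.P.shape[-1:] != (2,):
            raise ValueError("X and P must have a trailing axis of length 2")

    @property
    def batch_shape(self) -> tuple:
        return self.x.shape

    @property
    def z(self) -> np.ndarray:
        """Flattened phase-space vector(s), shape (..., 6)."""
        return np.stack(
            [self.x, self.X[..., 0], self.X[..., 1],
             self.p, self.P[..., 0], self.P[..., 1]], axis=-1)

    @classmethod
    def from_z(cls, z, t: float = 0.0) -> "PhaseSpacePoint":
        z = np.asarray(z, dtype=float)
        return cls(x=z[..., 0], p=z[..., 3],
                   X=z[..., (1, 2)], P=z[..., (4, 5)], t=t)

    def copy(self) -> "PhaseSpacePoint":
        return PhaseSpacePoint(self.x.copy(), self.p.copy(),
                               self.X.copy(), self.P.copy(), self.t)

    def isfinite(self) -> bool:
        return bool(np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.p))
                    and np.all(np.isfinite(self.X))
                    and np.all(np.isfinite(self.P)))


@dataclass(frozen=True)
class StepPlan:
    """Integrator choice, timestep and splitting order for one run.

    ``sandwich_order`` selects which sub-Hamiltonian is the outer half-step:
    the default ``h2h1h2`` sandwiches the H1 drift between two H2
    half-steps.  ``sl_variants`` gives the a/b ordering of the electronic vs
    nuclear sub-steps inside the two SL half-steps ('a' = electronic then
    nuclear, 'b' = the mirror image), chosen so the composed step is
    palindromic.  A negative ``dt`` propagates backward in time.
    """

    algorithm: str
    dt: float
    sandwich_order: str = "h2h1h2"
    sl_variants: tuple = ("a", "b")

    def __post_init__(self) -> None:
        object.__setattr__(self, "algorithm", str(self.algorithm).lower())
        if self.algorithm not in _ALGORITHMS:
            raise ValueError(f"algorithm must be one of {_ALGORITHMS}")
        if not np.isfinite(self.dt):
            raise ValueError("dt must be finite")
        if self.sandwich_order not in _ORDERS:
            raise ValueError(f"sandwich_order must be one of {_ORDERS}")
        if tuple(sorted(self.sl_variants)) != ("a", "b"):
            raise ValueError("sl_variants must be a permutation of ('a','b')")

    def reversed(self) -> "StepPlan":
        """Plan for backward propagation (dt -> -dt)."""
        return replace(self, dt=-self.dt)


@dataclass
class Trajectory:
    """Propagated time series on a uniform grid.

    ``states[k]`` is the phase-space point at time ``k*dt`` (possibly
    batched); ``energies[k]`` the MMST energy there.  ``weight`` carries the
    sampling weight(s) W of the initial condition(s) when the trajectory
    came from an equilibrium ensemble.
    """

    states: list
    energies: np.ndarray
    plan: StepPlan
    weight: np.ndarray | None = None
    monodromies: np.ndarray | None = field(default=None, repr=False)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.states)) * self.plan.dt

    def __len__(self) -> int:
        return len(self.states)


# ---------------------------------------------------------------------------
# array-level building blocks
# ---------------------------------------------------------------------------

def _mv(M: np.ndarray, v: np.ndarray) -> np.ndarray:
    return np.einsum("...ij,...j->...i", M, v)


def _quad(u: np.ndarray, M: np.ndarray, v: np.ndarray) -> np.ndarray:
    return np.einsum("...i,...ij,...j->...", u, M, v)


def _sandwich(S: np.ndarray, inner: np.ndarray) -> np.ndarray:
    """S @ inner @ S^T with batching."""
    return S @ inner @ np.swapaxes(S, -1, -2)


def _ef_kernels(lamdiff: np.ndarray, tau: float):
    """E, F momentum-integral kernels and their eigenvalue-gap derivatives.

    E(l) = sin(l*tau)/l  (symmetric, -> tau as l -> 0)
    F(l) = (1-cos(l*tau))/l  (skew-symmetric, -> 0 as l -> 0)
    dE, dF are d/dl; the removable singularity at l -> 0 is handled by a
    short Taylor series below |l*tau| = 1e-6.
    """
    u = lamdiff * tau
    small = np.abs(u) < _KERNEL_SERIES_CUTOFF
    l_safe = np.where(small, 1.0, lamdiff)
    E_exact = np.sin(u) / l_safe
    F_exact = (1.0 - np.cos(u)) / l_safe
    E_series = tau * (1.0 - u**2 / 6.0 + u**4 / 120.0)
    F_series = tau * (u / 2.0 - u**3 / 24.0)
    E = np.where(small, E_series, E_exact)
    F = np.where(small, F_series, F_exact)
    dE_exact = (tau * np.cos(u) - E) / l_safe
    dF_exact = (tau * np.sin(u) - F) / l_safe
    dE_series = tau**2 * (-u / 3.0 + u**3 / 30.0)
    dF_series = tau**2 * (0.5 - u**2 / 8.0 + u**4 / 144.0)
    dE = np.where(small, dE_series, dE_exact)
    dF = np.where(small, dF_series, dF_exact)
    return E, F, dE, dF


def _rotation_matrices(frame: AdiabaticFrame, tau: float):
    """C = S cos(Lam tau) S^T and D = S sin(Lam tau) S^T."""
    c = np.cos(frame.Lam * tau)
    s = np.sin(frame.Lam * tau)
    C = np.einsum("...ik,...k,...jk->...ij", frame.S, c, frame.S)
    D = np.einsum("...ik,...k,...jk->...ij", frame.S, s, frame.S)
    return C, D, c, s


def _eye6(batch_shape: tuple) -> np.ndarray:
    M = np.zeros(batch_shape + (6, 6))
    M[...] = np.eye(6)
    return M


def _rot_map(X, P, frame, tau, jac: bool):
    """Exact electronic rotation under Vt for duration tau; x, p fixed."""
    if tau == 0.0:
        return X.copy(), P.copy(), _eye6(X.shape[:-1]) if jac else None
    C, D, c, s = _rotation_matrices(frame, tau)
    Xn = _mv(C, X) + _mv(D, P)
    Pn = -_mv(D, X) + _mv(C, P)
    if not jac:
        return Xn, Pn, None
    S, w, dLam = frame.S, frame.w, frame.dLam
    # dC/dx = S [w c - c w - tau diag(Lam' sin)] S^T, dD/dx likewise
    innerC = w * c[..., None, :] - c[..., :, None] * w
    innerD = w * s[..., None, :] - s[..., :, None] * w
    idx = np.arange(2)
    innerC[..., idx, idx] -= tau * dLam * s
    innerD[..., idx, idx] += tau * dLam * c
    dC = _sandwich(S, innerC)
    dD = _sandwich(S, innerD)
    M = _eye6(X.shape[:-1])
    M[..., 1:3, 1:3] = C
    M[..., 1:3, 4:6] = D
    M[..., 4:6, 1:3] = -D
    M[..., 4:6, 4:6] = C
    M[..., 1:3, 0] = _mv(dC, X) + _mv(dD, P)
    M[..., 4:6, 0] = -_mv(dD, X) + _mv(dC, P)
    return Xn, Pn, M


def _kick_mint(p, X, P, frame, dm, tau, model=None, *, jac: bool = False):
    """Exact H2 momentum integral over [0, tau] at the initial X, P."""
    St = np.swapaxes(frame.S, -1, -2)
    Xb = _mv(St, X)
    Pb = _mv(St, P)
    E, F, dE, dF = _ef_kernels(frame.lamdiff, tau)
    G = frame.G
    A = G * E
    B = G * F
    dv = 0.5 * (_quad(Xb, A, Xb) + _quad(Pb, A, Pb)) + _quad(Xb, B, Pb)
    tr_dVt = dm.dVt[..., 0, 0] + dm.dVt[..., 1, 1]
    pn = p - tau * dm.dU - dv + 0.5 * tau * tr_dVt
    if not jac:
        return pn, None
    w, dLam = frame.w, frame.dLam
    dlamdiff = dLam[..., None, :] - dLam[..., :, None]
    dG = G @ w - w @ G
    dA = dG * E + G * dE * dlamdiff
    dB = dG * F + G * dF * dlamdiff
    ddv_dx = (0.5 * (_quad(Xb, dA, Xb) + _quad(Pb, dA, Pb))
              + _quad(Xb, dB, Pb)
              - _quad(Xb, A @ w, Xb) - _quad(Pb, A @ w, Pb)
              + _quad(Xb, w @ B - B @ w, Pb))
    ddU = model.mass * model.omega**2
    M = _eye6(p.shape)
    M[..., 3, 0] = -tau * ddU - ddv_dx
    M[..., 3, 1:3] = -_mv(frame.S, _mv(A, Xb) + _mv(B, Pb))
    M[..., 3, 4:6] = -_mv(frame.S, _mv(A, Pb) - _mv(B, Xb))
    return pn, M


def _kick_sl(p, X, P, dm, tau, model=None, *, jac: bool = False):
    """SL momentum kick: instantaneous force at frozen mapping variables."""
    tr_dVt = dm.dVt[..., 0, 0] + dm.dVt[..., 1, 1]
    force = (dm.dU + 0.5 * (_quad(X, dm.dVt, X) + _quad(P, dm.dVt, P))
             - 0.5 * tr_dVt)
    pn = p - tau * force
    if not jac:
        return pn, None
    ddU = model.mass * model.omega**2
    M = _eye6(p.shape)
    M[..., 3, 0] = -tau * ddU  # Vt'' = 0 for the linear vibronic family
    M[..., 3, 1:3] = -tau * _mv(dm.dVt, X)
    M[..., 3, 4:6] = -tau * _mv(dm.dVt, P)
    return pn, M


def _kick_de(p, X, P, frame, dm, tau, model=None, *, jac: bool = False):
    """DE momentum kick: degenerate-eigenvalue kernel at the initial X, P."""
    St = np.swapaxes(frame.S, -1, -2)
    Xb = _mv(St, X)
    Pb = _mv(St, P)
    dLam = frame.dLam
    action = Xb**2 + Pb**2
    pn = p - tau * dm.dU - 0.5 * tau * np.einsum("...n,...n->...", dLam, action)
    if not jac:
        return pn, None
    w = frame.w
    dG = frame.G @ w - w @ frame.G
    ddLam = np.stack([dG[..., 0, 0], dG[..., 1, 1]], axis=-1)
    Lpw = dLam[..., :, None] * w
    ddv_dx = (0.5 * np.einsum("...n,...n->...", ddLam, action)
              - _quad(Xb, Lpw, Xb) - _quad(Pb, Lpw, Pb))
    ddU = model.mass * model.omega**2
    M = _eye6(p.shape)
    M[..., 3, 0] = -tau * ddU - tau * ddv_dx
    M[..., 3, 1:3] = -tau * _mv(frame.S, dLam * Xb)
    M[..., 3, 4:6] = -tau * _mv(frame.S, dLam * Pb)
    return pn, M


def _h1_map(x, p, dt, model, jac: bool = False):
    xn = x + dt * p / model.mass
    if not jac:
        return xn, None
    M = _eye6(x.shape)
    M[..., 0, 3] = dt / model.mass
    return xn, M


def _h2_half(alg, x, p, X, P, frame, dm, tau, variant, model, jac):
    """One algorithm-specific H2 half-step; returns p', X', P' (+ Jacobian)."""
    if alg == "mint":
        # exact H2 flow: momentum integral at the initial X, P, then rotate
        pn, Mk = _kick_mint(p, X, P, frame, dm, tau, model, jac=jac)
        Xn, Pn, Mr = _rot_map(X, P, frame, tau, jac)
        M = Mr @ Mk if jac else None
    elif alg == "de":
        pn, Mk = _kick_de(p, X, P, frame, dm, tau, model, jac=jac)
        Xn, Pn, Mr = _rot_map(X, P, frame, tau, jac)
        M = Mr @ Mk if jac else None
    elif alg == "sl":
        if variant == "a":  # electronic rotation, then momentum kick
            Xn, Pn, Mr = _rot_map(X, P, frame, tau, jac)
            pn, Mk = _kick_sl(p, Xn, Pn, dm, tau, model, jac=jac)
            M = Mk @ Mr if jac else None
        else:               # mirror image: kick, then rotate
            pn, Mk = _kick_sl(p, X, P, dm, tau, model, jac=jac)
            Xn, Pn, Mr = _rot_map(X, P, frame, tau, jac)
            M = Mr @ Mk if jac else None
    else:  # pragma: no cover
        raise ValueError(alg)
    return pn, Xn, Pn, M


def _frame_at(model, x):
    dm = potential(model, x)
    return dm, adiabatize(dm)


def _full_step(model, plan, x, p, X, P, dm, frame, jac):
    """One composed step of the chosen flow map.

    ``dm``/``frame`` must belong to the incoming ``x`` (they are returned by
    the previous call for the default sandwich order, recomputed otherwise).
    Returns updated arrays, the potential/frame at the outgoing position and
    the analytic step Jacobian if requested.
    """
    dt = plan.dt
    tau = 0.5 * dt
    alg = plan.algorithm
    va, vb = plan.sl_variants
    if plan.sandwich_order == "h2h1h2":
        p, X, P, M1 = _h2_half(alg, x, p, X, P, frame, dm, tau, va, model, jac)
        x, Mh = _h1_map(x, p, dt, model, jac)
        dm, frame = _frame_at(model, x)
        p, X, P, M2 = _h2_half(alg, x, p, X, P, frame, dm, tau, vb, model, jac)
        M = M2 @ Mh @ M1 if jac else None
        return x, p, X, P, dm, frame, M
    # h1h2h1: drift half, both H2 half-steps at the midpoint, drift half
    x, Mh1 = _h1_map(x, p, tau, model, jac)
    dm_mid, frame_mid = _frame_at(model, x)
    p, X, P, M1 = _h2_half(alg, x, p, X, P, frame_mid, dm_mid, tau, va,
                           model, jac)
    p, X, P, M2 = _h2_half(alg, x, p, X, P, frame_mid, dm_mid, tau, vb,
                           model, jac)
    x, Mh2 = _h1_map(x, p, tau, model, jac)
    dm, frame = _frame_at(model, x)
    M = Mh2 @ M2 @ M1 @ Mh1 if jac else None
    return x, p, X, P, dm, frame, M


# ---------------------------------------------------------------------------
# public sub-step operations
# ---------------------------------------------------------------------------

def step_h1(state: PhaseSpacePoint, model: ModelParams,
            dt: float) -> PhaseSpacePoint:
    """Exact free-particle drift x -> x + p*dt/m; everything else unchanged."""
    xn, _ = _h1_map(state.x, state.p, dt, model, False)
    return PhaseSpacePoint(xn, state.p.copy(), state.X.copy(),
                           state.P.copy(), state.t)


def electronic_halfstep(state: PhaseSpacePoint, frame: AdiabaticFrame,
                        half_dt: float) -> PhaseSpacePoint:
    """Exact rotation of the mapping variables under Vt for ``half_dt``.

    Shared by all three algorithms; preserves sum(X^2 + P^2) exactly (up to
    roundoff) since C + iD is unitary.
    """
    Xn, Pn, _ = _rot_map(state.X, state.P, frame, half_dt, False)
    return PhaseSpacePoint(state.x.copy(), state.p.copy(), Xn, Pn, state.t)


def nuclear_halfstep_mint(state: PhaseSpacePoint, frame: AdiabaticFrame,
                          dm: DiabaticMatrices, half_dt: float) -> np.ndarray:
    """Exact MInt momentum integral over one H2 half-step; returns updated p.

    Uses the mapping variables of ``state`` (the values at the start of the
    half-step) contracted with the E/F kernels, plus the state-independent
    -U'(x)*half_dt contribution.  x, X, P are untouched by this sub-step.
    """
    pn, _ = _kick_mint(state.p, state.X, state.P, frame, dm, half_dt)
    return pn


def sl_h2_halfstep(state: PhaseSpacePoint, frame: AdiabaticFrame,
                   dm: DiabaticMatrices, half_dt: float,
                   variant: str = "a") -> PhaseSpacePoint:
    """One SL half-step of H2 (variant 'a': rotate then kick; 'b': mirror)."""
    if variant not in ("a", "b"):
        raise ValueError("variant must be 'a' or 'b'")
    pn, Xn, Pn, _ = _h2_half("sl", state.x, state.p, state.X, state.P,
                             frame, dm, half_dt, variant, None, False)
    return PhaseSpacePoint(state.x.copy(), pn, Xn, Pn, state.t)


def de_h2_halfstep(state: PhaseSpacePoint, frame: AdiabaticFrame,
                   dm: DiabaticMatrices, half_dt: float) -> PhaseSpacePoint:
    """One DE half-step: degenerate-eigenvalue kick at the initial mapping
    variables, then the shared electronic rotation."""
    pn, Xn, Pn, _ = _h2_half("de", state.x, state.p, state.X, state.P,
                             frame, dm, half_dt, None, None, False)
    return PhaseSpacePoint(state.x.copy(), pn, Xn, Pn, state.t)


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def propagate(state0: PhaseSpacePoint, model: ModelParams, plan: StepPlan,
              nsteps: int, *, monodromy: bool = False,
              weight: np.ndarray | None = None) -> Trajectory:
    """Propagate ``nsteps`` composed steps, recording states and energies.

    With ``monodromy=True`` the analytic per-step Jacobians are accumulated
    and the running monodromy matrices (shape ``(nsteps+1, ..., 6, 6)``) are
    stored on the returned trajectory.  Propagation is aborted with a
    diagnostic if a non-finite state is produced.
    """
    if nsteps < 0:
        raise ValueError("nsteps must be >= 0")
    if not state0.isfinite():
        raise FloatingPointError("non-finite initial state")
    x, p = state0.x.copy(), state0.p.copy()
    X, P = state0.X.copy(), state0.P.copy()
    dm, frame = _frame_at(model, x)
    states = [PhaseSpacePoint(x.copy(), p.copy(), X.copy(), P.copy(),
                              state0.t)]
    energies = [mmst_energy(model, states[0])]
    Ms = None
    if monodromy:
        M_acc = _eye6(x.shape)
        Ms = [M_acc.copy()]
    for k in range(nsteps):
        x, p, X, P, dm, frame, Mstep = _full_step(
            model, plan, x, p, X, P, dm, frame, monodromy)
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(p))
                and np.all(np.isfinite(X)) and np.all(np.isfinite(P))):
            raise FloatingPointError(
                f"non-finite state at step {k + 1}; propagation aborted")
        st = PhaseSpacePoint(x.copy(), p.copy(), X.copy(), P.copy(),
                             state0.t + (k + 1) * plan.dt)
        states.append(st)
        energies.append(mmst_energy(model, st))
        if monodromy:
            M_acc = Mstep @ M_acc
            Ms.append(M_acc.copy())
    traj = Trajectory(states=states, energies=np.stack(energies), plan=plan,
                      weight=weight,
                      monodromies=np.stack(Ms) if monodromy else None)
    return traj


def _eom(model: ModelParams):
    def f(t, z):
        state = PhaseSpacePoint.from_z(z)
        dm = potential(model, state.x)
        X, P = state.X, state.P
        xdot = state.p / model.mass
        tr_dVt = dm.dVt[..., 0, 0] + dm.dVt[..., 1, 1]
        pdot = -(dm.dU + 0.5 * (_quad(X, dm.dVt, X) + _quad(P, dm.dVt, P))
                 - 0.5 * tr_dVt)
        Xdot = _mv(dm.Vt, P)
        Pdot = -_mv(dm.Vt, X)
        return PhaseSpacePoint(xdot, pdot, Xdot, Pdot).z
    return f


def reference_propagate(state0: PhaseSpacePoint, model: ModelParams,
                        t: float, tol: float = 1e-12) -> PhaseSpacePoint:
    """High-order adaptive integration of the exact equations of motion.

    Serves as the trajectory oracle: DOP853 with rtol = atol = ``tol``
    (required <= 1e-10).  Only unbatched states are supported.
    """
    if tol > 1e-10:
        raise ValueError("tol must be <= 1e-10 for the reference oracle")
    if state0.batch_shape != ():
        raise ValueError("reference_propagate expects an unbatched state")
    if t == 0.0:
        out = state0.copy()
        return out
    sol = solve_ivp(_eom(model), (0.0, t), state0.z, method="DOP853",
                    rtol=tol, atol=tol, dense_output=False)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"reference integration failed: {sol.message}")
    return PhaseSpacePoint.from_z(sol.y[:, -1], t=state0.t + t)
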