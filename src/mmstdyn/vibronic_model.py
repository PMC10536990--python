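"""Two-state linear vibronic model and the MMST mapping Hamiltonian.

The model family is a one-dimensional spin-boson-like system: a harmonic
nuclear mode bilinearly coupled to two diabatic electronic states,

    V(x) = U(x) I + Vt(x),
    U(x)  = (1/2) m w^2 x^2,
    Vt(x) = [[kappa*x + alpha,  delta],
             [delta, -(kappa*x + alpha)]],

where ``delta`` is the electronic coupling, ``2*alpha`` the energy bias
between the diabats and ``kappa`` the vibronic coupling.  ``Vt`` is traceless
by construction, which the degenerate-eigenvalue integrator requires.

Reduced units with m = hbar = omega = 1 are used throughout by default, so
energies are measured in units of the nuclear frequency.

The classical MMST mapping Hamiltonian built on this splitting is

    H = p^2/(2m) + U(x) + (1/2)[X^T Vt X + P^T Vt P - tr Vt],

with two mapping (electronic) position/momentum pairs (X_n, P_n).  The
state-independent part U couples classically; only the traceless part is
contracted with the mapping variables.

All functions broadcast over a leading batch axis: ``x`` may be a scalar or
an array of positions, matrices then gain matching leading dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelParams",
    "DiabaticMatrices",
    "AdiabaticFrame",
    "build_model",
    "potential",
    "adiabatize",
    "mmst_energy",
]

#: Table of preset model parameters (alpha, delta); kappa = 1 for all.
_PRESETS = {
    1: dict(alpha=0.0, delta=4.0),   # adiabatic limit (strong coupling)
    2: dict(alpha=2.0, delta=1.0),   # inverted Marcus regime (strong bias)
    3: dict(alpha=0.0, delta=1.0),   # intermediate regime
}


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the two-state linear vibronic model.

    ``alpha`` is half the diabatic energy bias (the bias between the two
    surfaces is ``2*alpha``), ``delta`` the constant off-diagonal electronic
    coupling and ``kappa`` the linear vibronic coupling.  ``beta`` is the
    inverse temperature used for equilibrium sampling.
    """

    alpha: float
    delta: float
    kappa: float = 1.0
    mass: float = 1.0
    omega: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "delta", "kappa", "mass", "omega", "beta"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")
        if self.omega <= 0:
            raise ValueError(f"omega must be positive, got {self.omega}")
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")

    @property
    def nstates(self) -> int:
        return 2


@dataclass(frozen=True)
class DiabaticMatrices:
    """Diabatic potential matrix and its traceless splitting at position x.

    ``V = U*I + Vt`` with ``Vt`` symmetric and traceless; ``dU`` and ``dVt``
    are the derivatives with respect to x.  For the linear vibronic family
    ``dVt`` is constant and ``Vt`` is linear in x, so all second x-derivatives
    of ``Vt`` vanish.
    """

    x: np.ndarray
    V: np.ndarray      # (..., 2, 2)
    U: np.ndarray      # (...,)
    Vt: np.ndarray     # (..., 2, 2)
    dU: np.ndarray     # (...,)
    dVt: np.ndarray    # (..., 2, 2)


@dataclass(frozen=True)
class AdiabaticFrame:
    """Eigendecomposition of the traceless diabatic matrix Vt at fixed x.

    ``Vt = S diag(Lam) S^T`` with eigenvalues sorted ascending and the
    eigenvector sign fixed so the largest-magnitude component of each column
    is positive (reproducible frames along a trajectory).  ``G = S^T dVt S``
    is the potential derivative in the adiabatic frame, ``dLam = diag(G)``
    the eigenvalue derivatives, and ``lamdiff[n, m] = Lam[m] - Lam[n]``.

    ``w`` is the skew-symmetric eigenvector-derivative generator
    (``dS/dx = S w``, ``w_nm = G_nm / (Lam_m - Lam_n)`` off the diagonal),
    needed for the analytic monodromy matrices; it is zero in the degenerate
    branch.
    """

    S: np.ndarray        # (..., 2, 2) orthogonal
    Lam: np.ndarray      # (..., 2)
    dLam: np.ndarray     # (..., 2)
    G: np.ndarray        # (..., 2, 2) symmetric
    lamdiff: np.ndarray  # (..., 2, 2)
    w: np.ndarray = field(repr=False, default=None)  # (..., 2, 2) skew


def build_model(preset: int | None = None, *, alpha: float | None = None,
                delta: float | None = None, kappa: float = 1.0,
                mass: float = 1.0, omega: float = 1.0,
                beta: float = 1.0) -> ModelParams:
    """Construct model parameters from a preset id (1-3) or explicitly.

    Presets: 1 -> (alpha=0, delta=4), adiabatic limit; 2 -> (alpha=2,
    delta=1), inverted Marcus regime; 3 -> (alpha=0, delta=1), intermediate
    regime.  kappa = m = omega = 1 in all presets; ``beta`` is configurable
    and defaults to 1 (reduced units).  Explicit keyword arguments override
    the preset values.
    """
    if preset is not None:
        if preset not in _PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose 1, 2 or 3")
        p = _PRESETS[preset]
        alpha = p["alpha"] if alpha is None else alpha
        delta = p["delta"] if delta is None else delta
    if alpha is None or delta is None:
        raise ValueError("either a preset or both alpha and delta required")
    return ModelParams(alpha=float(alpha), delta=float(delta),
                       kappa=float(kappa), mass=float(mass),
                       omega=float(omega), beta=float(beta))


def potential(model: ModelParams, x) -> DiabaticMatrices:
    """Evaluate V, U, Vt and their x-derivatives at nuclear position(s) x."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite nuclear position")
    a = model.kappa * x + model.alpha
    shape = x.shape + (2, 2)
    Vt = np.empty(shape)
    Vt[..., 0, 0] = a
    Vt[..., 0, 1] = model.delta
    Vt[..., 1, 0] = model.delta
    Vt[..., 1, 1] = -a
    U = 0.5 * model.mass * model.omega**2 * x**2
    dU = model.mass * model.omega**2 * x
    dVt = np.zeros(shape)
    dVt[..., 0, 0] = model.kappa
    dVt[..., 1, 1] = -model.kappa
    V = Vt + U[..., None, None] * np.eye(2)
    return DiabaticMatrices(x=x, V=V, U=U, Vt=Vt, dU=dU, dVt=dVt)


# gap below which the frame falls back to the identity (Vt ~ 0)
_DEGENERATE_GAP = 1e-12


def adiabatize(dm: DiabaticMatrices) -> AdiabaticFrame:
    """Diagonalize Vt with a fixed ordering and sign convention.

    Closed-form symmetric 2x2 eigensolve.  Eigenvalues ascend; each
    eigenvector's largest-magnitude component is made positive.  A degenerate
    Vt (gap below 1e-12, i.e. Vt ~ 0 for this traceless family) returns the
    identity frame with zero eigenvector-derivative generator.
    """
    Vt, dVt = dm.Vt, dm.dVt
    h11 = Vt[..., 0, 0]
    h12 = Vt[..., 0, 1]
    # traceless input: mean = 0, but keep the general form
    mean = 0.5 * (Vt[..., 0, 0] + Vt[..., 1, 1])
    dev = 0.5 * (Vt[..., 0, 0] - Vt[..., 1, 1])
    gamma = np.hypot(dev, h12)
    lam1 = mean - gamma
    lam2 = mean + gamma
    Lam = np.stack([lam1, lam2], axis=-1)

    degen = gamma < _DEGENERATE_GAP
    safe_gamma = np.where(degen, 1.0, gamma)

    # eigenvector for lam2 = mean + gamma: (h12, gamma - dev) or
    # (gamma + dev, h12), picking the numerically stable branch
    use_b = dev >= 0
    v2x = np.where(use_b, gamma + dev, h12)
    v2y = np.where(use_b, h12, gamma - dev)
    norm = np.sqrt(v2x**2 + v2y**2)
    norm = np.where(degen, 1.0, norm)
    v2x, v2y = v2x / norm, v2y / norm
    # eigenvector for lam1 is the orthogonal complement
    v1x, v1y = -v2y, v2x

    S = np.empty(Vt.shape)
    S[..., 0, 0], S[..., 1, 0] = v1x, v1y
    S[..., 0, 1], S[..., 1, 1] = v2x, v2y
    # sign fix: largest-magnitude component of each column positive
    for col in (0, 1):
        c0, c1 = S[..., 0, col], S[..., 1, col]
        lead = np.where(np.abs(c0) >= np.abs(c1), c0, c1)
        sgn = np.where(lead < 0, -1.0, 1.0)
        S[..., :, col] *= sgn[..., None]
    # degenerate branch: identity frame
    eye = np.broadcast_to(np.eye(2), S.shape)
    S = np.where(degen[..., None, None], eye, S)
    Lam = np.where(degen[..., None], 0.0, Lam)

    G = np.swapaxes(S, -1, -2) @ dVt @ S
    G = 0.5 * (G + np.swapaxes(G, -1, -2))  # symmetrize against roundoff
    dLam = np.stack([G[..., 0, 0], G[..., 1, 1]], axis=-1)

    lamdiff = Lam[..., None, :] - Lam[..., :, None]

    # eigenvector-derivative generator: w_nm = G_nm / (lam_m - lam_n)
    w = np.zeros_like(G)
    gap = lam2 - lam1
    w01 = np.where(degen, 0.0, G[..., 0, 1] / np.where(degen, 1.0, gap))
    w[..., 0, 1] = w01
    w[..., 1, 0] = -w01
    del h11, safe_gamma
    return AdiabaticFrame(S=S, Lam=Lam, dLam=dLam, G=G, lamdiff=lamdiff, w=w)


def mmst_energy(model: ModelParams, state) -> np.ndarray:
    """MMST mapping energy H(x, p, X, P) for the traceless splitting.

    H = p^2/2m + U(x) + (1/2)[X^T Vt X + P^T Vt P - tr Vt].  Broadcasts over
    batched states; returns a scalar for unbatched input.
    """
    x, p, X, P = state.x, state.p, state.X, state.P
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(p))
            and np.all(np.isfinite(X)) and np.all(np.isfinite(P))):
        raise ValueError("non-finite phase-space state")
    dm = potential(model, x)
    quad = (np.einsum("...i,...ij,...j->...", X, dm.Vt, X)
            + np.einsum("...i,...ij,...j->...", P, dm.Vt, P))
    trVt = dm.Vt[..., 0, 0] + dm.Vt[..., 1, 1]
    return p**2 / (2.0 * model.mass) + dm.U + 0.5 * (quad - trVt)
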