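"""Monodromy matrices and symplecticity / Liouville / energy diagnostics.

The monodromy matrix M(t) = dz(t)/dz(0) is accumulated step by step,
M(t_k) = M_step(k) @ M(t_{k-1}), from the analytic Jacobian of each
composed flow-map step.  Three scalar diagnostics track integrator quality:

* symplecticity error  ||M^T J M - J||_F  (zero iff the flow preserves the
  symplectic two-form),
* Liouville error  (det M - 1)^2  (zero iff phase-space volume is
  preserved; a strictly weaker condition),
* energy criterion  (eps(t) - eps(0))^2  with eps the MMST energy.

Ensemble curves are averages over trajectories weighted by the equilibrium
sampling weight W.  A central-difference Jacobian of any flow map is
provided as an independent oracle for the analytic factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .propagators import (
    PhaseSpacePoint,
    StepPlan,
    _eye6,
    _frame_at,
    _full_step,
    structure_matrix,
)
from .vibronic_model import (
    AdiabaticFrame,
    DiabaticMatrices,
    ModelParams,
    mmst_energy,
)

__all__ = [
    "MonodromyMatrix",
    "DiagnosticSeries",
    "monodromy_step",
    "accumulate",
    "symplecticity_error",
    "liouville_error",
    "fd_monodromy",
    "weighted_ensemble_series",
    "ensemble_diagnostics",
]


@dataclass
class MonodromyMatrix:
    """6x6 Jacobian(s) of evolved phase space w.r.t. initial phase space.

    Stored in the documented ordering z = (x, X1, X2, p, P1, P2); may carry
    a leading batch shape.  M(t=0) is the identity.
    """

    M: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape[-2:] != (6, 6):
            raise ValueError("monodromy matrices must be (..., 6, 6)")
        if not np.all(np.isfinite(self.M)):
            raise ValueError("non-finite monodromy entries")

    @classmethod
    def identity(cls, batch_shape: tuple = ()) -> "MonodromyMatrix":
        return cls(M=_eye6(batch_shape), t=0.0)


@dataclass
class DiagnosticSeries:
    """Per-time diagnostic curves for one trajectory or a weighted ensemble.

    All series are nonnegative; ``sympl_error[0]`` vanishes because the
    monodromy matrix starts as the identity.  ``weight`` is the W of the
    underlying trajectory (or the total weight after averaging).
    """

    times: np.ndarray
    sympl_error: np.ndarray | None = None
    liouville_error: np.ndarray | None = None
    energy_criterion: np.ndarray | None = None
    weight: np.ndarray | float = 1.0


def monodromy_step(plan: StepPlan, state: PhaseSpacePoint,
                   frame: AdiabaticFrame | None,
                   dm: DiabaticMatrices | None,
                   model: ModelParams) -> MonodromyMatrix:
    """Analytic Jacobian of one composed step starting from ``state``.

    ``frame``/``dm`` are the adiabatic frame and potential at the starting
    position (recomputed when None); the factors for the second H2 half-step
    are evaluated at the drifted position internally.  The determinant of
    the returned factor is unity for all three algorithms.
    """
    if dm is None or frame is None:
        dm, frame = _frame_at(model, state.x)
    *_, M = _full_step(model, plan, state.x.copy(), state.p.copy(),
                       state.X.copy(), state.P.copy(), dm, frame, True)
    return MonodromyMatrix(M=M, t=state.t + plan.dt)


def accumulate(factors: Sequence) -> MonodromyMatrix:
    """Chain time-ordered per-step factors into the trajectory monodromy.

    The newest factor multiplies from the left; an empty sequence gives the
    identity.
    """
    M = None
    t = 0.0
    for f in factors:
        F = f.M if isinstance(f, MonodromyMatrix) else np.asarray(f, float)
        if F.shape[-2:] != (6, 6):
            raise ValueError("factor shape mismatch; expected (..., 6, 6)")
        M = F.copy() if M is None else F @ M
        if isinstance(f, MonodromyMatrix):
            t = f.t
    if M is None:
        return MonodromyMatrix.identity()
    return MonodromyMatrix(M=M, t=t)


def _as_matrix(M) -> np.ndarray:
    return M.M if isinstance(M, MonodromyMatrix) else np.asarray(M, float)


def symplecticity_error(M) -> np.ndarray:
    """Frobenius norm of the error matrix E_r = M^T J M - J.

    Zero iff the symplecticity criterion M^T J M = J holds.  The norm runs
    over all 36 entries with no normalization by the matrix size.
    """
    A = _as_matrix(M)
    J = structure_matrix()
    Er = np.swapaxes(A, -1, -2) @ J @ A - J
    return np.sqrt(np.sum(Er**2, axis=(-2, -1)))


def liouville_error(M) -> np.ndarray:
    """Squared deviation of det(M) from unity (volume preservation).

    Squaring prevents error cancellation when averaging over trajectories.
    """
    A = _as_matrix(M)
    return (np.linalg.det(A) - 1.0) ** 2


def fd_monodromy(stepper: Callable[[PhaseSpacePoint], PhaseSpacePoint],
                 state: PhaseSpacePoint, h: float = 1e-6) -> MonodromyMatrix:
    """Central-difference Jacobian of an arbitrary flow map (test oracle).

    ``stepper`` maps a PhaseSpacePoint to a PhaseSpacePoint; ``h`` is the
    displacement applied to each phase-space coordinate in turn.
    """
    if not (1e-8 <= h <= 1e-4):
        raise ValueError("h must lie in [1e-8, 1e-4]")
    if state.batch_shape != ():
        raise ValueError("fd_monodromy expects an unbatched state")
    z0 = state.z
    cols = []
    for j in range(6):
        dz = np.zeros(6)
        dz[j] = h
        zp = stepper(PhaseSpacePoint.from_z(z0 + dz, t=state.t)).z
        zm = stepper(PhaseSpacePoint.from_z(z0 - dz, t=state.t)).z
        if not (np.all(np.isfinite(zp)) and np.all(np.isfinite(zm))):
            raise FloatingPointError("non-finite perturbed evaluation")
        cols.append((zp - zm) / (2.0 * h))
    return MonodromyMatrix(M=np.stack(cols, axis=-1), t=state.t)


def weighted_ensemble_series(series: Sequence[DiagnosticSeries],
                             weights: Sequence[float] | None = None
                             ) -> DiagnosticSeries:
    """W-weighted mean of equal-length diagnostic series at each time point.

    Weights default to each series' own ``weight``; they must be nonnegative
    with a positive sum.
    """
    series = list(series)
    if not series:
        raise ValueError("no series to average")
    W = np.asarray([s.weight for s in series] if weights is None
                   else list(weights), dtype=float)
    if np.any(W < 0) or not np.all(np.isfinite(W)):
        raise ValueError("weights must be finite and nonnegative")
    tot = W.sum()
    if tot <= 0:
        raise ValueError("total weight must be positive")
    times = series[0].times
    for s in series[1:]:
        if len(s.times) != len(times):
            raise ValueError("series lengths differ")

    def avg(attr):
        vals = [getattr(s, attr) for s in series]
        if any(v is None for v in vals):
            return None
        stacked = np.stack([np.asarray(v, float) for v in vals], axis=-1)
        return stacked @ W / tot

    return DiagnosticSeries(times=times,
                            sympl_error=avg("sympl_error"),
                            liouville_error=avg("liouville_error"),
                            energy_criterion=avg("energy_criterion"),
                            weight=tot)


def ensemble_diagnostics(state0: PhaseSpacePoint, model: ModelParams,
                         plan: StepPlan, nsteps: int,
                         weights: np.ndarray | None = None,
                         per_trajectory: bool = False):
    """Propagate (a batch of) initial conditions with monodromy accumulation
    and return the W-weighted DiagnosticSeries.

    This is the batched workhorse behind the `diagnose` experiments: all
    trajectories advance together and the three criteria are evaluated at
    every step without storing the trajectory history.  With
    ``per_trajectory=True`` the unaveraged (nsteps+1, ...) arrays are
    returned alongside the averaged series.
    """
    batch = state0.batch_shape
    if weights is None:
        weights = np.ones(batch if batch else ())
    weights = np.asarray(weights, dtype=float)
    x, p = state0.x.copy(), state0.p.copy()
    X, P = state0.X.copy(), state0.P.copy()
    dm, frame = _frame_at(model, x)
    M = _eye6(batch)
    e0 = mmst_energy(model, PhaseSpacePoint(x, p, X, P))
    sympl = [np.zeros(batch)]
    liou = [np.zeros(batch)]
    ecrit = [np.zeros(batch)]
    from .propagators import _full_step as step  # local alias
    for _ in range(nsteps):
        x, p, X, P, dm, frame, Mstep = step(model, plan, x, p, X, P,
                                            dm, frame, True)
        M = Mstep @ M
        sympl.append(symplecticity_error(M))
        liou.append(liouville_error(M))
        e = mmst_energy(model, PhaseSpacePoint(x, p, X, P))
        ecrit.append((e - e0) ** 2)
    times = np.arange(nsteps + 1) * plan.dt
    sympl = np.stack(sympl)
    liou = np.stack(liou)
    ecrit = np.stack(ecrit)
    if batch:
        tot = weights.sum()
        if tot <= 0:
            raise ValueError("total weight must be positive")
        averaged = DiagnosticSeries(
            times=times,
            sympl_error=sympl @ weights / tot,
            liouville_error=liou @ weights / tot,
            energy_criterion=ecrit @ weights / tot,
            weight=tot)
    else:
        averaged = DiagnosticSeries(times=times, sympl_error=sympl,
                                    liouville_error=liou,
                                    energy_criterion=ecrit,
                                    weight=float(np.asarray(weights)))
    if per_trajectory:
        return averaged, dict(sympl=sympl, liouville=liou, energy=ecrit,
                              monodromy=M)
    return averaged
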