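"""Thermal correlation functions and the energy-conservation criterion.

Position and population autocorrelation functions are estimated over a
W-weighted ensemble of trajectories,

    C_xx(t)  = < W x(0) x(t) >_rho   / < W >,
    C_11(t)  = < W n1(0) n1(t) >_rho / < W >,

with n1 the mapping population estimator (X_1^2 + P_1^2 - 1)/2.  Standard
errors come from a delete-one weighted jackknife over trajectories (the
whole ratio estimator is recomputed with each member removed), which
correctly handles the correlated numerator and denominator.

The energy criterion is the squared deviation (eps(t) - eps(0))^2 of the
MMST energy from its initial value; it vanishes under perfect conservation
and scales as dt^4 for a second-order integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble_sampling import WeightedEnsemble, population_at_t
from .propagators import (
    PhaseSpacePoint,
    StepPlan,
    Trajectory,
    _frame_at,
    _full_step,
)
from .stability_diagnostics import DiagnosticSeries
from .vibronic_model import ModelParams, mmst_energy

__all__ = [
    "CorrelationResult",
    "energy_criterion_series",
    "correlation_functions",
]


@dataclass
class CorrelationResult:
    """Autocorrelation curves with jackknife error bands.

    ``Cxx`` is the nuclear-position autocorrelation, ``C11`` the
    population-1 autocorrelation; ``stderr_Cxx``/``stderr_C11`` are
    one-sigma jackknife bands.  ``config`` snapshots the run parameters.
    """

    times: np.ndarray
    Cxx: np.ndarray
    C11: np.ndarray
    n_traj: int
    stderr_Cxx: np.ndarray
    stderr_C11: np.ndarray
    config: dict = field(default_factory=dict)


def energy_criterion_series(traj: Trajectory) -> DiagnosticSeries:
    """Per-time energy criterion (eps(t) - eps(0))^2 for a trajectory.

    Invariant under time reversal of the trajectory (it compares each
    energy against the initial one).  Batched trajectories yield batched
    curves; combine with
    :func:`mmstdyn.stability_diagnostics.weighted_ensemble_series`.
    """
    e = np.asarray(traj.energies)
    crit = (e - e[0]) ** 2
    w = 1.0 if traj.weight is None else traj.weight
    return DiagnosticSeries(times=traj.times, energy_criterion=crit,
                            weight=w)


def _jackknife_ratio(num: np.ndarray, w: np.ndarray) -> tuple:
    """Weighted ratio estimate sum(num)/sum(w) per row with delete-one SE.

    ``num`` has shape (T, B) (already weighted numerator contributions),
    ``w`` shape (B,).  Returns (ratio (T,), stderr (T,)).
    """
    B = w.size
    A = num.sum(axis=-1)
    Wtot = w.sum()
    ratio = A / Wtot
    if B < 2:
        return ratio, np.full_like(ratio, np.nan)
    loo = (A[:, None] - num) / (Wtot - w)[None, :]
    mean_loo = loo.mean(axis=-1)
    se = np.sqrt((B - 1) / B * np.sum((loo - mean_loo[:, None]) ** 2,
                                      axis=-1))
    return ratio, se


def correlation_functions(ens: WeightedEnsemble, plan: StepPlan,
                          nsteps: int) -> CorrelationResult:
    """Propagate every ensemble member and accumulate the W-weighted
    position and population autocorrelation functions.

    All members advance together (batched propagation); only the product
    series x(0)x(t) and n1(0)n1(t) are stored, not the trajectories.
    """
    w = ens.weights
    if w.sum() <= 0:
        raise ValueError("zero total weight")
    model = ens.model
    s = ens.states
    x, p = s.x.copy(), s.p.copy()
    X, P = s.X.copy(), s.P.copy()
    dm, frame = _frame_at(model, x)
    x0 = x.copy()
    n1_0 = 0.5 * (X[:, 0] ** 2 + P[:, 0] ** 2 - 1.0)
    prod_x = [w * x0 * x0]
    prod_n = [w * n1_0 * n1_0]
    for _ in range(nsteps):
        x, p, X, P, dm, frame, _ = _full_step(model, plan, x, p, X, P,
                                              dm, frame, False)
        n1 = 0.5 * (X[:, 0] ** 2 + P[:, 0] ** 2 - 1.0)
        prod_x.append(w * x0 * x)
        prod_n.append(w * n1_0 * n1)
    prod_x = np.stack(prod_x)
    prod_n = np.stack(prod_n)
    Cxx, se_x = _jackknife_ratio(prod_x, w)
    C11, se_n = _jackknife_ratio(prod_n, w)
    times = np.arange(nsteps + 1) * plan.dt
    cfg = dict(algorithm=plan.algorithm, dt=plan.dt, nsteps=nsteps,
               n_traj=len(ens), seed=ens.seed,
               sandwich_order=plan.sandwich_order,
               model=dict(alpha=model.alpha, delta=model.delta,
                          kappa=model.kappa, mass=model.mass,
                          omega=model.omega, beta=model.beta))
    return CorrelationResult(times=times, Cxx=Cxx, C11=C11, n_traj=len(ens),
                             stderr_Cxx=se_x, stderr_C11=se_n, config=cfg)
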