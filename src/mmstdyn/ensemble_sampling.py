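"""Equilibrium sampling of mapping-variable initial conditions.

Initial conditions for thermal correlation functions are drawn from the
single-bead mapping distribution

    rho(x, p, X, P) = exp(-beta p^2/2m) exp(-beta U(x))
                      exp(-(X^T X + P^T P)) W(x, X, P),

where the nonnegative weight is the squared bilinear form

    W = P^T M X X^T M P = (X^T M P)^2,      M = exp(-beta Vt(x) / 2).

With this kernel the Gaussian mapping moments give <W> proportional to
tr exp(-beta Vt), the exact electronic partition function at fixed x, so
W-weighted averages reproduce quantum electronic equilibrium statistics for
classical nuclei.  Sampling is by importance sampling: (x, p) are drawn
from the Gaussian nuclear factor, (X, P) from the Gaussian mapping factor
(variance 1/2 per component), and W is carried as the weight — fully
deterministic for a given seed.

Two population estimators are provided: the equilibrium (t = 0 only)
estimator pop_n = <W_n>/<W> with W_n = (X^T M P) X_n (M P)_n (the W_n sum
to W identically, so populations sum to one), and the mapping-variable
estimator pop_n(t) = (X_n^2 + P_n^2 - 1)/2 valid along trajectories.  The
two agree at t = 0 in expectation.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np

from .propagators import PhaseSpacePoint
from .vibronic_model import ModelParams, adiabatize, potential

__all__ = [
    "WeightedEnsemble",
    "sampling_kernel",
    "weight_W",
    "sample_initial",
    "population_at_t",
    "initial_population",
    "effective_sample_size",
]


@dataclass
class WeightedEnsemble:
    """Sampled initial conditions with importance weights W.

    ``states`` is a single batched :class:`PhaseSpacePoint` holding all n
    members (indexable via :meth:`member`); ``weights`` the per-member W.
    ``sampler_meta`` records the proposal parameters and effective sample
    size so under-sampling is visible.
    """

    states: PhaseSpacePoint
    weights: np.ndarray
    seed: int
    model: ModelParams
    sampler_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != self.states.batch_shape:
            raise ValueError("weights and states lengths differ")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")

    def __len__(self) -> int:
        return int(np.prod(self.states.batch_shape))

    def member(self, i: int) -> PhaseSpacePoint:
        s = self.states
        return PhaseSpacePoint(s.x[i], s.p[i], s.X[i], s.P[i], s.t)

    @property
    def ess(self) -> float:
        return effective_sample_size(self.weights)

    # -- plain-text serialization (lossless round trip) -------------------

    _COLUMNS = ("x", "p", "X1", "X2", "P1", "P2", "W")

    def to_csv(self, path_or_buf) -> None:
        """Write the ensemble as CSV with full double precision.

        Model parameters and the seed are embedded in ``#``-prefixed header
        comments so the file round-trips without a sidecar.
        """
        s = self.states
        m = self.model
        header = (
            f"# mmstdyn ensemble seed={self.seed}\n"
            f"# model alpha={m.alpha!r} delta={m.delta!r} kappa={m.kappa!r}"
            f" mass={m.mass!r} omega={m.omega!r} beta={m.beta!r}\n"
        )
        cols = np.column_stack([s.x, s.p, s.X[:, 0], s.X[:, 1],
                                s.P[:, 0], s.P[:, 1], self.weights])
        own = isinstance(path_or_buf, (str, bytes, os.PathLike))
        fh = open(path_or_buf, "w") if own else path_or_buf
        try:
            fh.write(header)
            fh.write(",".join(self._COLUMNS) + "\n")
            np.savetxt(fh, cols, delimiter=",", fmt="%.17g")
        finally:
            if own:
                fh.close()

    @classmethod
    def from_csv(cls, path_or_buf) -> "WeightedEnsemble":
        own = isinstance(path_or_buf, (str, bytes, os.PathLike))
        fh = open(path_or_buf) if own else path_or_buf
        try:
            text = fh.read()
        finally:
            if own:
                fh.close()
        seed = 0
        kwargs = {}
        lines = text.splitlines()
        for ln in lines:
            if ln.startswith("# mmstdyn ensemble"):
                seed = int(ln.split("seed=")[1].split()[0])
            elif ln.startswith("# model"):
                for tok in ln.replace("# model", "").split():
                    k, v = tok.split("=")
                    kwargs[k] = float(v)
        data = np.loadtxt(io.StringIO(
            "\n".join(l for l in lines if not l.startswith("#"))),
            delimiter=",", skiprows=1, ndmin=2)
        model = ModelParams(**kwargs)
        states = PhaseSpacePoint(x=data[:, 0], p=data[:, 1],
                                 X=data[:, 2:4], P=data[:, 4:6])
        return cls(states=states, weights=data[:, 6], seed=seed, model=model)


def sampling_kernel(model: ModelParams, x) -> np.ndarray:
    """The 2x2 kernel M(x) = exp(-beta Vt(x)/2) of the weight W.

    Evaluated through the closed-form eigendecomposition of Vt, so it
    broadcasts over batched positions.
    """
    frame = adiabatize(potential(model, x))
    expo = np.exp(-0.5 * model.beta * frame.Lam)
    return np.einsum("...ik,...k,...jk->...ij", frame.S, expo, frame.S)


def weight_W(model: ModelParams, x, X, P) -> np.ndarray:
    """Nonnegative sampling weight W = P^T M X X^T M P = (X^T M P)^2."""
    x = np.asarray(x, dtype=float)
    X = np.asarray(X, dtype=float)
    P = np.asarray(P, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(X))
            and np.all(np.isfinite(P))):
        raise ValueError("non-finite inputs to weight_W")
    M = sampling_kernel(model, x)
    bilinear = np.einsum("...i,...ij,...j->...", X, M, P)
    return bilinear**2


def sample_initial(model: ModelParams, n: int, seed: int) -> WeightedEnsemble:
    """Draw an importance-sampled ensemble of n initial conditions.

    Proposals: x ~ N(0, 1/(beta m omega^2)), p ~ N(0, m/beta) from the
    nuclear Boltzmann factor; each mapping component ~ N(0, 1/2) from the
    Gaussian mapping factor.  All variates come from one numpy Generator
    seeded with ``seed`` in a fixed draw order, so ensembles are exactly
    reproducible.  The effective sample size (sum W)^2 / sum W^2 is recorded
    in ``sampler_meta``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sig_x = 1.0 / np.sqrt(model.beta * model.mass * model.omega**2)
    sig_p = np.sqrt(model.mass / model.beta)
    x = rng.normal(0.0, sig_x, size=n)
    p = rng.normal(0.0, sig_p, size=n)
    X = rng.normal(0.0, np.sqrt(0.5), size=(n, 2))
    P = rng.normal(0.0, np.sqrt(0.5), size=(n, 2))
    W = weight_W(model, x, X, P)
    meta = dict(proposal=dict(sigma_x=sig_x, sigma_p=sig_p,
                              sigma_mapping=np.sqrt(0.5)),
                ess=effective_sample_size(W), n=n)
    return WeightedEnsemble(states=PhaseSpacePoint(x, p, X, P, t=0.0),
                            weights=W, seed=int(seed), model=model,
                            sampler_meta=meta)


def effective_sample_size(weights: np.ndarray) -> float:
    w = np.asarray(weights, dtype=float)
    s = w.sum()
    if s <= 0:
        return 0.0
    return float(s**2 / np.sum(w**2))


def population_at_t(state: PhaseSpacePoint, n: int) -> np.ndarray:
    """Mapping-variable population estimator (X_n^2 + P_n^2 - 1)/2.

    ``n`` is the 1-based electronic state index.  Valid at any time along a
    trajectory; the two estimators sum to (sum_m X_m^2 + P_m^2)/2 - 1,
    which is conserved because all three integrators conserve electronic
    probability.
    """
    if n not in (1, 2):
        raise ValueError("state index must be 1 or 2")
    i = n - 1
    return 0.5 * (state.X[..., i] ** 2 + state.P[..., i] ** 2 - 1.0)


def initial_population(ens: WeightedEnsemble, n: int) -> float:
    """Equilibrium population of state n from the t = 0 estimator.

    pop_n = <W_n> / <W> with W_n = (X^T M P) X_n (M P)_n; the W_n sum to W
    member by member, so the populations sum to one up to Monte-Carlo noise
    in the shared denominator (exactly, in fact, since numerator sums
    telescope).  Only valid on the unpropagated ensemble.
    """
    if n not in (1, 2):
        raise ValueError("state index must be 1 or 2")
    tot = ens.weights.sum()
    if tot <= 0:
        raise ValueError("zero total weight")
    s = ens.states
    M = sampling_kernel(ens.model, s.x)
    bilinear = np.einsum("...i,...ij,...j->...", s.X, M, s.P)
    MP = np.einsum("...ij,...j->...i", M, s.P)
    Wn = bilinear * s.X[..., n - 1] * MP[..., n - 1]
    return float(Wn.sum() / tot)
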