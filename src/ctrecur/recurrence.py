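"""Time-delay embedding, fuzzy c-means and fuzzy recurrence plots.

A scalar series is embedded into phase space, partitioned with fuzzy c-means
(FCM), and the pairwise recurrence grades are inferred from the membership
matrix by max-min fuzzy-relation composition:

    R(i, j) = max_k min(mu(y_i, v_k), mu(v_k, y_j)),  R(i, i) = 1.

The result is a symmetric L x L matrix of grades in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import InputError

__all__ = ["PhaseSpace", "FuzzyPartition", "FRPMatrix", "embed", "fcm_partition", "frp"]

logger = logging.getLogger(__name__)


@dataclass
class PhaseSpace:
    """Delay-embedded trajectory: L points of dimension m at delay tau."""

    points: np.ndarray  # (L, m)
    m: int
    tau: int

    @property
    def L(self) -> int:
        return self.points.shape[0]


@dataclass
class FuzzyPartition:
    """FCM output: membership grades of L points against c cluster centres."""

    memberships: np.ndarray  # (L, c), rows sum to 1
    centres: np.ndarray  # (c, m)
    fuzzifier: float
    converged: bool
    objective: float
    seed: int | None = None

    @property
    def c(self) -> int:
        return self.memberships.shape[1]

    @property
    def L(self) -> int:
        return self.memberships.shape[0]


@dataclass
class FRPMatrix:
    """Fuzzy recurrence plot: symmetric L x L grades in [0, 1], unit diagonal."""

    R: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=np.float64)
        if self.R.ndim != 2 or self.R.shape[0] != self.R.shape[1]:
            raise InputError("recurrence matrix must be square")

    @property
    def L(self) -> int:
        return self.R.shape[0]


def embed(series, m: int, tau: int) -> PhaseSpace:
    """Delay-embed a series: point i is (x_i, x_{i+tau}, ..., x_{i+(m-1)tau}).

    Raises :class:`InputError` when the series is shorter than the
    ``(m - 1) * tau + 1`` samples needed for at least one point.
    """
    x = np.asarray(series, dtype=np.float64).ravel()
    if m < 1 or tau < 1:
        raise InputError("embedding dimension m and delay tau must be >= 1")
    T = x.size
    L = T - (m - 1) * tau
    if L <= 0:
        raise InputError(
            f"series of length {T} too short for m={m}, tau={tau}; "
            f"need at least {(m - 1) * tau + 1} samples"
        )
    idx = np.arange(L)[:, None] + tau * np.arange(m)[None, :]
    return PhaseSpace(points=x[idx], m=m, tau=tau)


def _fcm_run(Y: np.ndarray, c: int, fuzzifier: float, tol: float, max_iter: int,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, bool, float]:
    """One FCM descent from a random membership initialization."""
    L = Y.shape[0]
    U = rng.random((L, c))
    U /= U.sum(axis=1, keepdims=True)
    exponent = 2.0 / (fuzzifier - 1.0)
    converged = False
    for _ in range(max_iter):
        Um = U ** fuzzifier
        V = (Um.T @ Y) / Um.sum(axis=0)[:, None]
        d = cdist(Y, V)
        zero = d <= 0.0
        if zero.any():
            # points coincident with centres get full grade split among them
            U_new = np.zeros_like(U)
            hit = zero.any(axis=1)
            U_new[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
            dn = d[~hit]
            U_new[~hit] = 1.0 / ((dn[:, :, None] / dn[:, None, :]) ** exponent).sum(axis=2)
        else:
            U_new = 1.0 / ((d[:, :, None] / d[:, None, :]) ** exponent).sum(axis=2)
        shift = np.abs(U_new - U).max()
        U = U_new
        if shift < tol:
            converged = True
            break
    d = cdist(Y, V)
    objective = float(((U ** fuzzifier) * d ** 2).sum())
    return U, V, converged, objective


def fcm_partition(ps: PhaseSpace, c: int = 10, fuzzifier: float = 2.0,
                  tol: float = 1e-5, max_iter: int = 1000, seed: int | None = None,
                  n_restarts: int = 5) -> FuzzyPartition:
    """Fuzzy c-means partition of the phase-space points.

    Standard Bezdek iteration with random membership initialization from the
    seeded generator.  Degenerate runs (non-finite centres or objective) are
    retried up to ``n_restarts`` times with fresh draws; the best finite
    objective wins.  Deterministic given ``seed``.
    """
    Y = np.asarray(ps.points, dtype=np.float64)
    L = Y.shape[0]
    if not 1 <= c <= L:
        raise InputError(f"cluster count c={c} must lie in [1, L={L}]")
    if fuzzifier <= 1.0:
        raise InputError("fuzzifier must be > 1")
    if c == 1:
        U = np.ones((L, 1))
        V = Y.mean(axis=0, keepdims=True)
        return FuzzyPartition(U, V, fuzzifier, True, 0.0, seed)

    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, bool, float] | None = None
    for attempt in range(n_restarts):
        U, V, converged, objective = _fcm_run(Y, c, fuzzifier, tol, max_iter, rng)
        ok = np.isfinite(objective) and np.isfinite(V).all() and np.isfinite(U).all()
        if ok and (best is None or objective < best[3]):
            best = (U, V, converged, objective)
        if ok and converged and attempt == 0:
            break  # common case: clean first run, no restarts needed
    if best is None:
        raise InputError("FCM failed to produce a finite partition after restarts")
    U, V, converged, objective = best
    if not converged:
        logger.warning("FCM did not converge within max_iter=%d (tol=%g)", max_iter, tol)
    return FuzzyPartition(U, V, fuzzifier, converged, objective, seed)


def frp(partition: FuzzyPartition) -> FRPMatrix:
    """Fuzzy recurrence plot from a partition by max-min composition.

    ``R(i, j) = max_k min(mu_ik, mu_jk)`` for i != j, unit diagonal;
    symmetric by construction.
    """
    U = partition.memberships
    # max over k of elementwise min of column-k outer pairs
    R = np.minimum(U[:, None, :], U[None, :, :]).max(axis=2)
    np.fill_diagonal(R, 1.0)
    return FRPMatrix(R)
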