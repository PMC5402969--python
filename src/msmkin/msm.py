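"""Microstate Markov state model estimation.

Transition counting at a lag time, symmetrized (reversible) transition-matrix
estimation on the largest strongly connected component, stationary
distributions, implied timescales and Markovian lag-time selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse
from scipy.sparse.csgraph import connected_components

__all__ = [
    "DiscreteTrajectorySet",
    "CountMatrix",
    "TransitionModel",
    "ImpliedTimescaleScan",
    "count_transitions",
    "estimate_tmatrix",
    "stationary_distribution",
    "implied_timescales",
    "select_markov_lag",
]


@dataclass(frozen=True)
class DiscreteTrajectorySet:
    """Integer state sequences from independent trajectories.

    dtrajs : list of 1-D int arrays (states in 0..n_states-1)
    frame_time : time between consecutive frames, ns
    n_states : state-alphabet size
    """

    dtrajs: list
    frame_time: float
    n_states: int

    def __post_init__(self):
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")
        dtrajs = [np.asarray(d, dtype=np.int64) for d in self.dtrajs]
        for d in dtrajs:
            if len(d) and (d.min() < 0 or d.max() >= self.n_states):
                raise ValueError("states must lie in [0, n_states)")
        object.__setattr__(self, "dtrajs", dtrajs)

    @property
    def n_frames(self) -> int:
        return sum(len(d) for d in self.dtrajs)


@dataclass(frozen=True)
class CountMatrix:
    """Transition counts at a fixed lag."""

    counts: np.ndarray
    lag_in_frames: int
    frame_time: float

    @property
    def lag(self) -> float:
        """Lag time in ns."""
        return self.lag_in_frames * self.frame_time

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class TransitionModel:
    """Row-stochastic transition matrix at a stated lag time.

    transition_matrix : (k, k) on the connected state set
    lag : lag time in ns
    stationary : stationary distribution pi (piT = pi)
    state_map : original state index for each model state (ergodic trimming
        may have removed states)
    """

    transition_matrix: np.ndarray
    lag: float
    stationary: np.ndarray
    state_map: np.ndarray

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]


@dataclass(frozen=True)
class ImpliedTimescaleScan:
    """Implied timescales -tau/ln(lambda_i) across a set of lag times.

    timescales[i, j] is the j-th slowest timescale at lags_ns[i]; entries
    are NaN (and defined[i, j] False) where the eigenvalue was <= 0.
    """

    lags_ns: np.ndarray
    timescales: np.ndarray
    defined: np.ndarray


def count_transitions(dtrajs: DiscreteTrajectorySet, lag_in_frames: int) -> CountMatrix:
    """Sliding-window transition counts at the given lag.

    Every frame t with t + lag inside the same trajectory contributes the
    ordered pair (s_t, s_{t+lag}); pairs never span trajectory boundaries.
    """
    if lag_in_frames < 1:
        raise ValueError("lag_in_frames must be >= 1")
    n = dtrajs.n_states
    counts = np.zeros((n, n), dtype=float)
    any_pairs = False
    for d in dtrajs.dtrajs:
        if len(d) <= lag_in_frames:
            continue
        any_pairs = True
        i, j = d[:-lag_in_frames], d[lag_in_frames:]
        np.add.at(counts, (i, j), 1.0)
    if not any_pairs:
        raise ValueError(
            f"lag of {lag_in_frames} frames is too long for every trajectory"
        )
    return CountMatrix(counts=counts, lag_in_frames=int(lag_in_frames),
                       frame_time=dtrajs.frame_time)


def _largest_scc(counts: np.ndarray) -> np.ndarray:
    """Indices of the largest strongly connected component of the count graph,
    weighted by total counts to break size ties toward the data-rich component."""
    graph = scipy.sparse.csr_matrix(counts > 0)
    n_comp, labels = connected_components(graph, directed=True, connection="strong")
    best, best_weight = None, -1.0
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        w = counts[np.ix_(idx, idx)].sum()
        if len(idx) >= 2 and (best is None or w > best_weight):
            best, best_weight = idx, w
    if best is None:
        raise ValueError("no strongly connected component with >= 2 states")
    return best


def estimate_tmatrix(counts: CountMatrix) -> TransitionModel:
    """Symmetrize-and-normalize transition-matrix estimator.

    Restricts to the largest strongly connected component, symmetrizes
    C' = (C + C^T)/2 and row-normalizes.  The resulting chain satisfies
    detailed balance exactly, and its stationary distribution equals the
    normalized row sums of C'.
    """
    idx = _largest_scc(counts.counts)
    C = counts.counts[np.ix_(idx, idx)]
    Csym = 0.5 * (C + C.T)
    row = Csym.sum(axis=1)
    if np.any(row == 0):
        raise ValueError("state with zero counts inside connected component")
    T = Csym / row[:, None]
    pi = row / row.sum()
    return TransitionModel(transition_matrix=T, lag=counts.lag,
                           stationary=pi, state_map=idx)


def stationary_distribution(T: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix.

    Solves for the left eigenvector of eigenvalue 1; rejects reducible
    matrices (non-unique fixed point).
    """
    T = np.asarray(T, dtype=float)
    graph = scipy.sparse.csr_matrix(T > 0)
    n_comp, _ = connected_components(graph, directed=True, connection="strong")
    if n_comp != 1:
        raise ValueError("transition matrix is reducible; stationary "
                         "distribution is not unique")
    vals, vecs = scipy.linalg.eig(T.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    pi /= pi.sum()
    if not np.allclose(pi @ T, pi, atol=max(tol, 1e-8)):
        raise ValueError("failed to solve for stationary distribution")
    return pi


def _timescales_from_T(T: np.ndarray, pi: np.ndarray, lag_ns: float, m: int):
    """Top-m implied timescales of a reversible T via the symmetric
    similarity transform D^{1/2} T D^{-1/2} (numerically stable eigvalsh)."""
    d = np.sqrt(pi)
    sym = (d[:, None] * T) / d[None, :]
    sym = 0.5 * (sym + sym.T)
    ev = np.sort(np.linalg.eigvalsh(sym))[::-1]
    ev = ev[1:m + 1]  # drop the Perron eigenvalue 1
    ts = np.full(m, np.nan)
    ok = np.zeros(m, dtype=bool)
    for j, lam in enumerate(ev):
        if 0 < lam < 1:
            ts[j] = -lag_ns / np.log(lam)
            ok[j] = True
    return ts, ok


def implied_timescales(
    dtrajs: DiscreteTrajectorySet, lags, m: int = 3
) -> ImpliedTimescaleScan:
    """Implied timescale scan over lag times (lags given in frames).

    At each lag tau the model is re-estimated and the m slowest relaxation
    times -tau/ln(lambda_i) are reported; non-positive eigenvalues yield
    undefined (NaN, flagged) entries rather than being dropped.
    """
    lags = [int(l) for l in lags]
    ts = np.full((len(lags), m), np.nan)
    ok = np.zeros((len(lags), m), dtype=bool)
    lag_ns = np.empty(len(lags))
    for i, lag in enumerate(lags):
        model = estimate_tmatrix(count_transitions(dtrajs, lag))
        lag_ns[i] = model.lag
        mm = min(m, model.n_states - 1)
        ts[i, :mm], ok[i, :mm] = _timescales_from_T(
            model.transition_matrix, model.stationary, model.lag, mm)
    return ImpliedTimescaleScan(lags_ns=lag_ns, timescales=ts, defined=ok)


def select_markov_lag(scan: ImpliedTimescaleScan, tolerance: float = 0.1):
    """Smallest lag after which the slowest implied timescale has plateaued.

    A lag qualifies when every subsequent successive relative change of the
    slowest timescale is <= tolerance.  Returns the lag in ns, or None with
    a warning when no plateau exists within the scanned range.
    """
    if len(scan.lags_ns) < 3:
        raise ValueError("need at least 3 scanned lags")
    slow = scan.timescales[:, 0]
    if np.any(~scan.defined[:, 0]):
        warnings.warn("slowest timescale undefined at some lags; those lags "
                      "cannot start a plateau")
    rel = np.abs(np.diff(slow)) / np.abs(slow[:-1])
    for i in range(len(slow) - 1):
        window = rel[i:]
        if np.all(np.isfinite(window)) and np.all(window <= tolerance):
            return float(scan.lags_ns[i])
    warnings.warn("no implied-timescale plateau within the scanned lags")
    return None
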