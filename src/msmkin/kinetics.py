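"""Kinetics of a transition model: mean first passage times, relative free
energies, Arrhenius barrier heights, and transition-path-theory flux analysis.

MFPTs solve the boundary-value linear system

    x_i = tau + sum_j T_ij x_j   for i != target,   x_target = 0,

i.e. (I - T_sub) x = tau 1 on the non-target states, with results in ns.
Relative free energies follow FE_i = -ln(p_i / p_ref) (kT units).  Under
Arrhenius kinetics rate constants are proportional to exp(-barrier/kT), so
relative barrier heights follow from MFPT ratios: dG_ij = ln(MFPT_ij /
MFPT_min).  TPT supplies committors, net reactive fluxes and a top-pathway
decomposition by iterative bottleneck elimination.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .msm import TransitionModel

__all__ = [
    "MFPTMatrix",
    "FreeEnergyVector",
    "BarrierMatrix",
    "PathSet",
    "mfpt_to_state",
    "mfpt_matrix",
    "relative_free_energies",
    "relative_barriers",
    "committors",
    "net_flux_paths",
]


@dataclass(frozen=True)
class MFPTMatrix:
    """Pairwise mean first passage times in ns.

    mfpts[i, j] is the mean time to first reach j starting from i; the
    diagonal is zero.  Destination (column) and source (row) means are the
    off-diagonal averages reported alongside MFPT tables.
    """

    mfpts: np.ndarray

    @property
    def n_states(self) -> int:
        return self.mfpts.shape[0]

    @property
    def n_ordered_pairs(self) -> int:
        k = self.n_states
        return k * (k - 1)

    @property
    def destination_means(self) -> np.ndarray:
        """Mean MFPT into each ending state (column means, diagonal excluded)."""
        k = self.n_states
        return (self.mfpts.sum(axis=0)) / (k - 1)

    @property
    def source_means(self) -> np.ndarray:
        """Mean MFPT out of each starting state (row means, diagonal excluded)."""
        k = self.n_states
        return (self.mfpts.sum(axis=1)) / (k - 1)


@dataclass(frozen=True)
class FreeEnergyVector:
    """Free energies (kT) relative to a reference state; entries -ln(p_i/p_ref)."""

    values: np.ndarray
    ref: int


@dataclass(frozen=True)
class BarrierMatrix:
    """Relative barrier heights (kT) ln(MFPT_ij / MFPT_min); minimum entry 0."""

    values: np.ndarray

    @property
    def destination_means(self) -> np.ndarray:
        k = self.values.shape[0]
        off = self.values.copy()
        np.fill_diagonal(off, 0.0)
        return off.sum(axis=0) / (k - 1)

    @property
    def source_means(self) -> np.ndarray:
        k = self.values.shape[0]
        off = self.values.copy()
        np.fill_diagonal(off, 0.0)
        return off.sum(axis=1) / (k - 1)


@dataclass(frozen=True)
class PathSet:
    """TPT decomposition: committor, net flux matrix, and top pathways.

    paths : list of (state tuple, flux, fraction of total reactive flux)
    """

    qplus: np.ndarray
    net_flux: np.ndarray
    total_flux: float
    paths: list


def mfpt_to_state(model: TransitionModel, target: int) -> np.ndarray:
    """Mean first passage time from every state into `target`, in ns."""
    T = model.transition_matrix
    n = model.n_states
    if not (0 <= target < n):
        raise ValueError("target out of range")
    keep = np.array([i for i in range(n) if i != target])
    A = np.eye(n - 1) - T[np.ix_(keep, keep)]
    try:
        x = np.linalg.solve(A, np.full(n - 1, model.lag))
    except np.linalg.LinAlgError as exc:
        raise ValueError("MFPT system is singular (reducible chain?)") from exc
    if np.any(x <= 0):
        raise ValueError("MFPT solution non-positive; chain not irreducible "
                         "toward the target")
    out = np.zeros(n)
    out[keep] = x
    return out


def mfpt_matrix(model: TransitionModel) -> MFPTMatrix:
    """All-pairs MFPT matrix (rows = start state, columns = end state)."""
    n = model.n_states
    M = np.zeros((n, n))
    for j in range(n):
        M[:, j] = mfpt_to_state(model, j)
    return MFPTMatrix(mfpts=M)


def relative_free_energies(populations, ref: int) -> FreeEnergyVector:
    """FE_i = -ln(p_i / p_ref) in kT; the reference entry is zero."""
    p = np.asarray(populations, dtype=float)
    if np.any(p <= 0):
        raise ValueError("all populations must be positive")
    return FreeEnergyVector(values=-np.log(p / p[ref]), ref=int(ref))


def relative_barriers(mfpt: MFPTMatrix) -> BarrierMatrix:
    """Barrier heights above the lowest barrier: ln(MFPT_ij / MFPT_min), kT.

    MFPT_min runs over all off-diagonal entries; the matrix is invariant to
    a common rescaling of all MFPTs.
    """
    M = mfpt.mfpts
    off = ~np.eye(M.shape[0], dtype=bool)
    if np.any(M[off] <= 0) or not np.all(np.isfinite(M[off])):
        raise ValueError("all off-diagonal MFPTs must be finite and positive")
    vals = np.zeros_like(M)
    vals[off] = np.log(M[off] / M[off].min())
    return BarrierMatrix(values=vals)


def committors(model: TransitionModel, source, sink) -> np.ndarray:
    """Forward committor q+: probability of reaching sink before source.

    q+ = 0 on the source set, 1 on the sink set, and harmonic in between:
    q+_i = sum_j T_ij q+_j.
    """
    source = np.atleast_1d(np.asarray(source, dtype=int))
    sink = np.atleast_1d(np.asarray(sink, dtype=int))
    if len(source) == 0 or len(sink) == 0:
        raise ValueError("source and sink must be nonempty")
    if set(source.tolist()) & set(sink.tolist()):
        raise ValueError("source and sink must be disjoint")
    n = model.n_states
    T = model.transition_matrix
    q = np.zeros(n)
    q[sink] = 1.0
    inter = np.array([i for i in range(n)
                      if i not in set(source.tolist()) | set(sink.tolist())],
                     dtype=int)
    if len(inter):
        A = np.eye(len(inter)) - T[np.ix_(inter, inter)]
        b = T[np.ix_(inter, sink)].sum(axis=1)
        try:
            q[inter] = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise ValueError("committor system singular; intermediate states "
                             "disconnected from source/sink") from exc
    return np.clip(q, 0.0, 1.0)


def net_flux_paths(model: TransitionModel, qplus: np.ndarray,
                   top_k: int = 5, source=None, sink=None) -> PathSet:
    """Net reactive flux and top pathways between source and sink.

    Gross reactive flux f_ij = pi_i q-_i T_ij q+_j with q- = 1 - q+
    (reversible backward committor); net flux f+_ij = max(0, f_ij - f_ji).
    Pathways are extracted by iterative bottleneck decomposition: find the
    maximum-bottleneck source->sink path, subtract its bottleneck flux along
    the path, repeat up to top_k times.  Fractions are relative to the total
    reactive flux out of the source set.
    """
    q = np.asarray(qplus, dtype=float)
    pi = model.stationary
    T = model.transition_matrix
    n = model.n_states
    if source is None:
        source = np.flatnonzero(q == 0.0)
    if sink is None:
        sink = np.flatnonzero(q == 1.0)
    source = np.atleast_1d(np.asarray(source, dtype=int))
    sink = np.atleast_1d(np.asarray(sink, dtype=int))

    gross = (pi * (1.0 - q))[:, None] * T * q[None, :]
    np.fill_diagonal(gross, 0.0)
    net = np.maximum(0.0, gross - gross.T)
    total = float(net[source, :].sum())
    if total <= 0:
        return PathSet(qplus=q, net_flux=net, total_flux=0.0, paths=[])

    F = net.copy()
    paths = []
    src_set, snk_set = set(source.tolist()), set(sink.tolist())
    for _ in range(top_k):
        path, bottleneck = _widest_path(F, src_set, snk_set)
        if path is None or bottleneck <= 0:
            break
        for a, b in zip(path[:-1], path[1:]):
            F[a, b] -= bottleneck
        paths.append((tuple(path), float(bottleneck), float(bottleneck / total)))
    return PathSet(qplus=q, net_flux=net, total_flux=total, paths=paths)


def _widest_path(F: np.ndarray, sources: set, sinks: set):
    """Maximum-bottleneck path from any source to any sink (Dijkstra variant).

    Returns (path, bottleneck) or (None, 0) when no positive-capacity path
    exists.
    """
    n = F.shape[0]
    width = np.zeros(n)
    prev = np.full(n, -1)
    heap = []
    for s in sources:
        width[s] = np.inf
        heapq.heappush(heap, (-np.inf, s))
    done = np.zeros(n, dtype=bool)
    while heap:
        w, u = heapq.heappop(heap)
        w = -w
        if done[u]:
            continue
        done[u] = True
        if u in sinks:
            path = [u]
            while prev[path[-1]] != -1:
                path.append(int(prev[path[-1]]))
            return path[::-1], float(width[u])
        for v in np.flatnonzero(F[u] > 0):
            if done[v] or v in sources:
                continue
            cand = min(width[u], F[u, v])
            if cand > width[v]:
                width[v] = cand
                prev[v] = u
                heapq.heappush(heap, (-cand, v))
    return None, 0.0
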