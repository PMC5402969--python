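"""BACE coarse-graining of microstate models into macrostates.

The Bayesian agglomerative clustering engine merges, at every step, the pair
of states whose merge is least damaging under a multinomial likelihood model
of the observed transition counts.  The (log) Bayes factor for merging
states i and j is

    ln B_ij = C_i D(p_i || q) + C_j D(p_j || q)

where p_i is row i's normalized transition profile, C_i its total outgoing
counts, q the count-weighted average profile of the pair, and D the
Kullback-Leibler divergence.  A sharp rise of the minimal merge cost as the
model shrinks marks the natural number of macrostates (elbow selection).

The module also aggregates microstate models into macrostate models, samples
representative frames per macrostate, and classifies macrostates as
binding-competent from docking-score tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msm import CountMatrix, TransitionModel, estimate_tmatrix, _largest_scc

__all__ = [
    "BaceResult",
    "MacrostateModel",
    "ActivityLabels",
    "bace_merge",
    "select_macrostate_count",
    "lump",
    "sample_frames_per_state",
    "classify_binding_competence",
]


@dataclass(frozen=True)
class BaceResult:
    """Full BACE merge history.

    merges : list of (i, j) original-state-set pairs merged, in order
    merge_costs : dict size -> ln Bayes factor of the merge that produced
        that size (from size+1)
    maps : dict size -> array mapping each microstate to a macro index in
        0..size-1
    state_map : original microstate index per column of the count matrix used
    """

    merges: list
    merge_costs: dict
    maps: dict
    state_map: np.ndarray

    @property
    def sizes(self):
        return sorted(self.maps)


@dataclass(frozen=True)
class MacrostateModel:
    """Coarse-grained model: micro->macro map plus aggregated kinetics."""

    mapping: np.ndarray
    macro_counts: np.ndarray
    model: TransitionModel
    populations: np.ndarray

    @property
    def n_macrostates(self) -> int:
        return self.macro_counts.shape[0]


@dataclass(frozen=True)
class ActivityLabels:
    """Per-macrostate mean docking score and active/inactive label."""

    means: pd.Series
    labels: pd.Series
    cutoff: float
    active_population: float | None = None


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def _merge_cost(Ci, pi_row, Cj, pj_row) -> float:
    q = (Ci * pi_row + Cj * pj_row) / (Ci + Cj)
    return Ci * _kl(pi_row, q) + Cj * _kl(pj_row, q)


def bace_merge(counts: CountMatrix) -> BaceResult:
    """Agglomerate a count matrix down to one state, recording merge costs.

    Ties in the minimal cost are broken toward the lexicographically
    smallest (i, j) pair of current macro indices.
    """
    idx = _largest_scc(counts.counts)
    if len(idx) < counts.n_states:
        warnings.warn("count matrix not strongly connected; BACE restricted "
                      "to the largest connected component")
    C = counts.counts[np.ix_(idx, idx)].astype(float)
    n = len(C)
    if n < 2:
        raise ValueError("need at least 2 connected states")

    # active groups, each a sorted list of micro indices (within idx)
    groups = [[i] for i in range(n)]
    agg = C.copy()
    maps = {n: np.arange(n)}
    merges = []
    merge_costs = {}

    def cost_of(a, b):
        Ca, Cb = agg[a].sum(), agg[b].sum()
        return _merge_cost(Ca, agg[a] / Ca, Cb, agg[b] / Cb)

    size = n
    costs = np.full((n, n), np.inf)
    active = list(range(n))
    for a_i in range(n):
        for b_i in range(a_i + 1, n):
            costs[a_i, b_i] = cost_of(a_i, b_i)

    while size > 1:
        # lexicographically smallest among minima (row-major argmin)
        sub = costs[np.ix_(active, active)]
        flat = int(np.argmin(sub))
        ai, bi = divmod(flat, len(active))
        a, b = active[ai], active[bi]
        best = sub[ai, bi]
        merges.append((tuple(groups[a]), tuple(groups[b])))
        merge_costs[size - 1] = float(best)

        # merge b into a: sum rows and columns of the aggregated counts
        agg[a] += agg[b]
        agg[:, a] += agg[:, b]
        groups[a] = sorted(groups[a] + groups[b])
        active.remove(b)
        size -= 1

        # refresh costs involving a
        for c in active:
            if c == a:
                continue
            lo, hi = min(a, c), max(a, c)
            costs[lo, hi] = cost_of(lo, hi)

        mapping = np.empty(n, dtype=np.int64)
        for macro, g in enumerate(sorted(active)):
            mapping[groups[g]] = macro
        maps[size] = mapping

    return BaceResult(merges=merges, merge_costs=merge_costs, maps=maps,
                      state_map=idx)


def select_macrostate_count(result: BaceResult, jump_factor: float = 3.0) -> int:
    """Bayes-factor elbow: the size preceding the large cost increase.

    For each candidate size n the jump ratio cost(n-1)/cost(n) compares the
    damage of coarse-graining below n with the merge that produced n.  The
    selected size is the one at the most prominent jump (largest ratio, ties
    broken toward the smaller size), provided that jump reaches
    `jump_factor`; with sampled counts, mild spurious ratios occur all along
    the cost curve, so prominence — not the first qualifying ratio — marks
    the elbow.  Falls back to the smallest recorded size with a warning when
    no jump reaches the factor.
    """
    candidates = sorted(s for s in result.merge_costs if s - 1 in result.merge_costs)
    best, best_ratio = None, -np.inf
    for n in candidates:  # ascending; strict > keeps the smallest on ties
        c_n = result.merge_costs[n]       # cost of reaching size n
        c_prev = result.merge_costs[n - 1]  # cost of shrinking n -> n-1
        if c_n == 0:
            ratio = np.inf if c_prev > 0 else 1.0
        else:
            ratio = c_prev / c_n
        if ratio > best_ratio:
            best, best_ratio = n, ratio
    if best is None or best_ratio < jump_factor:
        smallest = min(result.merge_costs)
        warnings.warn("no Bayes-factor jump found; returning the smallest size")
        return smallest
    return best


def lump(model: TransitionModel, counts: CountMatrix, mapping) -> MacrostateModel:
    """Aggregate a microstate model into macrostates.

    Macro counts are sums of member micro counts (total counts conserved);
    the macro transition matrix is re-estimated from the aggregated counts
    by the same symmetrize-and-normalize scheme; macro populations are sums
    of member micro stationary weights.
    """
    mapping = np.asarray(mapping, dtype=np.int64)
    if len(mapping) != model.n_states:
        raise ValueError("mapping must cover every connected microstate")
    n_macro = int(mapping.max()) + 1
    if set(range(n_macro)) - set(mapping.tolist()):
        raise ValueError("mapping must be surjective onto 0..n_macro-1")

    C = counts.counts[np.ix_(model.state_map, model.state_map)]
    macro_counts = np.zeros((n_macro, n_macro))
    np.add.at(macro_counts, (mapping[:, None], mapping[None, :]), C)
    if n_macro == 1:
        macro_model = TransitionModel(transition_matrix=np.ones((1, 1)),
                                      lag=counts.lag,
                                      stationary=np.ones(1),
                                      state_map=np.zeros(1, dtype=np.int64))
    else:
        macro_model = estimate_tmatrix(
            CountMatrix(counts=macro_counts, lag_in_frames=counts.lag_in_frames,
                        frame_time=counts.frame_time))
    populations = np.zeros(n_macro)
    np.add.at(populations, mapping, model.stationary)
    return MacrostateModel(mapping=mapping, macro_counts=macro_counts,
                           model=macro_model, populations=populations)


def sample_frames_per_state(assignments, mapping, n: int, seed: int = 0,
                            state_map=None) -> dict:
    """Sample up to n frames per macrostate, uniformly without replacement.

    Frames are identified as (trajectory index, frame index).  `mapping`
    maps microstate -> macrostate; microstates outside `state_map` (trimmed
    during estimation) are skipped.  Macrostates holding fewer than n
    frames return their full membership with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mapping = np.asarray(mapping, dtype=np.int64)
    if state_map is None:
        state_map = np.arange(len(mapping))
    micro_to_macro = {int(s): int(mapping[i]) for i, s in enumerate(state_map)}

    frames_by_macro: dict[int, list] = {m: [] for m in np.unique(mapping)}
    for k, d in enumerate(assignments.dtrajs):
        for t, s in enumerate(d):
            m = micro_to_macro.get(int(s))
            if m is not None:
                frames_by_macro[m].append((k, t))

    out = {}
    for m, frames in frames_by_macro.items():
        if not frames:
            warnings.warn(f"macrostate {m} holds no frames")
            out[m] = []
        elif len(frames) <= n:
            if len(frames) < n:
                warnings.warn(f"macrostate {m} holds only {len(frames)} frames "
                              f"(< requested {n}); returning all")
            out[m] = list(frames)
        else:
            pick = rng.choice(len(frames), size=n, replace=False)
            out[m] = [frames[i] for i in sorted(pick)]
    return out


def classify_binding_competence(scores: pd.DataFrame, cutoff: float = -5.0,
                                populations=None) -> ActivityLabels:
    """Label each macrostate active/inactive by its mean docking score.

    A macrostate is binding-competent (active) when its mean score is at or
    below the cutoff (default -5.0 kcal/mol, boundary inclusive).  When a
    population vector indexed like the macrostate labels is supplied, the
    total active population is reported as well.
    """
    if len(scores) == 0:
        raise ValueError("empty docking-score table")
    if not np.all(np.isfinite(scores["score"])):
        raise ValueError("docking scores must be finite")
    means = scores.groupby("macrostate")["score"].mean()
    labels = pd.Series(np.where(means <= cutoff, "active", "inactive"),
                       index=means.index)
    active_pop = None
    if populations is not None:
        populations = pd.Series(populations)
        active_pop = float(populations.reindex(means.index[labels == "active"])
                           .fillna(0.0).sum())
    return ActivityLabels(means=means, labels=labels, cutoff=cutoff,
                          active_population=active_pop)
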