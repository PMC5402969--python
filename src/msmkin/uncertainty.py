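"""Monte-Carlo uncertainty for transition-matrix observables.

Transition matrices consistent with the observed counts are sampled by a
Metropolis random walk over row-stochastic matrices (the nonreversible
element shift move: pick a row and two entries, shift probability mass
between them) under the multinomial count likelihood.  Observables (MFPT
vectors, stationary populations) are recomputed on thinned samples and
summarized as percentile confidence intervals — by default the 80% level,
i.e. the (10th, 90th) percentile pair.  A generic bootstrap standard error
rounds out the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .msm import CountMatrix, TransitionModel, _largest_scc
from .kinetics import mfpt_to_state

__all__ = [
    "TMatrixSampleSet",
    "IntervalEstimate",
    "sample_tmatrices",
    "ci_mfpt",
    "ci_populations",
    "bootstrap_se",
]


@dataclass(frozen=True)
class TMatrixSampleSet:
    """Thinned Metropolis samples of row-stochastic transition matrices."""

    samples: list
    mle: np.ndarray
    acceptance_rate: float
    thin: int
    lag: float
    seed: int


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with a percentile confidence interval."""

    point: float
    lower: float
    upper: float
    level: float
    consistent: bool = True  # False when point falls outside [lower, upper]


def sample_tmatrices(counts: CountMatrix, n_steps: int = 1_000_000,
                     thin: int = 1000, proposal_width: float = 0.05,
                     seed: int = 0) -> TMatrixSampleSet:
    """Metropolis sampling of transition matrices given observed counts.

    Each step picks a row r and two distinct entries (j, k) and proposes
    T_rj += d, T_rk -= d with d ~ U(-w, w); proposals leaving [0, 1] are
    rejected outright, otherwise accepted with the multinomial likelihood
    ratio (T'_rj/T_rj)^C_rj (T'_rk/T_rk)^C_rk.  Every `thin` steps the
    current matrix is recorded.  Detailed balance is NOT imposed on the
    samples: the move is explicitly nonreversible-ensemble.

    Rows with zero total counts carry no likelihood and are held fixed.
    """
    if thin < 1 or n_steps < thin:
        raise ValueError("require n_steps >= thin >= 1")
    idx = _largest_scc(counts.counts)
    C = counts.counts[np.ix_(idx, idx)].astype(float)
    n = len(C)
    row_tot = C.sum(axis=1)
    active_rows = np.flatnonzero(row_tot > 0)
    if len(active_rows) < n:
        warnings.warn("rows with zero counts are held fixed during sampling")
    T = C / np.where(row_tot == 0, 1.0, row_tot)[:, None]
    T[row_tot == 0] = np.eye(n)[row_tot == 0]

    rng = np.random.default_rng(seed)
    n_samples = n_steps // thin
    samples = []
    accepted = 0
    block = 100_000
    done = 0
    mle = T.copy()
    while done < n_steps:
        todo = min(block, n_steps - done)
        rows = active_rows[rng.integers(len(active_rows), size=todo)]
        j_idx = rng.integers(n, size=todo)
        k_off = 1 + rng.integers(n - 1, size=todo)
        k_idx = (j_idx + k_off) % n
        deltas = rng.uniform(-proposal_width, proposal_width, size=todo)
        logu = np.log(rng.random(size=todo))
        for s in range(todo):
            r, j, k, d = rows[s], j_idx[s], k_idx[s], deltas[s]
            tj, tk = T[r, j], T[r, k]
            nj, nk = tj + d, tk - d
            if nj < 0.0 or nj > 1.0 or nk < 0.0 or nk > 1.0:
                pass
            else:
                log_ratio = 0.0
                ok = True
                if C[r, j] > 0:
                    if nj <= 0.0:
                        ok = False
                    else:
                        log_ratio += C[r, j] * np.log(nj / tj)
                if ok and C[r, k] > 0:
                    if nk <= 0.0:
                        ok = False
                    else:
                        log_ratio += C[r, k] * np.log(nk / tk)
                if ok and logu[s] <= log_ratio:
                    T[r, j], T[r, k] = nj, nk
                    accepted += 1
            done += 1
            if done % thin == 0:
                samples.append(T.copy())
    assert len(samples) == n_samples
    return TMatrixSampleSet(samples=samples, mle=mle,
                            acceptance_rate=accepted / n_steps,
                            thin=thin, lag=counts.lag, seed=seed)


def _percentile_interval(values: np.ndarray, point: float, level: float):
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(values, [alpha, 100.0 - alpha])
    consistent = bool(lo <= point <= hi)
    if not consistent:
        warnings.warn("point estimate outside the percentile interval "
                      "(skewed posterior); flagged, not hidden")
    return IntervalEstimate(point=float(point), lower=float(lo),
                            upper=float(hi), level=level,
                            consistent=consistent)


def _as_model(T: np.ndarray, lag: float) -> TransitionModel:
    # stationary unused by mfpt_to_state; supply uniform placeholder
    n = len(T)
    return TransitionModel(transition_matrix=T, lag=lag,
                           stationary=np.full(n, 1.0 / n),
                           state_map=np.arange(n))


def ci_mfpt(samples: TMatrixSampleSet, target: int, level: float = 0.80):
    """Percentile confidence intervals of MFPTs into `target` (per state).

    The MFPT vector is recomputed for every sampled matrix; samples whose
    linear system is singular (reducible draws) are skipped and counted.
    Returns (list of IntervalEstimate, n_skipped).
    """
    if not samples.samples:
        raise ValueError("no samples")
    vecs = []
    skipped = 0
    for T in samples.samples:
        try:
            vecs.append(mfpt_to_state(_as_model(T, samples.lag), target))
        except ValueError:
            skipped += 1
    if skipped > 0.5 * len(samples.samples):
        raise ValueError(f"{skipped}/{len(samples.samples)} samples reducible; "
                         "intervals unreliable")
    vecs = np.array(vecs)
    point = mfpt_to_state(_as_model(samples.mle, samples.lag), target)
    out = [_percentile_interval(vecs[:, i], point[i], level)
           for i in range(vecs.shape[1])]
    return out, skipped


def _stationary_general(T: np.ndarray) -> np.ndarray:
    """Stationary vector of a (possibly nonreversible) stochastic matrix."""
    vals, vecs = scipy.linalg.eig(T.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.abs(np.real(vecs[:, k]))
    return pi / pi.sum()


def ci_populations(samples: TMatrixSampleSet, level: float = 0.80):
    """Percentile confidence intervals of stationary populations per state."""
    if not samples.samples:
        raise ValueError("no samples")
    pis = np.array([_stationary_general(T) for T in samples.samples])
    point = _stationary_general(samples.mle)
    return [_percentile_interval(pis[:, i], point[i], level)
            for i in range(pis.shape[1])]


_STATISTICS = {
    "mean": np.mean,
    "median": np.median,
    "std": np.std,
}


def bootstrap_se(values, statistic="mean", n_rounds: int = 10_000,
                 seed: int = 0) -> float:
    """Bootstrap standard error of a statistic (resampling with replacement)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    if n_rounds < 100:
        raise ValueError("n_rounds must be >= 100")
    stat = _STATISTICS.get(statistic, statistic)
    if not callable(stat):
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(len(values), size=(n_rounds, len(values)))
    reps = stat(values[idx], axis=1)
    return float(np.std(reps))
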