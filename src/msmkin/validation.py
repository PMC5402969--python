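"""Chapman-Kolmogorov validation of an estimated Markov state model.

For each tested state A and each multiple k, the model prediction
pMSM(A, A; k*tau) = [T(tau)^k]_AA is compared with pMD(A, A; k*tau), the AA
element of a transition matrix re-estimated directly from the trajectories
at lag k*tau.  The statistical uncertainty of pMD is the binomial standard
error sqrt(pMD (1 - pMD) / N_A), with N_A the number of transition counts
originating in A at lag k*tau; a cell passes when |pMSM - pMD| <= 2 sigma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msm import DiscreteTrajectorySet, TransitionModel, count_transitions, \
    estimate_tmatrix

__all__ = ["CKTestResult", "ck_test"]


@dataclass(frozen=True)
class CKTestResult:
    """Per-state, per-multiple Chapman-Kolmogorov comparison.

    Arrays are indexed [state, k]; `testable` is False where the state had
    no counts (or dropped out of the connected set) at that lag.
    """

    states: np.ndarray
    k_values: np.ndarray
    p_msm: np.ndarray
    p_md: np.ndarray
    sigma: np.ndarray
    passed: np.ndarray
    testable: np.ndarray

    @property
    def fraction_passed(self) -> float:
        """Fraction of testable cells passing at 2 sigma."""
        t = self.testable
        return float(self.passed[t].mean()) if t.any() else float("nan")


def ck_test(dtrajs: DiscreteTrajectorySet, model: TransitionModel,
            k_values=(1, 2, 3), states=None) -> CKTestResult:
    """Chapman-Kolmogorov test of `model` against the trajectory data.

    `states` are model-state indices (defaults to all); `k_values` are the
    lag multiples, following the convention of stopping at k = 3 when
    trajectories are only a few lag times long.
    """
    k_values = np.asarray(sorted(int(k) for k in k_values), dtype=int)
    if np.any(k_values < 1):
        raise ValueError("k_values must be >= 1")
    lag_frames = int(round(model.lag / dtrajs.frame_time))
    if lag_frames < 1:
        raise ValueError("model lag shorter than one frame")
    if states is None:
        states = np.arange(model.n_states)
    states = np.asarray(states, dtype=int)

    n_s, n_k = len(states), len(k_values)
    p_msm = np.full((n_s, n_k), np.nan)
    p_md = np.full((n_s, n_k), np.nan)
    sigma = np.full((n_s, n_k), np.nan)
    passed = np.zeros((n_s, n_k), dtype=bool)
    testable = np.zeros((n_s, n_k), dtype=bool)

    T = model.transition_matrix
    Tk = np.eye(model.n_states)
    k_prev = 0
    for kc, k in enumerate(k_values):
        Tk = Tk @ np.linalg.matrix_power(T, k - k_prev)
        k_prev = k
        try:
            counts_k = count_transitions(dtrajs, k * lag_frames)
            model_k = estimate_tmatrix(counts_k)
        except ValueError:
            continue  # lag too long: column stays untestable
        # map original state labels -> re-estimated model indices
        back = {orig: i for i, orig in enumerate(model_k.state_map)}
        raw_rows = counts_k.counts.sum(axis=1)
        for sc, s in enumerate(states):
            orig = int(model.state_map[s])
            i = back.get(orig)
            if i is None or raw_rows[orig] == 0:
                continue
            pmd = float(model_k.transition_matrix[i, i])
            n_a = float(raw_rows[orig])
            sig = np.sqrt(max(pmd * (1.0 - pmd), 0.0) / n_a)
            pmsm = float(Tk[s, s])
            p_msm[sc, kc] = pmsm
            p_md[sc, kc] = pmd
            sigma[sc, kc] = sig
            passed[sc, kc] = abs(pmsm - pmd) <= 2.0 * sig
            testable[sc, kc] = True
    return CKTestResult(states=states, k_values=k_values, p_msm=p_msm,
                        p_md=p_md, sigma=sigma, passed=passed,
                        testable=testable)
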