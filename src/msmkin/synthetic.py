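"""Synthetic ground-truth kinetic networks, trajectories and auxiliary data.

Everything downstream of this module (clustering, MSM estimation, coarse
graining, kinetics, uncertainty, rate recovery) is exercised against data
generated here, where the true transition matrix, stationary distribution,
bias schedule and docking-score distributions are known exactly.

All generators are pure functions of their parameters and an integer seed:
identical inputs yield byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msm import DiscreteTrajectorySet
from .clustering import FeatureTrajectorySet
from .rates import BiasTrace

__all__ = [
    "GroundTruthChain",
    "EmissionSpec",
    "BiasSchedule",
    "TemperatureLadder",
    "make_metastable_chain",
    "sample_discrete_trajectories",
    "emit_features",
    "make_bias_trace",
    "make_docking_scores",
    "remd_ladder",
]


@dataclass(frozen=True)
class GroundTruthChain:
    """A discrete-time Markov chain with known stationary distribution.

    The chain is constructed reversibly (detailed balance holds exactly),
    so every downstream quantity — implied timescales, mean first passage
    times, committors — is analytically checkable.

    Attributes
    ----------
    transition_matrix : (n, n) row-stochastic per-step probabilities.
    stationary : (n,) stationary distribution (exact left eigenvector).
    macro_of_micro : (n,) ground-truth block (macrostate) label per state.
    frame_time : time per step in ns.
    """

    transition_matrix: np.ndarray
    stationary: np.ndarray
    macro_of_micro: np.ndarray
    frame_time: float
    seed: int

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]


@dataclass(frozen=True)
class EmissionSpec:
    """Isotropic Gaussian feature emission per state.

    means : (n_states, n_features); sds : (n_states,) with sd >= 0.
    """

    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self):
        means = np.atleast_2d(np.asarray(self.means, dtype=float))
        sds = np.asarray(self.sds, dtype=float)
        if means.shape[0] != sds.shape[0]:
            raise ValueError("one mean/sd pair required per state")
        if np.any(sds < 0):
            raise ValueError("standard deviations must be >= 0")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


@dataclass(frozen=True)
class BiasSchedule:
    """Deterministic deposited-bias schedule V(t) for rate recovery tests.

    kind:
      * ``zero``                — no bias, V = 0.
      * ``constant``            — V = level everywhere.
      * ``ramp``                — V grows linearly at `rate` per ns.
      * ``gaussian-deposition`` — well-tempered-like accumulation: at every
        deposition interval the increment is ``height * exp(-V/((gamma-1) kBT))``,
        emulating the tempered decay of hill heights.  Defaults mirror a
        typical well-tempered metadynamics setup (2.5 kJ/mol starting hills
        deposited every 5 ps with bias factor 10).

    Energies in kJ/mol, times in ns.
    """

    kind: str = "zero"
    duration: float = 1.0
    kBT: float = 2.479
    dt: float = 0.005
    level: float = 0.0
    rate: float = 0.0
    height: float = 2.5
    deposition_interval: float = 0.005
    bias_factor: float = 10.0

    def __post_init__(self):
        if self.kind not in {"zero", "constant", "ramp", "gaussian-deposition"}:
            raise ValueError(f"unknown bias schedule kind: {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.kBT <= 0:
            raise ValueError("kBT must be positive")


@dataclass(frozen=True)
class TemperatureLadder:
    """Geometric replica-exchange temperature ladder."""

    temperatures: np.ndarray
    n_replicas: int

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        if len(t) != self.n_replicas:
            raise ValueError("ladder length must equal n_replicas")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        object.__setattr__(self, "temperatures", t)

    @property
    def mean_spacing(self) -> float:
        """Arithmetic mean spacing (t_max - t_min)/(n - 1) in K."""
        t = self.temperatures
        return float((t[-1] - t[0]) / (self.n_replicas - 1))


def make_metastable_chain(
    n_macro: int,
    populations,
    intra_block_sizes=None,
    mixing: float = 0.05,
    frame_time: float = 0.1,
    seed: int = 0,
) -> GroundTruthChain:
    """Build a reversible metastable chain with prescribed block populations.

    States are grouped into ``n_macro`` blocks; block b holds
    ``intra_block_sizes[b]`` microstates (default 1 each) sharing the block
    population uniformly.  The transition matrix is the mixture

        T = (1 - mixing) * U_block + mixing * 1 pi^T,

    where U_block jumps to a uniformly chosen member of the current block
    and 1 pi^T jumps to the global stationary law.  Both components are
    reversible with respect to pi, so detailed balance holds exactly and pi
    is the exact stationary vector.  Same-block microstates have identical
    rows (they are exchangeable), which is what makes the block structure
    recoverable by coarse-graining; the non-unit spectrum is analytic:
    eigenvalue (1 - mixing) with multiplicity n_macro - 1 (inter-block
    relaxation) and 0 for all within-block modes.

    Smaller ``mixing`` means rarer inter-block transitions, i.e. stronger
    metastability and a slower leading implied timescale; mixing -> 1
    collapses the slow timescales onto the fast within-block scale.
    """
    populations = np.asarray(populations, dtype=float)
    if len(populations) != n_macro:
        raise ValueError("need one population per macrostate")
    if np.any(populations <= 0):
        raise ValueError("all populations must be positive")
    if not np.isclose(populations.sum(), 1.0, atol=1e-8):
        raise ValueError("populations must sum to 1")
    if not (0 < mixing <= 1):
        raise ValueError("mixing must lie in (0, 1]")
    if intra_block_sizes is None:
        intra_block_sizes = [1] * n_macro
    intra_block_sizes = [int(s) for s in intra_block_sizes]
    if len(intra_block_sizes) != n_macro or any(s < 1 for s in intra_block_sizes):
        raise ValueError("intra_block_sizes must list a positive size per block")

    n = sum(intra_block_sizes)
    macro = np.concatenate(
        [np.full(s, b, dtype=int) for b, s in enumerate(intra_block_sizes)]
    )
    pi = np.empty(n)
    block_size = np.empty(n)
    for b, s in enumerate(intra_block_sizes):
        pi[macro == b] = populations[b] / s
        block_size[macro == b] = s

    same_block = macro[:, None] == macro[None, :]
    u_block = np.where(same_block, 1.0 / block_size[:, None], 0.0)
    T = (1.0 - mixing) * u_block + mixing * pi[None, :].repeat(n, axis=0)
    return GroundTruthChain(
        transition_matrix=T,
        stationary=pi,
        macro_of_micro=macro,
        frame_time=float(frame_time),
        seed=int(seed),
    )


def sample_discrete_trajectories(
    chain: GroundTruthChain, n_traj: int, n_steps: int, seed: int = 0
) -> DiscreteTrajectorySet:
    """Sample independent realizations of the chain from its stationary law.

    All trajectories are advanced in lockstep (vectorized over trajectories),
    so sampling 30 x 1e5 frames takes about a second.
    """
    if n_traj < 1 or n_steps < 1:
        raise ValueError("n_traj and n_steps must be >= 1")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2 for a usable trajectory")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(chain.transition_matrix, axis=1)
    cum[:, -1] = 1.0
    out = np.empty((n_traj, n_steps), dtype=np.int64)
    state = np.searchsorted(np.cumsum(chain.stationary), rng.random(n_traj))
    out[:, 0] = state
    u = rng.random((n_steps - 1, n_traj))
    for t in range(1, n_steps):
        state = (cum[state] < u[t - 1, :, None]).sum(axis=1)
        out[:, t] = state
    return DiscreteTrajectorySet(
        dtrajs=[out[k] for k in range(n_traj)],
        frame_time=chain.frame_time,
        n_states=chain.n_states,
    )


def emit_features(
    dtrajs: DiscreteTrajectorySet, spec: EmissionSpec, seed: int = 0
) -> FeatureTrajectorySet:
    """Emit per-frame Gaussian features conditioned on the hidden state."""
    max_state = max(int(d.max()) for d in dtrajs.dtrajs)
    if max_state >= spec.n_states:
        raise ValueError(
            f"emission spec covers {spec.n_states} states but trajectories "
            f"contain state {max_state}"
        )
    rng = np.random.default_rng(seed)
    trajs = []
    for d in dtrajs.dtrajs:
        noise = rng.standard_normal((len(d), spec.n_features))
        trajs.append(spec.means[d] + spec.sds[d][:, None] * noise)
    ids = [f"traj_{k:03d}" for k in range(len(trajs))]
    return FeatureTrajectorySet(trajs=trajs, frame_time=dtrajs.frame_time, ids=ids)


def make_bias_trace(schedule: BiasSchedule, seed: int = 0) -> BiasTrace:
    """Realize a bias schedule as a (time, bias) trace.

    The trace is deterministic given the schedule; the seed is accepted for
    interface uniformity with the other generators.
    """
    dt = schedule.dt
    times = np.arange(dt, schedule.duration + 0.5 * dt, dt)
    if schedule.kind == "zero":
        bias = np.zeros_like(times)
    elif schedule.kind == "constant":
        bias = np.full_like(times, schedule.level)
    elif schedule.kind == "ramp":
        bias = schedule.rate * times
    else:  # gaussian-deposition
        n_dep = np.floor(times / schedule.deposition_interval).astype(int)
        bias = np.empty_like(times)
        v = 0.0
        damp = (schedule.bias_factor - 1.0) * schedule.kBT
        deposited = 0
        for i, nd in enumerate(n_dep):
            while deposited < nd:
                v += schedule.height * np.exp(-v / damp)
                deposited += 1
            bias[i] = v
    return BiasTrace(times=times, bias=bias, kBT=schedule.kBT)


def make_docking_scores(
    macro_labels, means, sd: float, n_per_state: int, seed: int = 0
):
    """Gaussian docking-score table: n_per_state scores per macrostate label.

    Emulates docking a ligand into conformers sampled from each macrostate;
    per-state means are placed around the activity cutoff so classification
    is testable.  Returns a DataFrame with columns ``macrostate, score``
    (kcal/mol).
    """
    import pandas as pd

    if n_per_state < 1:
        raise ValueError("n_per_state must be >= 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    means = np.asarray(means, dtype=float)
    if len(means) != len(macro_labels):
        raise ValueError("one mean required per macrostate label")
    rng = np.random.default_rng(seed)
    frames = []
    for label, mu in zip(macro_labels, means):
        scores = mu + sd * rng.standard_normal(n_per_state)
        frames.append(pd.DataFrame({"macrostate": label, "score": scores}))
    return pd.concat(frames, ignore_index=True)


def remd_ladder(t_min: float, t_max: float, n: int) -> TemperatureLadder:
    """Exponentially (geometrically) spaced replica temperatures.

    T_i = t_min * (t_max/t_min)^(i/(n-1)), the standard spacing giving
    roughly uniform exchange acceptance across the ladder.
    """
    if n < 2:
        raise ValueError("need at least two replicas")
    if not (t_max > t_min > 0):
        raise ValueError("require t_max > t_min > 0")
    i = np.arange(n)
    temps = t_min * (t_max / t_min) ** (i / (n - 1))
    temps[0], temps[-1] = t_min, t_max
    return TemperatureLadder(temperatures=temps, n_replicas=n)
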