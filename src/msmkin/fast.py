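"""FAST goal-oriented adaptive-sampling allocation.

Each candidate restart state i gets a reward

    rf(i) = fbar(i) + a * ybar(i)

combining a directed term fbar — the min-max normalized structural objective
f (favoring states that optimize f) — with an undirected term ybar =
(C_max - C_i)/(C_max - C_min) favoring undersampled states.  a = 1 weights
the two equally.  The next batch of simulations is split proportionally to
rf with largest-remainder (Hamilton) rounding so counts sum exactly to the
batch size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["RewardTable", "Allocation", "fast_reward", "allocate"]


@dataclass(frozen=True)
class RewardTable:
    """Per-state FAST reward decomposition: rf = fbar + a * ybar."""

    f: np.ndarray
    fbar: np.ndarray
    ybar: np.ndarray
    rf: np.ndarray
    counts: np.ndarray
    a: float
    direction: str


@dataclass(frozen=True)
class Allocation:
    """Integer simulation counts per state for the next batch."""

    counts: np.ndarray
    batch_size: int


def fast_reward(f_values, counts, a: float = 1.0,
                direction: str = "maximize") -> RewardTable:
    """Compute FAST rewards from a structural objective and visit counts.

    direction="maximize": fbar = (f - f_min)/(f_max - f_min);
    direction="minimize": fbar = (f_max - f)/(f_max - f_min).
    Degenerate spreads (f_max == f_min, or C_max == C_min) zero the
    corresponding term: an uninformative term expresses no preference.
    """
    f = np.asarray(f_values, dtype=float)
    c = np.asarray(counts, dtype=float)
    if len(f) < 2:
        raise ValueError("need at least 2 states")
    if len(f) != len(c):
        raise ValueError("f_values and counts must have equal length")
    if direction not in ("maximize", "minimize"):
        raise ValueError("direction must be 'maximize' or 'minimize'")

    span = f.max() - f.min()
    if span == 0:
        fbar = np.zeros_like(f)
    elif direction == "maximize":
        fbar = (f - f.min()) / span
    else:
        fbar = (f.max() - f) / span

    cspan = c.max() - c.min()
    if cspan == 0:
        ybar = np.zeros_like(c)
    else:
        ybar = (c.max() - c) / cspan

    return RewardTable(f=f, fbar=fbar, ybar=ybar, rf=fbar + a * ybar,
                       counts=c, a=float(a), direction=direction)


def allocate(rewards: RewardTable, batch_size: int) -> Allocation:
    """Split a batch proportionally to rewards (largest-remainder rounding).

    Ideal shares batch * rf_i / sum(rf) are floored; leftover simulations go
    to the largest fractional remainders (ties to the lower state index).
    All-zero rewards fall back to a uniform split with a warning.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    rf = rewards.rf
    if np.any(rf < 0):
        raise ValueError("rewards must be nonnegative")
    if rf.sum() == 0:
        warnings.warn("all rewards zero; allocating uniformly")
        rf = np.ones_like(rf)
    ideal = batch_size * rf / rf.sum()
    counts = np.floor(ideal).astype(int)
    remainder = ideal - counts
    short = batch_size - counts.sum()
    if short > 0:
        # stable sort descending by remainder -> ties break to lower index
        order = np.argsort(-remainder, kind="stable")
        counts[order[:short]] += 1
    return Allocation(counts=counts, batch_size=int(batch_size))
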