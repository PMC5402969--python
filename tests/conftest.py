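import numpy as np
import pytest

import msmkin
from msmkin.msm import DiscreteTrajectorySet, TransitionModel

# dominant pair of populations as reported for the landscape; the six minor
# states are fixture values chosen inside the reported 0.5-6.0% band
LANDSCAPE_POPULATIONS = (0.439, 0.389, 0.060, 0.042, 0.031, 0.022, 0.012, 0.005)


@pytest.fixture(scope="session")
def chain8():
    """8-macrostate ground-truth chain, 3 microstates per block."""
    return msmkin.make_metastable_chain(
        8, LANDSCAPE_POPULATIONS, intra_block_sizes=[3] * 8, mixing=0.05,
        frame_time=0.1, seed=3)


@pytest.fixture(scope="session")
def dtrajs8(chain8):
    """30 trajectories x 20k frames from the 8-block chain."""
    return msmkin.sample_discrete_trajectories(chain8, 30, 20_000, seed=11)


@pytest.fixture
def two_state_model():
    """Closed-form two-state chain: T = [[0.9, 0.1], [0.2, 0.8]], lag 1 ns."""
    T = np.array([[0.9, 0.1], [0.2, 0.8]])
    return TransitionModel(transition_matrix=T, lag=1.0,
                           stationary=np.array([2 / 3, 1 / 3]),
                           state_map=np.arange(2))


def make_model(T, lag=1.0):
    """Wrap a row-stochastic matrix as a TransitionModel with its exact pi."""
    T = np.asarray(T, dtype=float)
    pi = msmkin.stationary_distribution(T)
    return TransitionModel(transition_matrix=T, lag=lag, stationary=pi,
                           state_map=np.arange(len(T)))


def dtraj_set(*seqs, frame_time=1.0, n_states=None):
    seqs = [np.asarray(s, dtype=np.int64) for s in seqs]
    if n_states is None:
        n_states = int(max(s.max() for s in seqs)) + 1
    return DiscreteTrajectorySet(dtrajs=list(seqs), frame_time=frame_time,
                                 n_states=n_states)
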