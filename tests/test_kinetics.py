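"""MFPTs, free energies, barriers, committors, and flux pathways."""

import numpy as np
import pytest

from msmkin.kinetics import (committors, mfpt_matrix, mfpt_to_state,
                             net_flux_paths, relative_barriers,
                             relative_free_energies, MFPTMatrix)
from conftest import make_model


def simulate_hitting_times(T, start, target, n_passages, seed, max_steps=10_000):
    """Monte-Carlo mean hitting time oracle (vectorized over walkers)."""
    rng = np.random.default_rng(seed)
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0
    state = np.full(n_passages, start)
    steps = np.zeros(n_passages)
    alive = state != target
    for _ in range(max_steps):
        idx = np.flatnonzero(alive)
        if not len(idx):
            break
        u = rng.random(len(idx))
        state[idx] = (cum[state[idx]] < u[:, None]).sum(axis=1)
        steps[idx] += 1
        alive[idx] = state[idx] != target
    assert not alive.any(), "oracle did not absorb all walkers"
    return steps.mean()


class TestMfpt:
    def test_two_state_geometric_waiting_times(self, two_state_model):
        # leaving state 0 happens w.p. 0.1 per ns -> MFPT(0 -> 1) = 10 ns
        m = mfpt_matrix(two_state_model)
        assert m.mfpts[0, 1] == pytest.approx(10.0)
        assert m.mfpts[1, 0] == pytest.approx(5.0)
        assert m.mfpts[0, 0] == 0.0

    def test_absorbing_target_unreachable_rejected(self):
        T = np.array([[1.0, 0.0], [0.5, 0.5]])
        from msmkin.msm import TransitionModel
        model = TransitionModel(transition_matrix=T, lag=1.0,
                                stationary=np.array([1.0, 0.0]),
                                state_map=np.arange(2))
        with pytest.raises(ValueError):
            mfpt_to_state(model, 1)

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(12)
        T = rng.dirichlet(np.ones(4) * 2.0, size=4)
        model = make_model(T)
        x = mfpt_to_state(model, 0)
        mc = simulate_hitting_times(T, start=2, target=0, n_passages=200_000,
                                    seed=1)
        assert x[2] == pytest.approx(mc, rel=0.02)

    def test_fundamental_matrix_closed_form(self):
        # (I - T_sub)^-1 t 1 equals the linear-system solution to 1e-8
        rng = np.random.default_rng(5)
        for n in (3, 5):
            T = rng.dirichlet(np.ones(n), size=n)
            model = make_model(T, lag=2.0)
            for target in range(n):
                keep = [i for i in range(n) if i != target]
                closed = np.linalg.inv(np.eye(n - 1) - T[np.ix_(keep, keep)]) \
                    @ (2.0 * np.ones(n - 1))
                got = mfpt_to_state(model, target)[keep]
                np.testing.assert_allclose(got, closed, atol=1e-8)

    def test_mfpt_scales_with_lag(self):
        T = np.random.default_rng(3).dirichlet(np.ones(4), size=4)
        m1 = mfpt_matrix(make_model(T, lag=1.0)).mfpts
        m5 = mfpt_matrix(make_model(T, lag=5.0)).mfpts
        np.testing.assert_allclose(m5, 5.0 * m1, atol=1e-9)

    def test_eight_states_give_56_ordered_pairs(self, chain8):
        model = make_model(chain8.transition_matrix[:8, :8] /
                           chain8.transition_matrix[:8, :8].sum(1)[:, None])
        assert mfpt_matrix(model).n_ordered_pairs == 56

    def test_symmetric_chain_symmetric_mfpts(self):
        T = np.array([[0.8, 0.2], [0.2, 0.8]])
        m = mfpt_matrix(make_model(T)).mfpts
        assert m[0, 1] == pytest.approx(m[1, 0])


class TestFreeEnergies:
    def test_reference_zero_and_arithmetic(self):
        fe = relative_free_energies([0.5, 0.25, 0.25], ref=0)
        np.testing.assert_allclose(fe.values, [0.0, np.log(2), np.log(2)])

    def test_permutation_equivariance(self):
        p = np.array([0.4, 0.3, 0.2, 0.1])
        perm = np.array([2, 0, 3, 1])
        fe = relative_free_energies(p, ref=0).values
        fe_perm = relative_free_energies(p[perm],
                                         ref=int(np.argmax(perm == 0))).values
        np.testing.assert_allclose(fe_perm, fe[perm])

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            relative_free_energies([0.5, 0.0, 0.5], ref=0)


class TestBarriers:
    def test_minimum_entry_zero_and_log_ratio(self):
        # slowest/fastest = 4430/50 ns: barrier ln(88.6) = 4.48 kT (~4.5)
        M = np.array([[0.0, 4430.0], [50.0, 0.0]])
        b = relative_barriers(MFPTMatrix(mfpts=M))
        assert b.values[1, 0] == 0.0
        assert b.values[0, 1] == pytest.approx(np.log(4430 / 50))
        assert round(b.values[0, 1], 1) == 4.5

    def test_e_fold_entry_is_one_kt(self):
        M = np.array([[0.0, 50.0 * np.e], [50.0, 0.0]])
        b = relative_barriers(MFPTMatrix(mfpts=M))
        assert b.values[0, 1] == pytest.approx(1.0)

    def test_invariant_to_common_rescaling(self):
        rng = np.random.default_rng(0)
        M = rng.uniform(10, 1000, size=(4, 4))
        np.fill_diagonal(M, 0.0)
        b1 = relative_barriers(MFPTMatrix(mfpts=M)).values
        b2 = relative_barriers(MFPTMatrix(mfpts=7.3 * M)).values
        np.testing.assert_allclose(b1, b2, atol=1e-12)


class TestCommittors:
    def test_two_states_trivial(self):
        q = committors(make_model([[0.5, 0.5], [0.5, 0.5]]), [0], [1])
        np.testing.assert_allclose(q, [0.0, 1.0])

    def test_symmetric_linear_chain_middle_half(self):
        T = np.array([[0.8, 0.2, 0.0],
                      [0.2, 0.6, 0.2],
                      [0.0, 0.2, 0.8]])
        q = committors(make_model(T), [0], [2])
        assert q[1] == pytest.approx(0.5)

    def test_single_equation_hand_solution(self):
        # from state 1: to source w.p. 0.3, to sink w.p. 0.1
        # q(1) = 0.1 / (0.1 + 0.3) = 0.25
        T = np.array([[0.9, 0.1, 0.0],
                      [0.3, 0.6, 0.1],
                      [0.0, 0.1, 0.9]])
        q = committors(make_model(T), [0], [2])
        assert q[1] == pytest.approx(0.25)

    def test_source_sink_overlap_rejected(self, two_state_model):
        with pytest.raises(ValueError):
            committors(two_state_model, [0], [0])


class TestNetFluxPaths:
    def test_linear_chain_single_path(self):
        T = np.array([[0.8, 0.2, 0.0],
                      [0.2, 0.6, 0.2],
                      [0.0, 0.2, 0.8]])
        model = make_model(T)
        q = committors(model, [0], [2])
        ps = net_flux_paths(model, q, top_k=5, source=[0], sink=[2])
        assert len(ps.paths) == 1
        assert ps.paths[0][0] == (0, 1, 2)
        assert ps.paths[0][2] == pytest.approx(1.0)

    def test_flux_conservation_identity(self, chain8):
        model = make_model(chain8.transition_matrix)
        src, snk = [0], [chain8.n_states - 1]
        q = committors(model, src, snk)
        ps = net_flux_paths(model, q, top_k=3, source=src, sink=snk)
        expected = float(np.sum(model.stationary[src][:, None] *
                                model.transition_matrix[src, :] * q[None, :]))
        assert ps.total_flux == pytest.approx(expected, abs=1e-10)

    def test_parallel_channels_ordered_by_flux(self):
        # 0 -> {1, 2} -> 3, symmetric (hence reversible, uniform pi) with
        # channel via state 1 carrying 3x the rate of the channel via 2;
        # both committors are 1/2, so analytic net fluxes are
        # pi * k * 1/2 per channel: fractions 0.75 and 0.25
        T = np.array([
            [0.6, 0.3, 0.1, 0.0],
            [0.3, 0.4, 0.0, 0.3],
            [0.1, 0.0, 0.8, 0.1],
            [0.0, 0.3, 0.1, 0.6]])
        model = make_model(T)
        q = committors(model, [0], [3])
        np.testing.assert_allclose(q, [0.0, 0.5, 0.5, 1.0], atol=1e-12)
        ps = net_flux_paths(model, q, top_k=5, source=[0], sink=[3])
        assert len(ps.paths) == 2
        assert ps.paths[0][0] == (0, 1, 3)
        assert ps.paths[1][0] == (0, 2, 3)
        fractions = [p[2] for p in ps.paths]
        assert sum(fractions) == pytest.approx(1.0)
        np.testing.assert_allclose(fractions, [0.75, 0.25], atol=1e-10)

    def test_top_k_one(self, chain8):
        model = make_model(chain8.transition_matrix)
        q = committors(model, [0], [5])
        ps = net_flux_paths(model, q, top_k=1, source=[0], sink=[5])
        assert len(ps.paths) == 1
        assert 0 < ps.paths[0][2] <= 1.0
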