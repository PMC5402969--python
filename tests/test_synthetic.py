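"""Ground-truth generators: exact stationary laws, determinism, known outputs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import msmkin
from msmkin.synthetic import BiasSchedule, EmissionSpec


class TestMetastableChain:
    def test_two_block_symmetric(self):
        chain = msmkin.make_metastable_chain(2, [0.5, 0.5], mixing=0.1)
        np.testing.assert_allclose(chain.stationary, [0.5, 0.5])
        T = chain.transition_matrix
        np.testing.assert_allclose(T, T.T, atol=1e-15)

    def test_stationary_is_left_eigenvector(self, chain8):
        pi, T = chain8.stationary, chain8.transition_matrix
        np.testing.assert_allclose(pi @ T, pi, atol=1e-10)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(T >= 0)
        np.testing.assert_allclose(pi.sum(), 1.0, atol=1e-12)

    def test_detailed_balance(self, chain8):
        pi, T = chain8.stationary, chain8.transition_matrix
        flux = pi[:, None] * T
        np.testing.assert_allclose(flux, flux.T, atol=1e-15)

    def test_requested_populations_recovered_8_state(self):
        pops = [0.439, 0.389, 0.060, 0.042, 0.031, 0.022, 0.012, 0.005]
        chain = msmkin.make_metastable_chain(8, pops, mixing=0.05)
        # independent eigen-decomposition check
        vals, vecs = np.linalg.eig(chain.transition_matrix.T)
        k = np.argmin(np.abs(vals - 1))
        pi = np.abs(np.real(vecs[:, k]))
        pi /= pi.sum()
        np.testing.assert_allclose(pi, pops, atol=1e-10)

    def test_high_mixing_collapses_slow_timescale(self):
        # mixing -> 1: second eigenvalue (1 - mixing) -> 0, so the slowest
        # implied timescale approaches the fast within-block scale
        for mixing, bound in [(0.999, 0.2), (0.5, 1.6)]:
            chain = msmkin.make_metastable_chain(
                4, [0.25] * 4, intra_block_sizes=[2] * 4, mixing=mixing)
            ev = np.sort(np.abs(np.linalg.eigvals(chain.transition_matrix)))[::-1]
            ts = -1.0 / np.log(ev[1])
            assert ts < bound

    @pytest.mark.parametrize("pops", [[0.5, 0.6], [0.5, -0.5, 1.0], [1.0, 0.0]])
    def test_invalid_populations_rejected(self, pops):
        with pytest.raises(ValueError):
            msmkin.make_metastable_chain(len(pops), pops)


class TestSampling:
    def test_identity_chain_is_constant(self):
        chain = msmkin.make_metastable_chain(3, [0.3, 0.3, 0.4], mixing=1e-12)
        # force exact identity
        object.__setattr__(chain, "transition_matrix", np.eye(3))
        d = msmkin.sample_discrete_trajectories(chain, 5, 50, seed=0)
        for t in d.dtrajs:
            assert len(np.unique(t)) == 1

    def test_transition_frequencies_match_chain(self):
        # two-state chain with p = q = 0.2; empirical per-step transition
        # frequency must sit within 3 binomial standard errors of 0.2
        from msmkin.msm import count_transitions

        T = np.array([[0.8, 0.2], [0.2, 0.8]])
        chain = msmkin.make_metastable_chain(2, [0.5, 0.5], mixing=0.4)
        object.__setattr__(chain, "transition_matrix", T)
        d = msmkin.sample_discrete_trajectories(chain, 30, 100_000, seed=5)
        C = count_transitions(d, 1).counts
        for i in range(2):
            phat = C[i, 1 - i] / C[i].sum()
            se = np.sqrt(0.2 * 0.8 / C[i].sum())
            assert abs(phat - 0.2) < 3 * se

    def test_seed_determinism(self, chain8):
        a = msmkin.sample_discrete_trajectories(chain8, 3, 100, seed=42)
        b = msmkin.sample_discrete_trajectories(chain8, 3, 100, seed=42)
        for x, y in zip(a.dtrajs, b.dtrajs):
            np.testing.assert_array_equal(x, y)

    def test_bad_sizes_rejected(self, chain8):
        with pytest.raises(ValueError):
            msmkin.sample_discrete_trajectories(chain8, 0, 10)
        with pytest.raises(ValueError):
            msmkin.sample_discrete_trajectories(chain8, 1, 1)


class TestEmission:
    def test_zero_noise_reproduces_means(self, chain8):
        d = msmkin.sample_discrete_trajectories(chain8, 2, 200, seed=1)
        means = np.arange(chain8.n_states, dtype=float)[:, None] * [1.0, -1.0]
        spec = EmissionSpec(means=means, sds=np.zeros(chain8.n_states))
        feats = msmkin.emit_features(d, spec, seed=0)
        for dt, ft in zip(d.dtrajs, feats.trajs):
            np.testing.assert_array_equal(ft, means[dt])

    def test_separated_means_recoverable(self, chain8):
        d = msmkin.sample_discrete_trajectories(chain8, 5, 2000, seed=2)
        means = 10.0 * np.arange(chain8.n_states, dtype=float)[:, None]
        spec = EmissionSpec(means=means, sds=np.ones(chain8.n_states))
        feats = msmkin.emit_features(d, spec, seed=3)
        correct = total = 0
        for dt, ft in zip(d.dtrajs, feats.trajs):
            label = np.argmin(np.abs(ft - means[:, 0][None, :]), axis=1)
            correct += (label == dt).sum()
            total += len(dt)
        assert correct / total >= 0.999

    def test_missing_state_rejected(self, chain8):
        d = msmkin.sample_discrete_trajectories(chain8, 2, 200, seed=1)
        spec = EmissionSpec(means=np.zeros((2, 1)), sds=np.zeros(2))
        with pytest.raises(ValueError):
            msmkin.emit_features(d, spec)

    def test_determinism(self, chain8):
        d = msmkin.sample_discrete_trajectories(chain8, 2, 100, seed=1)
        spec = EmissionSpec(means=np.zeros((chain8.n_states, 2)),
                            sds=np.ones(chain8.n_states))
        a = msmkin.emit_features(d, spec, seed=7)
        b = msmkin.emit_features(d, spec, seed=7)
        for x, y in zip(a.trajs, b.trajs):
            np.testing.assert_array_equal(x, y)


class TestBiasTrace:
    def test_zero_schedule(self):
        tr = msmkin.make_bias_trace(BiasSchedule(kind="zero", duration=1.0))
        assert np.all(tr.bias == 0)
        assert np.all(np.diff(tr.times) > 0)

    def test_constant_schedule_level(self):
        kBT = 2.479
        tr = msmkin.make_bias_trace(
            BiasSchedule(kind="constant", duration=1.0, kBT=kBT,
                         level=kBT * np.log(2)))
        np.testing.assert_allclose(tr.bias, kBT * np.log(2))

    def test_deposition_nondecreasing(self):
        tr = msmkin.make_bias_trace(
            BiasSchedule(kind="gaussian-deposition", duration=0.5))
        assert np.all(np.diff(tr.bias) >= 0)
        assert tr.bias[-1] > 0

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            BiasSchedule(kind="zero", duration=0.0)


class TestDockingScores:
    def test_zero_sd_exact(self):
        t = msmkin.make_docking_scores(["M1"], [-5.7], sd=0.0, n_per_state=10)
        assert np.all(t["score"] == -5.7)

    def test_row_count_500_per_state(self):
        t = msmkin.make_docking_scores(
            [f"M{i}" for i in range(1, 9)], [-5.0] * 8, sd=1.0,
            n_per_state=500, seed=1)
        assert len(t) == 500 * 8

    def test_means_recovered(self):
        means = [-5.7, -2.0, 2.8]
        t = msmkin.make_docking_scores(["a", "b", "c"], means, sd=0.5,
                                       n_per_state=500, seed=3)
        got = t.groupby("macrostate")["score"].mean()
        for label, mu in zip(["a", "b", "c"], means):
            assert abs(got[label] - mu) < 3 * 0.5 / np.sqrt(500)


class TestRemdLadder:
    def test_two_replicas(self):
        lad = msmkin.remd_ladder(300.0, 400.0, 2)
        np.testing.assert_allclose(lad.temperatures, [300.0, 400.0])

    def test_published_ladder_spacing_and_second_rung(self):
        lad = msmkin.remd_ladder(295.0, 406.0, 32)
        # mean spacing (406-295)/31 = 3.58 K -> ~3.5 K at 0.5 K rounding
        assert round(lad.mean_spacing * 2) / 2 == 3.5
        assert abs(lad.temperatures[1] - 295.0 * (406.0 / 295.0) ** (1 / 31)) < 1e-9
        assert abs(lad.temperatures[1] - 298.06) < 0.05

    @given(st.floats(200, 300), st.floats(310, 500), st.integers(2, 64))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_geometric_property(self, tmin, tmax, n):
        lad = msmkin.remd_ladder(tmin, tmax, n)
        r = lad.temperatures[1:] / lad.temperatures[:-1]
        np.testing.assert_allclose(r, r[0], rtol=1e-9)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            msmkin.remd_ladder(300, 400, 1)
        with pytest.raises(ValueError):
            msmkin.remd_ladder(400, 300, 4)
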