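"""Markov-kernel estimation, analytic tilting and spectral/thermal analysis."""

import numpy as np
import pytest

from calipath.markov import (TransitionKernel, default_three_state_kernel,
                             eigenspectrum, enumerate_paths, estimate_kernel,
                             expected_pair_rate, free_energy_profile,
                             reweight_kernel, stationary_distribution)
from calipath.synthetic import simulate_markov
from calipath.trajectory import BinningSpec

from conftest import make_traj


class TestKernelContainer:
    def test_rows_must_be_stochastic(self):
        with pytest.raises(ValueError):
            TransitionKernel(np.array([[0.5, 0.4], [0.2, 0.8]]))
        with pytest.raises(ValueError):
            TransitionKernel(np.array([[1.1, -0.1], [0.2, 0.8]]))

    def test_csv_round_trip(self, tmp_path):
        k = default_three_state_kernel()
        p = tmp_path / "k.csv"
        k.to_csv(p)
        assert np.allclose(TransitionKernel.from_csv(p).matrix, k.matrix)

    def test_shipped_kernel_rate_regime(self):
        # documented calibration: unconstrained pair rate ~0.089
        k = default_three_state_kernel()
        rate = expected_pair_rate(k, [(0, 1), (1, 2)])
        assert rate == pytest.approx(0.0893, abs=0.0005)


class TestEstimateKernel:
    def test_deterministic_alternation(self):
        k = estimate_kernel(make_traj([0, 1, 0, 1, 0]))
        assert np.allclose(k.matrix, [[0, 1], [1, 0]])

    def test_direct_count_row(self):
        # a state seen only as the final sample has no outgoing counts
        with pytest.raises(ValueError, match="source"):
            estimate_kernel(make_traj([0, 0, 0, 1]), n_states=2)
        k = estimate_kernel(make_traj([0, 0, 0, 1, 1]), n_states=2)
        assert np.allclose(k.matrix[0], [2 / 3, 1 / 3])

    def test_long_sample_recovers_kernel(self):
        k = default_three_state_kernel()
        traj = simulate_markov(k, 200_000, init=0, seed=31)
        est = estimate_kernel(traj, n_states=3)
        # 3 binomial sigma entrywise
        counts = np.zeros((3, 3))
        np.add.at(counts, (traj.states[:-1], traj.states[1:]), 1)
        n_m = counts.sum(axis=1)
        se = np.sqrt(k.matrix * (1 - k.matrix) / n_m[:, None])
        assert np.all(np.abs(est.matrix - k.matrix) < 3 * se)

    def test_unvisited_source_rejected(self):
        with pytest.raises(ValueError, match="never visited"):
            estimate_kernel(make_traj([0, 1, 0, 1]), n_states=3)


class TestReweightKernel:
    def test_zero_tilt_is_identity(self):
        k = default_three_state_kernel()
        out = reweight_kernel(k, 0.0, [(0, 1), (1, 0)])
        assert np.allclose(out.matrix, k.matrix)

    def test_hand_renormalization(self):
        k = TransitionKernel(np.array([[0.9, 0.1], [0.2, 0.8]]))
        # e^{-dl} = 2 on the (0,1) entry
        out = reweight_kernel(k, -np.log(2.0), [(0, 1)])
        assert np.allclose(out.matrix[0], np.array([0.9, 0.2]) / 1.1)
        assert np.allclose(out.matrix[1], [0.2, 0.8])

    def test_per_step_convention_divides_by_length(self):
        k = TransitionKernel(np.array([[0.9, 0.1], [0.2, 0.8]]))
        a = reweight_kernel(k, -50.0, [(0, 1)], convention="per_step",
                            traj_length=100)
        b = reweight_kernel(k, -0.5, [(0, 1)])
        assert np.allclose(a.matrix, b.matrix)

    def test_composition_adds_tilts(self):
        k = default_three_state_kernel()
        pairs = [(0, 1), (1, 0), (1, 2), (2, 1)]
        once = reweight_kernel(k, 0.7, pairs)
        twice = reweight_kernel(reweight_kernel(k, 0.3, pairs), 0.4, pairs)
        assert np.allclose(once.matrix, twice.matrix, atol=1e-12)


class TestStationaryAndSpectrum:
    def test_symmetric_two_state(self):
        k = TransitionKernel(np.array([[0.7, 0.3], [0.3, 0.7]]))
        assert np.allclose(stationary_distribution(k), [0.5, 0.5])

    def test_two_by_two_linear_solve(self):
        k = TransitionKernel(np.array([[0.9, 0.1], [0.2, 0.8]]))
        assert np.allclose(stationary_distribution(k), [2 / 3, 1 / 3])

    def test_uniform_kernel_pair_rate(self):
        k = TransitionKernel(np.full((3, 3), 1 / 3))
        rate = expected_pair_rate(k, [(0, 1), (1, 2)])
        assert rate == pytest.approx(4 / 9)

    def test_reducible_kernel_rejected(self):
        k = TransitionKernel(np.eye(3))
        with pytest.raises(ValueError, match="reducible"):
            stationary_distribution(k)

    def test_identity_eigenvalues(self):
        vals, _ = eigenspectrum(TransitionKernel(np.eye(2) * 1.0 + 0.0))
        assert np.allclose(vals, 1.0)

    def test_two_state_closed_form(self):
        a, b = 0.2, 0.35
        k = TransitionKernel(np.array([[1 - a, a], [b, 1 - b]]))
        vals, ts = eigenspectrum(k, dt=2.0)
        assert vals[0] == pytest.approx(1.0)
        assert vals[1].real == pytest.approx(1 - a - b)
        assert ts[1] == pytest.approx(-2.0 / np.log(1 - a - b))

    def test_leading_eigenvalue_always_one(self, rng):
        m = rng.random((5, 5))
        k = TransitionKernel(m / m.sum(axis=1, keepdims=True))
        vals, _ = eigenspectrum(k)
        assert abs(vals[0]) == pytest.approx(1.0, abs=1e-10)


class TestFreeEnergy:
    def test_uniform_occupancy_is_flat_zero(self):
        t = make_traj(np.tile(np.arange(4), 25))
        assert np.allclose(free_energy_profile(t), 0.0)

    def test_ratio_arithmetic(self):
        t = make_traj([0] * 8 + [1] * 2)
        F = free_energy_profile(t, kT=1.0)
        assert F[0] == pytest.approx(0.0)
        assert F[1] == pytest.approx(np.log(4.0))

    def test_count_scaling_invariance(self):
        t1 = make_traj([0, 0, 1])
        t2 = make_traj([0, 0, 1] * 7)
        assert np.allclose(free_energy_profile(t1), free_energy_profile(t2))

    def test_unoccupied_bins_are_infinite(self):
        t = make_traj([0, 0, 1], BinningSpec(4, 0, 4))
        F = free_energy_profile(t)
        assert np.isinf(F[2]) and np.isinf(F[3])


class TestEnumeratePaths:
    def test_probabilities_sum_to_one(self):
        k = default_three_state_kernel()
        paths, probs = enumerate_paths(k, n_steps=5, init=0)
        assert paths.shape == (3 ** 6, 6)
        assert probs.sum() == pytest.approx(1.0, abs=1e-10)

    def test_single_step_structure(self):
        k = TransitionKernel(np.array([[0.9, 0.1], [0.2, 0.8]]))
        paths, probs = enumerate_paths(k, n_steps=1, init=0)
        table = {tuple(p): q for p, q in zip(paths, probs)}
        assert table[(0, 0)] == pytest.approx(0.9)
        assert table[(0, 1)] == pytest.approx(0.1)
        assert table[(1, 0)] == 0.0

    def test_pair_rate_consistency_with_stationary_formula(self):
        # stationary init: enumeration average == closed-form pi_m p_mn sum
        k = default_three_state_kernel()
        pi = stationary_distribution(k)
        paths, probs = enumerate_paths(k, n_steps=6, init=pi)
        pairs = [(0, 1), (1, 2)]
        lo = np.minimum(paths[:, :-1], paths[:, 1:])
        hi = np.maximum(paths[:, :-1], paths[:, 1:])
        events = sum(((lo == a) & (hi == b)).sum(axis=1) for a, b in pairs)
        avg = probs @ (events / 6)
        assert avg == pytest.approx(expected_pair_rate(k, pairs), abs=1e-12)

    def test_state_space_limit(self):
        k = TransitionKernel(np.full((10, 10), 0.1))
        with pytest.raises(ValueError, match="enumeration limit"):
            enumerate_paths(k, n_steps=7, init=0)
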