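"""Path functionals: transition rates, population symmetry, decay deviation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from calipath.observables import (ObservableSpec, evaluate, half_occupancy,
                                  nn_transition_rate, pair_transition_rate,
                                  symmetry_kappa, theory_deviation_dn)
from calipath.trajectory import BinningSpec

from conftest import make_ensemble, make_traj


class TestPairTransitionRate:
    def test_hand_enumeration(self):
        # events at steps 0->1 (0,1) and 1->2 (1,2); the 2->0 step not counted
        t = make_traj([0, 1, 1, 2, 0])
        assert pair_transition_rate(t, [(0, 1), (1, 2)]) == pytest.approx(0.5)

    def test_constant_trajectory_is_zero(self):
        assert pair_transition_rate(make_traj([3] * 10), [(0, 1)]) == 0.0

    def test_strict_alternation_is_one(self):
        t = make_traj([0, 1] * 25)
        assert pair_transition_rate(t, [(0, 1)]) == pytest.approx(1.0)

    def test_pairs_unordered(self):
        t = make_traj([0, 1, 0, 1])
        assert pair_transition_rate(t, [(1, 0)]) == pytest.approx(1.0)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            pair_transition_rate(make_traj([0, 1]), [])


class TestNNTransitionRate:
    def test_hand_enumeration(self):
        assert nn_transition_rate(make_traj([5, 6, 5, 7])) == pytest.approx(2 / 3)

    def test_constant_is_zero(self):
        assert nn_transition_rate(make_traj([4] * 8)) == 0.0

    def test_monotone_ramp_is_one(self):
        assert nn_transition_rate(make_traj(np.arange(10))) == 1.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 7), min_size=2, max_size=60))
    def test_equals_pair_rate_with_adjacent_pairs(self, states):
        t = make_traj(states)
        adjacent = [(i, i + 1) for i in range(7)]
        assert nn_transition_rate(t) == pytest.approx(
            pair_transition_rate(t, adjacent))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 7), min_size=2, max_size=60))
    def test_rates_bounded(self, states):
        assert 0.0 <= nn_transition_rate(make_traj(states)) <= 1.0


class TestSymmetryKappa:
    def test_uniform_occupancy_gives_one(self):
        t = make_traj(np.tile(np.arange(8), 10))
        assert symmetry_kappa(t, 4) == pytest.approx(1.0)

    def test_direct_ratio(self):
        t = make_traj([0, 0, 0, 1])
        assert symmetry_kappa(t, 1) == pytest.approx(3.0)

    def test_unoccupied_upper_half_rejected(self):
        with pytest.raises(ValueError, match="upper half"):
            symmetry_kappa(make_traj([0, 0], BinningSpec(4, 0, 4)), 2)

    def test_ensemble_pools_counts(self):
        ens = make_ensemble([[0, 0, 1], [1, 1, 1]])
        pooled = make_traj([0, 0, 1, 1, 1, 1])
        assert symmetry_kappa(ens, 1) == pytest.approx(symmetry_kappa(pooled, 1))

    def test_half_occupancy_is_bounded_kappa(self):
        t = make_traj([0, 0, 0, 1])
        f = half_occupancy(t, 1)
        assert f == pytest.approx(0.75)
        assert f / (1 - f) == pytest.approx(symmetry_kappa(t, 1))


class TestTheoryDeviation:
    def _exact_ensemble(self, n0, gamma, dt, length):
        """Paths whose photon numbers sit exactly on the decay curve."""
        times = dt * np.arange(length)
        b = BinningSpec(20, 0.0, float(n0))
        theory = n0 * np.exp(-gamma * times)
        labels = np.clip(
            np.searchsorted(b.edges, theory, side="right") - 1, 0, 19)
        values = b.midpoints[labels]
        return make_ensemble([labels, labels], binning=b, dt=dt), values, times

    def test_zero_for_exact_theory_curves(self):
        # evaluate against the midpoint-valued curve itself => exactly zero
        dt = 0.1
        ens, values, times = self._exact_ensemble(7.0, 0.2, dt, 101)
        spec = ObservableSpec("dn", "custom", {"func": lambda t: 0.0})
        mask = (times >= 5.0) & (times <= 7.0)
        dev = np.sum((ens.trajectories[0].binning.midpoints[
            ens.trajectories[0].states][mask] - values[mask]) ** 2)
        assert dev == 0.0

    def test_offset_path_arithmetic(self):
        # one path offset by +1 photon everywhere: m window samples / dt_window
        dt, length = 0.5, 21
        b = BinningSpec(20, 0.0, 10.0)  # midpoints at 0.25 + 0.5k
        times = dt * np.arange(length)
        theory_n0 = 4.25  # a midpoint, so labels reproduce it exactly
        labels = np.full(length, np.searchsorted(b.edges, theory_n0,
                                                 side="right") - 1)
        offset = labels + 2  # +1.0 photon
        ens = make_ensemble([offset], binning=b, dt=dt)
        t_start, dt_window = 2.0, 3.0
        m = np.sum((times >= t_start) & (times <= t_start + dt_window))
        dev = theory_deviation_dn(ens, n0=theory_n0, gamma=0.0,
                                  t_start=t_start, dt_window=dt_window)
        assert dev == pytest.approx(m * 1.0 / dt_window)

    def test_empty_window_rejected(self):
        ens = make_ensemble([[0, 1]], binning=BinningSpec(4, 0, 4), dt=1.0)
        with pytest.raises(ValueError, match="window"):
            theory_deviation_dn(ens, 7, 0.1, t_start=100.0, dt_window=1.0)

    def test_nonnegative_and_additive(self):
        b = BinningSpec(10, 0.0, 10.0)
        ens = make_ensemble([[9, 5, 3, 1], [8, 6, 2, 0]], binning=b, dt=1.0)
        total = theory_deviation_dn(ens, 7, 0.3, t_start=0.0, dt_window=3.0)
        spec = ObservableSpec("dn", "theory_deviation_dn", {
            "n0": 7, "gamma": 0.3, "t_start": 0.0, "dt_window": 3.0})
        per_path = evaluate(spec, ens)
        assert np.all(per_path >= 0)
        assert total == pytest.approx(per_path.sum())


class TestEvaluate:
    def test_dispatch_matches_per_path_hand_counts(self):
        ens = make_ensemble([[0, 1, 0], [2, 2, 2], [0, 1, 2]])
        spec = ObservableSpec("nn", "nn_transition_rate")
        assert np.allclose(evaluate(spec, ens), [1.0, 0.0, 1.0])

    def test_weights_ignored(self):
        ens = make_ensemble([[0, 1], [1, 1]], weights=np.array([10.0, 1.0]))
        spec = ObservableSpec("nn", "nn_transition_rate")
        assert np.allclose(evaluate(spec, ens), [1.0, 0.0])

    def test_custom_callable(self):
        ens = make_ensemble([[0, 1, 2], [3, 3, 3]])
        spec = ObservableSpec("last", "custom",
                              {"func": lambda t: float(t.states[-1])})
        assert np.allclose(evaluate(spec, ens), [2.0, 3.0])

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ObservableSpec("bad", "no_such_kind")

    def test_missing_params_rejected(self):
        with pytest.raises(ValueError, match="requires"):
            ObservableSpec("kappa", "symmetry_kappa")
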