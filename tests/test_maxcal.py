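"""Maximum-Caliber tilt solving, path weights and biased subsampling."""

import numpy as np
import pytest
from scipy.optimize import bisect

from calipath import maxcal
from calipath.maxcal import (ConstraintTarget, effective_sample_size,
                             path_weights, reweighted_mean, solve_delta_lambda,
                             solve_multi, subsample)
from calipath.observables import ObservableSpec

from conftest import make_ensemble


class TestSolveDeltaLambda:
    def test_target_at_mean_gives_zero(self):
        s = np.array([0.1, 0.2, 0.3, 0.4])
        assert solve_delta_lambda(s, s.mean()) == pytest.approx(0.0, abs=1e-9)

    def test_two_point_logistic_closed_form(self):
        # s in {0,1}: reweighted mean = 1/(1+e^{dl}); target 1/(1+e) => dl=1
        s = np.array([0.0, 1.0] * 10)
        assert solve_delta_lambda(s, 0.5) == pytest.approx(0.0, abs=1e-9)
        dl = solve_delta_lambda(s, 1.0 / (1.0 + np.e))
        assert dl == pytest.approx(1.0, rel=1e-9)

    def test_agrees_with_bisection_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            s = rng.normal(size=50)
            target = rng.uniform(np.quantile(s, 0.1), np.quantile(s, 0.9))
            dl = solve_delta_lambda(s, target)
            oracle = bisect(lambda x: reweighted_mean(s, x) - target,
                            -200.0, 200.0, xtol=1e-12)
            assert dl == pytest.approx(oracle, abs=1e-7)

    def test_raising_a_rate_target_gives_negative_multiplier(self):
        # tilting toward more transitions means dl < 0 (sign convention)
        s = np.array([0.05, 0.08, 0.09, 0.10, 0.12, 0.15])
        assert solve_delta_lambda(s, 0.13) < 0

    def test_unreachable_target_rejected(self):
        s = np.array([0.0, 1.0])
        with pytest.raises(ValueError, match="unreachable"):
            solve_delta_lambda(s, 1.5)
        with pytest.raises(ValueError, match="unreachable"):
            solve_delta_lambda(s, 1.0)  # open range excludes max

    def test_degenerate_observable_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            solve_delta_lambda(np.ones(10), 1.0)

    def test_residual_precision(self):
        rng = np.random.default_rng(17)
        s = rng.exponential(size=200)
        target = 0.4 * s.mean()
        dl = solve_delta_lambda(s, target)
        assert abs(reweighted_mean(s, dl) - target) < 1e-10 * target


class TestPathWeights:
    def test_zero_tilt_is_uniform(self):
        w = path_weights(np.array([1.0, 2.0, 3.0]), 0.0)
        assert np.allclose(w, 1 / 3)

    def test_two_point_ratio(self):
        w = path_weights(np.array([0.0, 1.0]), np.log(3.0))
        assert np.allclose(w, [0.75, 0.25])

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=30)
        assert np.allclose(path_weights(s, 1.7), path_weights(s + 5.0, 1.7))

    def test_log_space_matches_naive_in_safe_regime(self):
        rng = np.random.default_rng(4)
        s = rng.uniform(-1, 1, size=40)
        dl = 3.0  # |dl * s| < 20
        naive = np.exp(-dl * s)
        naive /= naive.sum()
        assert np.allclose(path_weights(s, dl), naive, atol=1e-12)

    def test_extreme_tilt_does_not_overflow(self):
        s = np.linspace(0, 1, 50)
        w = path_weights(s, -5000.0)
        assert np.isfinite(w).all()
        assert w.argmax() == 49  # all weight on the largest s

    def test_monotone_reweighted_mean(self):
        # d<s>/d(dl) = -Var_w(s) <= 0 at every tested point
        rng = np.random.default_rng(5)
        for _ in range(20):
            s = rng.normal(size=30)
            grid = np.linspace(-4, 4, 41)
            means = [reweighted_mean(s, d) for d in grid]
            assert np.all(np.diff(means) <= 1e-12)


class TestSolveMulti:
    def test_targets_at_means_give_zeros(self):
        rng = np.random.default_rng(6)
        s1, s2 = rng.normal(size=50), rng.normal(size=50)
        dl = solve_multi([(s1, s1.mean()), (s2, s2.mean())])
        assert np.allclose(dl, 0.0, atol=1e-8)

    def test_inconsistent_correlated_targets_fail(self):
        s = np.array([0.0, 1.0] * 20)
        # s2 == s1 but targets disagree: no solution exists
        with pytest.raises((RuntimeError, ValueError)):
            solve_multi([(s, 0.3), (s, 0.7)])

    def test_two_constraint_toy_matches_grid_oracle(self):
        # enumerable weights over (s1, s2) in {0,1}^2
        s1 = np.array([0.0, 0.0, 1.0, 1.0])
        s2 = np.array([0.0, 1.0, 0.0, 1.0])
        t1, t2 = 0.4, 0.35
        dl = solve_multi([(s1, t1), (s2, t2)])
        w = path_weights(np.column_stack([s1, s2]), dl)
        assert w @ s1 == pytest.approx(t1, abs=1e-8)
        assert w @ s2 == pytest.approx(t2, abs=1e-8)
        # brute-force grid refinement around the solution
        best, best_err = None, np.inf
        for a in np.linspace(dl[0] - 0.5, dl[0] + 0.5, 81):
            for b in np.linspace(dl[1] - 0.5, dl[1] + 0.5, 81):
                wg = path_weights(np.column_stack([s1, s2]), [a, b])
                err = abs(wg @ s1 - t1) + abs(wg @ s2 - t2)
                if err < best_err:
                    best, best_err = (a, b), err
        assert np.allclose(dl, best, atol=2e-2)

    def test_requires_two_constraints(self):
        with pytest.raises(ValueError):
            solve_multi([(np.array([0.0, 1.0]), 0.5)])


class TestSubsample:
    def test_uniform_full_draw_is_permutation(self):
        ens = make_ensemble([[i, i] for i in range(6)])
        out = subsample(ens, np.ones(6), 6, seed=3)
        got = sorted(t.states[0] for t in out)
        assert got == list(range(6))

    def test_point_mass_selects_that_path(self):
        ens = make_ensemble([[0, 0], [1, 1], [2, 2]])
        w = np.array([0.0, 1.0, 0.0])
        out = subsample(ens, w, 1, seed=0)
        assert out.trajectories[0].states[0] == 1

    def test_selection_frequencies_match_weights(self):
        ens = make_ensemble([[0, 0], [1, 1], [2, 2], [3, 3]])
        w = np.array([0.1, 0.2, 0.3, 0.4])
        counts = np.zeros(4)
        n_rep = 10_000
        for i in range(n_rep):
            out = subsample(ens, w, 1, seed=i)
            counts[out.trajectories[0].states[0]] += 1
        freq = counts / n_rep
        se = np.sqrt(w * (1 - w) / n_rep)
        assert np.all(np.abs(freq - w) < 3 * se)

    def test_k_exceeding_nonzero_weights_rejected(self):
        ens = make_ensemble([[0, 0], [1, 1], [2, 2]])
        with pytest.raises(ValueError, match="nonzero"):
            subsample(ens, np.array([1.0, 0.0, 0.0]), 2, seed=0)

    def test_systematic_resampling_mean_matches_weights(self):
        ens = make_ensemble([[i, i] for i in range(5)])
        w = np.array([0.05, 0.1, 0.15, 0.3, 0.4])
        out = subsample(ens, w, 5, seed=11, method="systematic")
        vals = np.array([t.states[0] for t in out])
        # systematic draw puts each path in with multiplicity ~ 5*w
        assert abs(vals.mean() - np.arange(5) @ w) < 1.0


class TestConstraintTarget:
    def test_quantile_resolution(self):
        spec = ObservableSpec("nn", "nn_transition_rate")
        c = ConstraintTarget(observable=spec, target_quantile=0.25)
        s = np.arange(101, dtype=float)
        assert c.resolve_target(s) == pytest.approx(25.0)

    def test_requires_some_target(self):
        spec = ObservableSpec("nn", "nn_transition_rate")
        with pytest.raises(ValueError):
            ConstraintTarget(observable=spec)

    def test_ess(self):
        assert effective_sample_size(np.ones(8)) == pytest.approx(8.0)
        assert effective_sample_size(np.array([1.0, 0, 0])) == pytest.approx(1.0)
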