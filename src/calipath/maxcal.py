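"""Maximum-Caliber resampling of generated path ensembles.

Maximum Caliber is the dynamical analogue of maximum entropy: among all path
distributions matching a set of path-ensemble-averaged constraints
<s_j(Gamma)> = s_bar_j, the one closest to a reference distribution P^A is
the exponentially tilted

    P^B(Gamma)  ∝  exp(-sum_j dlambda_j s_j(Gamma)) P^A(Gamma).

Given a sample Omega = {Gamma_k} drawn from P^A (here: trajectories
generated by a trained sequence model), each dlambda_j is fixed by requiring
the self-normalized reweighted average to hit its target,

    s_bar^B = sum_k s(Gamma_k) e^{-dl s(Gamma_k)} / sum_k e^{-dl s(Gamma_k)},

which is strictly decreasing in dlambda (its derivative is minus the
weighted variance), so a bracketed root find is guaranteed to converge once
the root is bracketed.  The constrained ("path-sampled") model is obtained
by drawing a small subset with probability proportional to the tilted
weights and retraining a fresh sequence model on that subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

from . import model as _model
from .observables import ObservableSpec, evaluate
from .trajectory import PathEnsemble

__all__ = [
    "ConstraintTarget",
    "ConstraintSolution",
    "solve_delta_lambda",
    "solve_multi",
    "path_weights",
    "reweighted_mean",
    "effective_sample_size",
    "subsample",
    "constrain_pipeline",
]


@dataclass
class ConstraintTarget:
    """One constraint: an observable and the ensemble average it must take.

    ``target_quantile``, if given, resolves the numeric target at solve time
    as that quantile of the sampled per-path values — the practical way to
    push an always-positive penalty observable (e.g. the decay-curve
    deviation delta_n) toward its sampled minimum, since an exact target of
    0 lies outside the open range of any finite sample.
    """

    observable: ObservableSpec
    target: Optional[float] = None
    tolerance: float = 0.02
    target_quantile: Optional[float] = None

    def __post_init__(self) -> None:
        if self.target is None and self.target_quantile is None:
            raise ValueError("either target or target_quantile is required")
        if self.target is not None and not np.isfinite(self.target):
            raise ValueError("target must be finite")
        if self.target_quantile is not None and not (0 < self.target_quantile < 1):
            raise ValueError("target_quantile must lie in (0, 1)")

    def resolve_target(self, s_values: np.ndarray) -> float:
        if self.target is not None:
            return float(self.target)
        return float(np.quantile(s_values, self.target_quantile))


@dataclass
class ConstraintSolution:
    """Solved multipliers, per-path weights and diagnostics."""

    delta_lambda: np.ndarray
    weights: np.ndarray
    achieved: np.ndarray
    ess: float
    targets: np.ndarray = field(default=None)  # type: ignore[assignment]
    diagnostics: dict = field(default_factory=dict)


def _log_weights(s_matrix: np.ndarray, delta_lambda: np.ndarray) -> np.ndarray:
    s = np.atleast_2d(np.asarray(s_matrix, dtype=float).T).T  # (K, J)
    dl = np.atleast_1d(np.asarray(delta_lambda, dtype=float))
    return -(s @ dl)


def path_weights(s_matrix: np.ndarray, delta_lambda) -> np.ndarray:
    """Normalized tilted weights w_k ∝ exp(-sum_j dl_j s_j(Gamma_k)).

    Computed in log space (log-sum-exp) so large |dl * s| cannot overflow.
    ``s_matrix`` is (K,) for one constraint or (K, J) for J constraints.
    """
    logw = _log_weights(s_matrix, delta_lambda)
    return np.exp(logw - logsumexp(logw))


def reweighted_mean(s_values: np.ndarray, delta_lambda: float) -> float:
    """Self-normalized tilted average of one observable."""
    s = np.asarray(s_values, dtype=float)
    logw = -delta_lambda * s
    logw -= logw.max()
    w = np.exp(logw)
    return float((w @ s) / w.sum())


def effective_sample_size(weights: np.ndarray) -> float:
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    return float(1.0 / np.sum(w * w))


def solve_delta_lambda(s_values: Sequence[float], target: float) -> float:
    """Solve the single-constraint tilted-average equation for dlambda.

    Requires ``min(s) < target < max(s)`` strictly: the tilted average can
    only reach values in the open range of the sampled observable.
    """
    s = np.asarray(s_values, dtype=float)
    if s.size < 2:
        raise ValueError("need at least two sampled values")
    smin, smax = float(s.min()), float(s.max())
    if smin == smax:
        raise ValueError("degenerate observable: all sampled values equal")
    if not (smin < target < smax):
        raise ValueError(
            f"constraint unreachable from sampled ensemble: target {target} "
            f"outside open range ({smin}, {smax}) — generate more/longer paths")

    def f(dl: float) -> float:
        return reweighted_mean(s, dl) - target

    # f is strictly decreasing; expand a bracket geometrically
    scale = 1.0 / max(float(np.std(s)), 1e-12)
    lo, hi = -scale, scale
    for _ in range(200):
        if f(lo) > 0:
            break
        lo *= 2.0
    for _ in range(200):
        if f(hi) < 0:
            break
        hi *= 2.0
    root = optimize.brentq(f, lo, hi, xtol=1e-300, rtol=8.9e-16, maxiter=300)
    resid = abs(f(root)) / max(1.0, abs(target))
    if resid > 1e-10:
        raise RuntimeError(f"root refinement failed, relative residual {resid:.2e}")
    return float(root)


def solve_multi(
    constraints: Sequence[Tuple[Sequence[float], float]],
) -> np.ndarray:
    """Solve the coupled tilted-average equations for >= 2 constraints.

    Weights are exp(-sum_j dl_j s_j(Gamma)); the residual vector of
    reweighted averages minus targets is driven below 1e-8 by a hybrid
    Newton root find with finite-difference Jacobian.
    """
    if len(constraints) < 2:
        raise ValueError("solve_multi needs >= 2 constraints")
    s_mat = np.column_stack([np.asarray(s, dtype=float) for s, _ in constraints])
    targets = np.asarray([t for _, t in constraints], dtype=float)
    for j in range(s_mat.shape[1]):
        col = s_mat[:, j]
        if not (col.min() < targets[j] < col.max()):
            raise ValueError(
                f"constraint {j}: target {targets[j]} outside open sampled "
                f"range ({col.min()}, {col.max()})")

    def resid(dl: np.ndarray) -> np.ndarray:
        w = path_weights(s_mat, dl)
        return w @ s_mat - targets

    sol = optimize.root(resid, x0=np.zeros(len(targets)), method="hybr",
                        options={"maxfev": 20000})
    r = resid(sol.x)
    if np.max(np.abs(r)) > 1e-8:
        raise RuntimeError(
            f"multi-constraint solve did not converge; residuals {r} "
            "(targets may be jointly unreachable, e.g. perfectly correlated "
            "observables with inconsistent targets)")
    return np.asarray(sol.x)


def subsample(
    ensemble: PathEnsemble,
    weights: Sequence[float],
    k: int,
    seed: int,
    method: str = "without_replacement",
) -> PathEnsemble:
    """Draw ``k`` trajectories with probability proportional to ``weights``.

    Default is weighted draws without replacement (no duplicate training
    sequences in the retraining subset); ``method='systematic'`` offers
    low-variance systematic resampling (with replacement semantics) for
    small ensembles.  Returns an unweighted ensemble; seed-reproducible.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (ensemble.n_paths,):
        raise ValueError("one weight per path required")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if k > ensemble.n_paths:
        raise ValueError("k exceeds ensemble size")
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    if method == "without_replacement":
        if k > int(np.sum(p > 0)):
            raise ValueError(
                f"k={k} exceeds the {int(np.sum(p > 0))} paths with nonzero weight")
        idx = rng.choice(ensemble.n_paths, size=k, replace=False, p=p)
    elif method == "systematic":
        positions = (rng.random() + np.arange(k)) / k
        idx = np.searchsorted(np.cumsum(p), positions)
        idx = np.minimum(idx, ensemble.n_paths - 1)
    else:
        raise ValueError(f"unknown subsampling method {method!r}")
    return PathEnsemble(trajectories=[ensemble.trajectories[i] for i in idx])


def constrain_pipeline(
    model: "_model.SequenceModel",
    constraints: Sequence[ConstraintTarget],
    n_generate: int,
    subset_size: int,
    length: int,
    init,
    seed: int,
    retrain_config: Optional["_model.ModelConfig"] = None,
    subsample_method: str = "without_replacement",
    verify: bool = True,
    verify_n_paths: int = 50,
) -> Tuple["_model.SequenceModel", ConstraintSolution, PathEnsemble]:
    """Full constrained-retraining workflow (the "path-sampled" model).

    generate -> evaluate s(Gamma) -> solve dlambda -> weighted subsample ->
    retrain a fresh model on the subset.  The retrained model's own
    generated ensemble is then re-measured against each target; a miss
    beyond tolerance raises a warning with the achieved values (never a
    silent success).

    Returns ``(retrained_model, solution, subset_ensemble)``.
    """
    if n_generate < subset_size:
        raise ValueError("n_generate must be >= subset_size")
    seeds = np.random.SeedSequence(seed).generate_state(4) % (2**31)

    ens = _model.generate(model, n_generate, length, init, seed=int(seeds[0]))

    if constraints:
        s_cols, targets = [], []
        for c in constraints:
            s = evaluate(c.observable, ens)
            s_cols.append(s)
            targets.append(c.resolve_target(s))
        s_mat = np.column_stack(s_cols)
        if len(constraints) == 1:
            dl = np.asarray([solve_delta_lambda(s_mat[:, 0], targets[0])])
        else:
            dl = solve_multi(list(zip(s_cols, targets)))
        weights = path_weights(s_mat, dl)
        achieved = weights @ s_mat
        targets = np.asarray(targets)
    else:
        s_mat = np.zeros((n_generate, 0))
        dl = np.zeros(0)
        weights = np.full(n_generate, 1.0 / n_generate)
        achieved = np.zeros(0)
        targets = np.zeros(0)

    subset = subsample(ens, weights, subset_size, seed=int(seeds[1]),
                       method=subsample_method)

    cfg = retrain_config
    if cfg is None:
        cfg = _model.ModelConfig(**{**model.config.__dict__})
    cfg.seed = int(seeds[2])  # fresh random initialization, never a warm start
    new_model = _model.train(subset, cfg)

    diagnostics = {
        "per_path_s": s_mat,
        "subset_s": None if not constraints else np.column_stack(
            [evaluate(c.observable, subset) for c in constraints]),
    }
    if verify and constraints:
        vens = _model.generate(new_model, verify_n_paths, length, init,
                               seed=int(seeds[3]))
        v_means = np.asarray(
            [np.mean(evaluate(c.observable, vens)) for c in constraints])
        diagnostics["verified"] = v_means
        for j, c in enumerate(constraints):
            rel = abs(v_means[j] - targets[j]) / max(abs(targets[j]), 1e-12)
            if rel > c.tolerance:
                warnings.warn(
                    f"constraint {c.observable.name!r}: retrained model "
                    f"achieves {v_means[j]:.4g} vs target {targets[j]:.4g} "
                    f"(relative error {rel:.1%} > tolerance {c.tolerance:.1%})")

    solution = ConstraintSolution(
        delta_lambda=dl,
        weights=weights,
        achieved=achieved,
        ess=effective_sample_size(weights),
        targets=targets,
        diagnostics=diagnostics,
    )
    return new_model, solution, subset
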