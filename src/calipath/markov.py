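"""Closed-form Markov-chain machinery used as the analytic oracle.

For a discrete-time Markov chain the path probability factorizes,
P(Gamma) = p_{i0} * prod_k p_{i_k i_{k+1}}, so Maximum-Caliber tilting of
pairwise transition counts has an exact closed form: each counted kernel
entry is multiplied by exp(-dlambda) (or exp(-dlambda / L_traj) when the
constrained observable is a per-step rate) and rows are renormalized.  This
module provides kernel estimation by direct counting, that analytic
reweighting, stationary/spectral analysis, free-energy profiles and exact
small-system path enumeration — everything the sampled pipeline is checked
against.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.sparse.csgraph import connected_components

from .trajectory import BinningSpec, PathEnsemble

__all__ = [
    "TransitionKernel",
    "default_three_state_kernel",
    "estimate_kernel",
    "reweight_kernel",
    "stationary_distribution",
    "expected_pair_rate",
    "eigenspectrum",
    "free_energy_profile",
    "enumerate_paths",
]


@dataclass
class TransitionKernel:
    """Row-stochastic transition matrix with 0-based state labels."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("kernel must be a square matrix")
        if np.any(m < 0):
            raise ValueError("kernel entries must be nonnegative")
        rows = m.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-10):
            raise ValueError(f"rows must sum to 1 within 1e-10, got {rows}")
        self.matrix = m

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]

    def to_csv(self, path: Union[str, Path]) -> None:
        n = self.n_states
        lines = [",".join(str(j) for j in range(n))]
        for row in self.matrix:
            lines.append(",".join(repr(float(v)) for v in row))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "TransitionKernel":
        lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
        rows = [[float(c) for c in ln.split(",")] for ln in lines[1:]]
        return cls(matrix=np.asarray(rows))


def default_three_state_kernel() -> TransitionKernel:
    """The repository's documented 3-state benchmark kernel.

    Symmetric (hence uniform stationary distribution) and calibrated so the
    unconstrained nearest-neighbour pair rate over {0,1} and {1,2} is
    4 * 0.067 / 3 ~= 0.0893, the slow-hopping regime of the 3-state
    constraint experiment.
    """
    from importlib import resources

    with resources.as_file(
        resources.files("calipath.data") / "three_state_kernel.csv"
    ) as p:
        return TransitionKernel.from_csv(p)


def _pooled_transition_counts(data, n_states: Optional[int]) -> np.ndarray:
    if isinstance(data, PathEnsemble):
        trajs = list(data.trajectories)
    else:
        trajs = [data]
    if n_states is None:
        binning = trajs[0].binning
        if binning is not None:
            n_states = binning.n_bins
        else:
            n_states = max(int(t.states.max()) for t in trajs) + 1
    counts = np.zeros((n_states, n_states))
    for t in trajs:
        s = t.states
        np.add.at(counts, (s[:-1], s[1:]), 1.0)
    return counts


def estimate_kernel(data, n_states: Optional[int] = None) -> TransitionKernel:
    """Maximum-likelihood kernel by direct transition counting.

    Every state in 0..n_states-1 must occur at least once as a source;
    otherwise its row would be undefined and an error lists the culprits.
    """
    counts = _pooled_transition_counts(data, n_states)
    row_tot = counts.sum(axis=1)
    empty = np.flatnonzero(row_tot == 0)
    if empty.size:
        raise ValueError(f"states never visited as a source: {empty.tolist()}")
    return TransitionKernel(matrix=counts / row_tot[:, None])


def reweight_kernel(
    kernel: TransitionKernel,
    delta_lambda: float,
    counted_transitions: Iterable[Tuple[int, int]],
    convention: str = "per_event",
    traj_length: Optional[int] = None,
) -> TransitionKernel:
    """Analytic Maximum-Caliber tilt of a Markov kernel.

    Each counted (ordered) entry (m, n) is multiplied by exp(-x) and rows
    are renormalized, where x = delta_lambda for a per-event constraint or
    x = delta_lambda / traj_length when the constrained observable is a
    transition rate per step (``convention='per_step'``).
    """
    if convention == "per_event":
        expo = delta_lambda
    elif convention == "per_step":
        if traj_length is None or traj_length <= 0:
            raise ValueError("per_step convention requires a positive traj_length")
        expo = delta_lambda / traj_length
    else:
        raise ValueError(f"unknown convention {convention!r}")
    n = kernel.n_states
    factor = np.ones((n, n))
    for m, k in counted_transitions:
        if not (0 <= m < n and 0 <= k < n):
            raise ValueError(f"transition ({m},{k}) out of range")
        factor[m, k] = np.exp(-expo)
    tilted = kernel.matrix * factor
    return TransitionKernel(matrix=tilted / tilted.sum(axis=1, keepdims=True))


def _require_irreducible(kernel: TransitionKernel) -> None:
    adj = (kernel.matrix > 0).astype(int)
    n_comp, _ = connected_components(adj, directed=True, connection="strong")
    if n_comp != 1:
        raise ValueError("kernel is reducible; stationary distribution not unique")


def stationary_distribution(kernel: TransitionKernel) -> np.ndarray:
    """pi with pi P = pi, sum(pi) = 1, via a dense linear solve."""
    _require_irreducible(kernel)
    n = kernel.n_states
    a = np.vstack([kernel.matrix.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def expected_pair_rate(kernel: TransitionKernel, pairs: Iterable) -> float:
    """Stationary per-step rate <N> = sum over counted (m,n) of pi_m p_mn.

    ``pairs`` are unordered; both directions are counted.
    """
    pi = stationary_distribution(kernel)
    seen = set()
    for a, b in pairs:
        seen.add((int(a), int(b)))
        seen.add((int(b), int(a)))
    return float(sum(pi[m] * kernel.matrix[m, k] for m, k in seen if m != k))


def eigenspectrum(kernel: TransitionKernel, dt: float = 1.0):
    """Eigenvalues sorted by modulus (leading one is 1) + implied timescales.

    Timescales t_i = -dt / ln|lambda_i| are reported for |lambda_i| < 1;
    the stationary eigenvalue has no finite timescale (inf).
    """
    vals = np.linalg.eigvals(kernel.matrix)
    order = np.argsort(-np.abs(vals))
    vals = vals[order]
    if abs(abs(vals[0]) - 1.0) > 1e-10:
        raise RuntimeError("leading eigenvalue of a stochastic matrix must be 1")
    mod = np.abs(vals)
    with np.errstate(divide="ignore"):
        timescales = np.where(mod < 1.0, -dt / np.log(np.where(mod < 1, mod, 0.5)),
                              np.inf)
    return vals, timescales


def free_energy_profile(
    data,
    binning: Optional[BinningSpec] = None,
    kT: float = 1.0,
) -> np.ndarray:
    """F_i = -kT ln P_i from direct counting, shifted so min F = 0.

    Unoccupied bins get +inf.
    """
    if isinstance(data, PathEnsemble):
        states = data.states_matrix().ravel()
        b = binning or data.trajectories[0].binning
    else:
        states = data.states
        b = binning or data.binning
    n_bins = b.n_bins if b is not None else int(states.max()) + 1
    counts = np.bincount(states, minlength=n_bins).astype(float)
    if counts.sum() == 0:
        raise ValueError("empty input")
    with np.errstate(divide="ignore"):
        F = -kT * np.log(counts / counts.sum())
    finite = np.isfinite(F)
    F[finite] -= F[finite].min()
    return F


def enumerate_paths(
    kernel: TransitionKernel,
    n_steps: int,
    init: Union[int, Sequence[float]],
) -> Tuple[np.ndarray, np.ndarray]:
    """All paths of ``n_steps`` transitions with exact probabilities.

    Returns ``(paths, probs)`` with ``paths`` of shape
    (n_states**(n_steps+1), n_steps+1); probabilities sum to 1.  ``init`` is
    a start label or a distribution over start states.
    """
    n = kernel.n_states
    n_paths = n ** (n_steps + 1)
    if n_paths > 10**6:
        raise ValueError(
            f"{n_paths} paths exceed the enumeration limit; sample instead")
    if np.isscalar(init):
        p0 = np.zeros(n)
        p0[int(init)] = 1.0
    else:
        p0 = np.asarray(init, dtype=float)
        if p0.shape != (n,) or not np.isclose(p0.sum(), 1.0):
            raise ValueError("init distribution must be a length-n probability vector")
    # mixed-radix enumeration, most significant digit = first state
    idx = np.arange(n_paths)
    paths = np.empty((n_paths, n_steps + 1), dtype=np.int64)
    for pos in range(n_steps, -1, -1):
        paths[:, pos] = idx % n
        idx //= n
    with np.errstate(divide="ignore"):
        logp = np.log(p0)[paths[:, 0]]
        logk = np.log(kernel.matrix)
    for t in range(n_steps):
        logp = logp + logk[paths[:, t], paths[:, t + 1]]
    probs = np.exp(logp)
    probs[~np.isfinite(logp)] = 0.0
    return paths, probs
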