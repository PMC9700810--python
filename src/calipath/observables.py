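"""Path-dependent functionals s(Gamma) evaluated on trajectories/ensembles.

These are the quantities constrained by Maximum-Caliber resampling:

* ``pair_transition_rate`` — mean number of transitions per step between a
  chosen set of unordered state pairs, <N> = N_events / L_traj.
* ``nn_transition_rate`` — same with all nearest-neighbour (|i-j| = 1)
  pairs; a diffusivity-like kinetic observable.
* ``symmetry_kappa`` — ratio of lower-half to upper-half bin populations;
  kappa = 1 for a symmetric equilibrium profile.
* ``theory_deviation_dn`` — windowed squared deviation of photon-number
  trajectories from the classical exponential-decay curve n0*exp(-gamma*t).

``L_traj`` is the number of steps (length - 1), so a path that transitions
at every step has rate exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import numpy as np

from .trajectory import DiscreteTrajectory, PathEnsemble

__all__ = [
    "ObservableSpec",
    "pair_transition_rate",
    "nn_transition_rate",
    "symmetry_kappa",
    "half_occupancy",
    "theory_deviation_dn",
    "evaluate",
]

_KINDS = {
    "nn_transition_rate",
    "pair_transition_rate",
    "symmetry_kappa",
    "half_occupancy",
    "theory_deviation_dn",
    "custom",
}


@dataclass
class ObservableSpec:
    """Named observable with kind-specific parameters.

    ``params`` by kind:
      pair_transition_rate: ``pairs`` — iterable of unordered label pairs
      symmetry_kappa:       ``split`` — bin index separating the halves
      theory_deviation_dn:  ``n0, gamma, t_start, dt_window`` (+ optional
                            ``time_step`` overriding the trajectory dt)
      custom:               ``func`` — callable DiscreteTrajectory -> float
    """

    name: str
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown observable kind {self.kind!r}")
        required = {
            "pair_transition_rate": ["pairs"],
            "symmetry_kappa": ["split"],
            "half_occupancy": ["split"],
            "theory_deviation_dn": ["n0", "gamma", "t_start", "dt_window"],
            "custom": ["func"],
        }.get(self.kind, [])
        missing = [k for k in required if k not in self.params]
        if missing:
            raise ValueError(f"{self.kind} requires params {missing}")


def _normalize_pairs(pairs: Iterable) -> set:
    out = set()
    for p in pairs:
        a, b = p
        out.add((int(min(a, b)), int(max(a, b))))
    if not out:
        raise ValueError("pair set must be non-empty")
    return out


def pair_transition_rate(traj: DiscreteTrajectory, pairs: Iterable) -> float:
    """<N>: transitions between the listed unordered pairs, per step."""
    pset = _normalize_pairs(pairs)
    s = traj.states
    if len(s) < 2:
        raise ValueError("need at least 2 samples to count transitions")
    a, b = s[:-1], s[1:]
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    events = sum(np.sum((lo == p[0]) & (hi == p[1])) for p in pset)
    return float(events) / traj.n_steps


def nn_transition_rate(traj: DiscreteTrajectory) -> float:
    """<N>: fraction of steps that move by exactly one bin."""
    s = traj.states
    if len(s) < 2:
        raise ValueError("need at least 2 samples to count transitions")
    return float(np.sum(np.abs(np.diff(s)) == 1)) / traj.n_steps


def _occupancy_counts(data, n_bins: Optional[int] = None) -> np.ndarray:
    if isinstance(data, PathEnsemble):
        states = data.states_matrix().ravel()
        binning = data.trajectories[0].binning
    else:
        states = data.states
        binning = data.binning
    if n_bins is None:
        n_bins = binning.n_bins if binning is not None else int(states.max()) + 1
    return np.bincount(states, minlength=n_bins)


def symmetry_kappa(data, split: int) -> float:
    """Population ratio kappa = P(bin < split) / P(bin >= split).

    For an ensemble the counts are pooled over all paths.  The split is a
    clean disjoint partition (lower bins 0..split-1 vs upper bins split..).
    """
    counts = _occupancy_counts(data)
    if split <= 0 or split >= len(counts):
        raise ValueError(f"split {split} outside bin range 1..{len(counts)-1}")
    upper = counts[split:].sum()
    if upper == 0:
        raise ValueError("upper half unoccupied; kappa undefined")
    return float(counts[:split].sum()) / float(upper)


def half_occupancy(data, split: int) -> float:
    """Fraction of samples in bins below ``split``.

    The bounded reparametrization of kappa: f = kappa / (1 + kappa), so
    f = 0.5 is the symmetric point.  Because f is an occupancy *fraction*,
    the pooled kappa of a subset equals f_bar/(1 - f_bar) of the subset's
    mean fraction — the per-path ratio kappa has no such property (a ratio
    of sums is not a mean of ratios), which makes f the better-behaved
    constraint variable for population-symmetry targets on short paths.
    """
    counts = _occupancy_counts(data)
    if split <= 0 or split >= len(counts):
        raise ValueError(f"split {split} outside bin range 1..{len(counts)-1}")
    return float(counts[:split].sum()) / float(counts.sum())


def _photon_values(traj: DiscreteTrajectory) -> np.ndarray:
    if traj.binning is None:
        # integer labels are the photon numbers themselves
        return traj.states.astype(float)
    return traj.binning.midpoints[traj.states]


def _dn_single(
    traj: DiscreteTrajectory,
    n0: float,
    gamma: float,
    t_start: float,
    dt_window: float,
    time_step: Optional[float] = None,
) -> float:
    dt = time_step if time_step is not None else traj.dt
    times = dt * np.arange(len(traj))
    mask = (times >= t_start) & (times <= t_start + dt_window)
    if not np.any(mask):
        raise ValueError("window contains no samples")
    n = _photon_values(traj)[mask]
    theory = n0 * np.exp(-gamma * times[mask])
    return float(np.sum((n - theory) ** 2)) / dt_window


def theory_deviation_dn(
    ensemble: PathEnsemble,
    n0: float,
    gamma: float,
    t_start: float,
    dt_window: float,
    time_step: Optional[float] = None,
) -> float:
    """Total windowed squared deviation from the decay curve n0*exp(-gamma t).

    delta_n = (1/dt_window) * sum_paths sum_{t in window} (n_t - theory_t)^2.
    The per-path contributions (what enters resampling) are available through
    :func:`evaluate`; this returns their sum over the ensemble.
    """
    return float(sum(
        _dn_single(t, n0, gamma, t_start, dt_window, time_step)
        for t in ensemble
    ))


def evaluate(spec: ObservableSpec, ensemble: PathEnsemble) -> np.ndarray:
    """Per-path observable values s(Gamma_k); ensemble weights are ignored."""
    kind, p = spec.kind, spec.params
    if kind == "nn_transition_rate":
        fn: Callable[[DiscreteTrajectory], float] = nn_transition_rate
    elif kind == "pair_transition_rate":
        pairs = _normalize_pairs(p["pairs"])
        fn = lambda t: pair_transition_rate(t, pairs)  # noqa: E731
    elif kind == "symmetry_kappa":
        split = int(p["split"])
        fn = lambda t: symmetry_kappa(t, split)  # noqa: E731
    elif kind == "half_occupancy":
        split = int(p["split"])
        fn = lambda t: half_occupancy(t, split)  # noqa: E731
    elif kind == "theory_deviation_dn":
        fn = lambda t: _dn_single(  # noqa: E731
            t, p["n0"], p["gamma"], p["t_start"], p["dt_window"],
            p.get("time_step"))
    elif kind == "custom":
        fn = p["func"]
    else:  # pragma: no cover - guarded by ObservableSpec
        raise ValueError(f"unknown kind {kind!r}")
    return np.asarray([float(fn(t)) for t in ensemble])
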