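"""Data model, discretization and plain-text I/O for 1-D trajectories.

A trajectory is a one-dimensional time series of an order parameter (a
collective variable of a molecular system, a photon count of a cavity, a
Markov state label, ...).  Continuous series are discretized onto a uniform
(or user-supplied) grid of states; all downstream modules operate on the
integer state labels.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "BinningSpec",
    "DiscreteTrajectory",
    "PathEnsemble",
    "discretize",
    "undiscretize",
    "read_trajectory",
    "write_trajectory",
    "read_ensemble",
    "write_ensemble",
]


@dataclass(frozen=True)
class BinningSpec:
    """Uniform (or custom) partition of ``[lo, hi]`` into ``n_bins`` states.

    Binning is half-open, ``[edge_i, edge_{i+1})``; values below ``lo`` clamp
    to bin 0 and values at/above ``hi`` clamp to bin ``n_bins - 1``, so
    discretization is total, deterministic and monotone.
    """

    n_bins: int
    lo: float
    hi: float
    edges: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        if not (self.lo < self.hi):
            raise ValueError(f"need lo < hi, got lo={self.lo}, hi={self.hi}")
        if self.edges is None:
            edges = np.linspace(self.lo, self.hi, self.n_bins + 1)
        else:
            edges = np.asarray(self.edges, dtype=float)
            if edges.shape != (self.n_bins + 1,):
                raise ValueError("edges must have n_bins + 1 entries")
            if not np.all(np.diff(edges) > 0):
                raise ValueError("edges must be strictly increasing")
            if not (np.isclose(edges[0], self.lo) and np.isclose(edges[-1], self.hi)):
                raise ValueError("edges must span [lo, hi]")
        object.__setattr__(self, "edges", edges)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinningSpec):
            return NotImplemented
        return (
            self.n_bins == other.n_bins
            and np.allclose(self.edges, other.edges)
        )


@dataclass
class DiscreteTrajectory:
    """Integer state-label time series with optional binning metadata.

    ``dt`` is the sampling interval (arbitrary units; metadata only).
    """

    states: np.ndarray
    dt: float = 1.0
    binning: Optional[BinningSpec] = None

    def __post_init__(self) -> None:
        states = np.asarray(self.states)
        if states.ndim != 1 or states.size < 1:
            raise ValueError("states must be a non-empty 1-D sequence")
        if not np.issubdtype(states.dtype, np.integer):
            if not np.all(states == np.floor(states)):
                raise ValueError("states must be integer labels")
            states = states.astype(np.int64)
        if states.min() < 0:
            raise ValueError("state labels must be >= 0")
        if self.binning is not None and states.max() >= self.binning.n_bins:
            raise ValueError(
                f"label {states.max()} out of range for {self.binning.n_bins} bins"
            )
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.states = states.astype(np.int64)

    def __len__(self) -> int:
        return len(self.states)

    @property
    def n_steps(self) -> int:
        """Number of transitions (length - 1)."""
        return len(self.states) - 1

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(len(self.states))

    def values(self) -> np.ndarray:
        """Continuous representation via bin midpoints (requires binning)."""
        return undiscretize(self)


@dataclass
class PathEnsemble:
    """A set of equal-length discrete trajectories, optionally weighted."""

    trajectories: list
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise ValueError("ensemble must contain at least one trajectory")
        lengths = {len(t) for t in self.trajectories}
        if len(lengths) != 1:
            raise ValueError(f"trajectories must have equal length, got {sorted(lengths)}")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(self.trajectories),):
                raise ValueError("one weight per trajectory required")
            if np.any(w < 0):
                raise ValueError("weights must be nonnegative")
            if w.sum() <= 0:
                raise ValueError("weights must have positive sum")
            self.weights = w

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def __getitem__(self, i: int) -> DiscreteTrajectory:
        return self.trajectories[i]

    @property
    def n_paths(self) -> int:
        return len(self.trajectories)

    @property
    def length(self) -> int:
        return len(self.trajectories[0])

    def states_matrix(self) -> np.ndarray:
        """(n_paths, length) array of state labels."""
        return np.stack([t.states for t in self.trajectories])

    def normalized_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.full(self.n_paths, 1.0 / self.n_paths)
        return self.weights / self.weights.sum()


def discretize(
    series: Sequence[float],
    spec: BinningSpec,
    dt: float = 1.0,
    return_clamp_counts: bool = False,
):
    """Map a real-valued series onto integer bin labels.

    Values below ``spec.lo`` clamp to bin 0; values at/above ``spec.hi``
    clamp to the top bin.  Clamp counts are logged (and returned on request).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("series must be a non-empty 1-D sequence")
    bad = np.flatnonzero(~np.isfinite(x))
    if bad.size:
        raise ValueError(f"non-finite value in series at index {bad[0]}")
    labels = np.searchsorted(spec.edges, x, side="right") - 1
    n_low = int(np.sum(labels < 0))
    n_high = int(np.sum(labels > spec.n_bins - 1))
    # values exactly at hi land in the (virtual) bin n_bins; clamp them too
    labels = np.clip(labels, 0, spec.n_bins - 1)
    if n_low or n_high:
        logger.info("discretize: clamped %d low / %d high values", n_low, n_high)
    traj = DiscreteTrajectory(states=labels, dt=dt, binning=spec)
    if return_clamp_counts:
        return traj, (n_low, n_high)
    return traj


def undiscretize(traj: DiscreteTrajectory) -> np.ndarray:
    """Map labels back to bin midpoints."""
    if traj.binning is None:
        raise ValueError("trajectory has no BinningSpec; cannot undiscretize")
    return traj.binning.midpoints[traj.states]


# ---------------------------------------------------------------------------
# Plain-text I/O.  One value per line (or per CSV cell); metadata in
# '#'-prefixed 'key=value' header comments.
# ---------------------------------------------------------------------------

def _metadata_header(dt: float, binning: Optional[BinningSpec]) -> list:
    lines = [f"# dt={dt!r}"]
    if binning is not None:
        lines.append(f"# n_bins={binning.n_bins}")
        lines.append(f"# lo={binning.lo!r}")
        lines.append(f"# hi={binning.hi!r}")
    return lines


def _parse_metadata(lines: list) -> dict:
    meta = {}
    for ln in lines:
        body = ln.lstrip("#").strip()
        if "=" in body:
            key, _, val = body.partition("=")
            meta[key.strip()] = val.strip()
    return meta


def write_trajectory(
    traj: Union[DiscreteTrajectory, Sequence[float]],
    path: Union[str, Path],
    fmt: str = "csv",
) -> None:
    """Write a trajectory as one value per line with a metadata header."""
    if fmt not in {"csv", "tsv", "txt"}:
        raise ValueError(f"unsupported format {fmt!r}")
    path = Path(path)
    if isinstance(traj, DiscreteTrajectory):
        header = _metadata_header(traj.dt, traj.binning)
        body = [str(int(s)) for s in traj.states]
    else:
        header = _metadata_header(1.0, None)
        body = [repr(float(v)) for v in np.asarray(traj, dtype=float)]
    path.write_text("\n".join(header + body) + "\n")


def read_trajectory(path: Union[str, Path]):
    """Read a one-column trajectory file.

    Returns a :class:`DiscreteTrajectory` when every token is an integer,
    otherwise a float array.  Malformed lines raise with their line number.
    """
    path = Path(path)
    meta_lines, tokens = [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            meta_lines.append(line)
            continue
        cells = [c for c in line.replace("\t", ",").split(",") if c.strip()]
        if len(cells) != 1:
            raise ValueError(f"{path}:{lineno}: expected one column, got {len(cells)}")
        tokens.append((lineno, cells[0].strip()))
    meta = _parse_metadata(meta_lines)
    values = []
    is_int = True
    for lineno, tok in tokens:
        try:
            values.append(float(tok))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric token {tok!r}") from exc
        if "." in tok or "e" in tok.lower():
            is_int = False
    dt = float(meta.get("dt", 1.0))
    binning = None
    if "n_bins" in meta:
        binning = BinningSpec(int(meta["n_bins"]), float(meta["lo"]), float(meta["hi"]))
    arr = np.asarray(values)
    if is_int and arr.size and np.all(arr == np.floor(arr)):
        return DiscreteTrajectory(states=arr.astype(np.int64), dt=dt, binning=binning)
    return arr


def write_ensemble(ens: PathEnsemble, path: Union[str, Path]) -> None:
    """Write an ensemble as a single wide CSV, one column per path.

    If ``path`` is an existing directory (or has no suffix), one CSV per
    trajectory is written into it instead (``path_000.csv``, ...).
    """
    path = Path(path)
    if path.is_dir() or path.suffix == "":
        path.mkdir(parents=True, exist_ok=True)
        for i, traj in enumerate(ens.trajectories):
            write_trajectory(traj, path / f"path_{i:03d}.csv")
        return
    t0 = ens.trajectories[0]
    lines = _metadata_header(t0.dt, t0.binning)
    lines.append(f"# n_paths={ens.n_paths}")
    if ens.weights is not None:
        lines.append("# weights=" + ",".join(repr(float(w)) for w in ens.weights))
    mat = ens.states_matrix()  # (K, T)
    for row in mat.T:
        lines.append(",".join(str(int(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_ensemble(path: Union[str, Path]) -> PathEnsemble:
    """Read an ensemble: a wide CSV, or a directory of one-column CSVs."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.csv"))
        if not files:
            raise ValueError(f"{path}: no CSV trajectories found")
        trajs = [read_trajectory(f) for f in files]
        if any(not isinstance(t, DiscreteTrajectory) for t in trajs):
            raise ValueError(f"{path}: ensemble directories must hold "
                             "integer-label trajectories")
        return PathEnsemble(trajectories=trajs)
    meta_lines, rows = [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            meta_lines.append(line)
            continue
        cells = line.split(",")
        try:
            rows.append([int(c) for c in cells])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer token") from exc
    if not rows:
        raise ValueError(f"{path}: empty ensemble file")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows, widths {sorted(widths)}")
    meta = _parse_metadata(meta_lines)
    dt = float(meta.get("dt", 1.0))
    binning = None
    if "n_bins" in meta:
        binning = BinningSpec(int(meta["n_bins"]), float(meta["lo"]), float(meta["hi"]))
    mat = np.asarray(rows).T  # (K, T)
    trajs = [DiscreteTrajectory(states=row, dt=dt, binning=binning) for row in mat]
    weights = None
    if "weights" in meta:
        weights = np.asarray([float(w) for w in meta["weights"].split(",")])
    return PathEnsemble(trajectories=trajs, weights=weights)
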