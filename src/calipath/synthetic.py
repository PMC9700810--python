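"""Synthetic trajectory generators for the three benchmark systems.

Every downstream stage (sequence-model training, Maximum-Caliber
resampling, kernel oracles) is exercised on data produced here, so each
generator documents its exact update rule and is seed-deterministic:

* :func:`simulate_markov` — exact ancestral sampling from a discrete-time
  transition kernel (the 3-state benchmark).
* :func:`simulate_double_well` — a discrete-state Metropolis walk on an
  asymmetric bistable free-energy profile.  This is a surrogate for the
  slow two-well order-parameter dynamics of a helix-inverting peptide
  (left/right helicity coordinate): detailed balance holds exactly, the
  equilibrium population ratio of the two halves is controlled analytically
  by the well asymmetry (kappa ~ exp(-asymmetry)), and the
  nearest-neighbour transition rate is controlled by the proposal rate.
* :func:`simulate_quantum_jump` — Monte-Carlo wavefunction trajectories of
  a two-level atom coupled to a leaky single-mode cavity
  (H = w1 a†a + w2 s+s- + g(s- a† + a s+), single photon-loss channel
  sqrt(gamma) a), recorded as discretized photon-number time series;
  :func:`lindblad_mean` integrates the corresponding Lindblad master
  equation densely as the deterministic oracle for the ensemble mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.linalg import expm

from .trajectory import BinningSpec, DiscreteTrajectory, PathEnsemble, discretize
from .markov import TransitionKernel

__all__ = [
    "DoubleWellSpec",
    "QuantumJumpSpec",
    "simulate_markov",
    "double_well_profile",
    "simulate_double_well",
    "simulate_quantum_jump",
    "lindblad_mean",
]


# ---------------------------------------------------------------------------
# Markov chain
# ---------------------------------------------------------------------------

def simulate_markov(
    kernel: TransitionKernel,
    length: int,
    init: Union[int, Sequence[float]],
    seed: int,
) -> DiscreteTrajectory:
    """Exact ancestral sampling: s_{t+1} ~ P[s_t, :]."""
    if length < 2:
        raise ValueError("length must be >= 2")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(kernel.matrix, axis=1)
    cum[:, -1] = 1.0
    if np.isscalar(init):
        s0 = int(init)
    else:
        s0 = int(np.searchsorted(np.cumsum(init), rng.random()))
    u = rng.random(length - 1)
    states = np.empty(length, dtype=np.int64)
    states[0] = s0
    s = s0
    for t in range(length - 1):
        s = int(np.searchsorted(cum[s], u[t], side="right"))
        states[t + 1] = s
    return DiscreteTrajectory(states=states)


# ---------------------------------------------------------------------------
# Bistable order parameter (Metropolis walk)
# ---------------------------------------------------------------------------

@dataclass
class DoubleWellSpec:
    """Asymmetric double-well Metropolis walk.

    The discrete free-energy profile over ``n_bins`` states is

        F_i = barrier * ((2 i/(n-1) - 1)^2 - 1)^2 + asymmetry * [i < n/2]

    (kT units): a quartic with minima at both ends of the range and a
    barrier of height ``barrier`` in the middle; the left half is raised by
    ``asymmetry``, so the equilibrium population ratio kappa of lower to
    upper half is ~ exp(-asymmetry).  At each step, with probability
    ``diffusion`` a symmetric move of 1..``max_hop`` bins is proposed (hop
    size k drawn with weight ``hop_weights[k-1]``, direction uniform,
    rejected outside the range) and accepted with the Metropolis rule
    min(1, exp(-(F_new - F_old))), which satisfies detailed balance;
    otherwise the walker stays put.  Multi-bin hops emulate the several-bin
    frame-to-frame motion of a real projected order parameter and set the
    well-to-well mixing time; the nearest-neighbour transition rate is
    diffusion * hop_weights[0] * <acceptance>.

    Defaults give kappa ~ 0.5 (asymmetry ln 2) and a nearest-neighbour rate
    ~ 0.4, the regime of the helicity-coordinate experiments; the order
    parameter spans [x_lo, x_hi] and continuous output adds sub-bin jitter.
    """

    n_bins: int = 32
    asymmetry: float = float(np.log(2.0))
    barrier: float = 1.5
    diffusion: float = 0.75
    length: int = 20000
    seed: int = 0
    x_lo: float = -15.0
    x_hi: float = 15.0
    max_hop: int = 3
    hop_weights: tuple = (0.6, 0.25, 0.15)

    def __post_init__(self) -> None:
        if self.barrier <= 0:
            raise ValueError("barrier must be > 0")
        if self.n_bins < 4:
            raise ValueError("n_bins must be >= 4")
        if not (0 < self.diffusion <= 1):
            raise ValueError("diffusion must lie in (0, 1]")
        if self.length < 2:
            raise ValueError("length must be >= 2")
        if len(self.hop_weights) != self.max_hop or min(self.hop_weights) <= 0:
            raise ValueError("hop_weights must give a positive weight per hop size")

    @property
    def binning(self) -> BinningSpec:
        return BinningSpec(self.n_bins, self.x_lo, self.x_hi)


def double_well_profile(spec: DoubleWellSpec) -> np.ndarray:
    """F_i (kT units) of the generator's discrete potential."""
    n = spec.n_bins
    u = 2.0 * np.arange(n) / (n - 1) - 1.0
    F = spec.barrier * (u * u - 1.0) ** 2
    F[: n // 2] += spec.asymmetry
    return F


def simulate_double_well(
    spec: DoubleWellSpec,
    init_bin: Optional[int] = None,
    return_states: bool = False,
):
    """Metropolis walk on the double-well profile.

    Returns a continuous order-parameter series (bin midpoint plus uniform
    sub-bin jitter so discretization recovers the walk exactly); with
    ``return_states=True`` the raw :class:`DiscreteTrajectory` instead.
    Walks start at the barrier top (middle bin) by default, so a fresh
    trajectory commits stochastically to one of the wells.
    """
    rng = np.random.default_rng(spec.seed)
    F = double_well_profile(spec)
    n = spec.n_bins
    s = n // 2 if init_bin is None else int(init_bin)
    if not (0 <= s < n):
        raise ValueError("init_bin out of range")
    u_move = rng.random(spec.length - 1)
    u_dir = rng.random(spec.length - 1)
    u_acc = rng.random(spec.length - 1)
    hw = np.asarray(spec.hop_weights, dtype=float)
    hops = 1 + rng.choice(spec.max_hop, size=spec.length - 1, p=hw / hw.sum())
    states = np.empty(spec.length, dtype=np.int64)
    states[0] = s
    for t in range(spec.length - 1):
        if u_move[t] < spec.diffusion:
            prop = s + (hops[t] if u_dir[t] < 0.5 else -hops[t])
            if 0 <= prop < n and u_acc[t] < np.exp(-(F[prop] - F[s])):
                s = prop
        states[t + 1] = s
    traj = DiscreteTrajectory(states=states, dt=1.0, binning=spec.binning)
    if return_states:
        return traj
    mid = spec.binning.midpoints[states]
    width = (spec.x_hi - spec.x_lo) / n
    return mid + width * rng.uniform(-0.45, 0.45, size=spec.length)


# ---------------------------------------------------------------------------
# Open quantum system (Monte-Carlo wavefunction + Lindblad oracle)
# ---------------------------------------------------------------------------

@dataclass
class QuantumJumpSpec:
    """Two-level atom in a leaky single-mode cavity.

    H_sys = omega1 a†a + omega2 s+s- + g (s- a† + a s+), one dissipation
    channel sqrt(gamma) a (photon emission).  The initial state is
    |n_photons_init> (x) |up>.  ``hilbert_cutoff`` counts photon levels
    0..cutoff-1; the default 9 makes the truncation exact for the default
    initial state (the excitation-conserving coupling reaches level
    n_photons_init + 1 and photon loss only moves down).  Angular
    frequencies default to 2*pi and g to pi/2 (natural units, hbar = 1).
    """

    n_photons_init: int = 7
    omega1: float = 2.0 * np.pi
    omega2: float = 2.0 * np.pi
    g: float = np.pi / 2.0
    gamma: float = 0.1
    t_max: float = 20.0
    dt: float = 0.005
    sample_dt: float = 0.1
    hilbert_cutoff: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.hilbert_cutoff <= self.n_photons_init:
            raise ValueError("hilbert_cutoff must exceed n_photons_init")
        if self.dt <= 0 or self.sample_dt < self.dt:
            raise ValueError("need 0 < dt <= sample_dt")
        if self.gamma * self.n_photons_init * self.dt >= 0.1:
            raise ValueError("dt too coarse: gamma*<n>*dt must stay below 0.1")

    @property
    def dim(self) -> int:
        return 2 * self.hilbert_cutoff

    def operators(self) -> dict:
        """Dense operators on the (photon ⊗ spin) product space."""
        nc = self.hilbert_cutoff
        a_ph = np.diag(np.sqrt(np.arange(1, nc)), k=1)
        i_ph = np.eye(nc)
        sm = np.array([[0.0, 0.0], [1.0, 0.0]])  # |down><up| with up = index 0
        i_sp = np.eye(2)
        a = np.kron(a_ph, i_sp)
        sminus = np.kron(i_ph, sm)
        num = a.conj().T @ a
        spsm = sminus.conj().T @ sminus
        h_sys = (self.omega1 * num + self.omega2 * spsm
                 + self.g * (sminus @ a.conj().T + a @ sminus.conj().T))
        return {"a": a, "n": num, "spsm": spsm, "H": h_sys}

    def initial_state(self) -> np.ndarray:
        psi = np.zeros(self.dim, dtype=complex)
        psi[2 * self.n_photons_init] = 1.0  # photon n0, spin up (index 0)
        return psi

    def default_binning(self) -> BinningSpec:
        return BinningSpec(20, 0.0, float(self.n_photons_init))

    @property
    def sample_times(self) -> np.ndarray:
        stride = int(round(self.sample_dt / self.dt))
        n_steps = int(round(self.t_max / self.dt))
        return self.dt * np.arange(0, n_steps + 1, stride)


def simulate_quantum_jump(
    spec: QuantumJumpSpec,
    n_paths: int,
    seed: Optional[int] = None,
    binning: Optional[BinningSpec] = None,
    return_raw: bool = False,
):
    """Monte-Carlo wavefunction trajectories of the cavity photon number.

    Each path evolves under the non-Hermitian H_eff = H_sys - i(gamma/2)a†a
    via the exact step propagator expm(-i H_eff dt); the squared norm decays
    and, when it falls below a uniformly drawn threshold, a photon-emission
    jump a|psi>/||a|psi>|| is applied and the threshold redrawn (the
    standard waiting-time unravelling of the Lindblad equation, jump times
    resolved to dt).  The expectation <a†a> is recorded every ``sample_dt``
    and discretized per ``binning`` (default: 20 bins over
    [0, n_photons_init]).

    Returns a :class:`PathEnsemble`, or ``(times, values)`` raw arrays with
    ``return_raw=True``.
    """
    if n_paths <= 0:
        raise ValueError("n_paths must be positive")
    ops = spec.operators()
    h_eff = ops["H"] - 0.5j * spec.gamma * ops["n"]
    u_step = expm(-1j * h_eff * spec.dt)
    a_op = ops["a"]
    diag_n = np.real(np.diag(ops["n"]))

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    psi = np.tile(spec.initial_state(), (n_paths, 1))
    thresholds = rng.random(n_paths)

    stride = int(round(spec.sample_dt / spec.dt))
    n_steps = int(round(spec.t_max / spec.dt))
    times = spec.dt * np.arange(0, n_steps + 1, stride)
    values = np.empty((n_paths, len(times)))

    def record(col: int) -> None:
        norm2 = np.einsum("ij,ij->i", psi.conj(), psi).real
        nexp = np.einsum("ij,j,ij->i", psi.conj(), diag_n, psi).real
        values[:, col] = nexp / norm2

    record(0)
    col = 1
    top_pop = 0.0
    ut = u_step.T
    for step in range(1, n_steps + 1):
        psi = psi @ ut
        norm2 = np.einsum("ij,ij->i", psi.conj(), psi).real
        jump = norm2 < thresholds
        if np.any(jump):
            phi = psi[jump] @ a_op.T
            nrm = np.sqrt(np.einsum("ij,ij->i", phi.conj(), phi).real)
            nrm[nrm == 0] = 1.0  # vacuum cannot emit; leave state untouched
            psi[jump] = phi / nrm[:, None]
            thresholds[jump] = rng.random(int(jump.sum()))
        if step % stride == 0:
            # |top photon, atom excited> is the only component whose coupling
            # would leave the truncated space
            top = np.abs(psi[:, -2]) ** 2
            top_pop = max(top_pop, float(
                (top / np.einsum("ij,ij->i", psi.conj(), psi).real).max()))
            record(col)
            col += 1
    if top_pop > 1e-6:
        warnings.warn(
            f"population {top_pop:.2e} at the top photon level; "
            "increase hilbert_cutoff")
    if return_raw:
        return times, values
    b = binning or spec.default_binning()
    trajs = [discretize(row, b, dt=spec.sample_dt) for row in values]
    return PathEnsemble(trajectories=trajs)


def lindblad_mean(
    spec: QuantumJumpSpec,
    check_positivity: bool = False,
) -> Tuple[np.ndarray, np.ndarray]:
    """Deterministic <a†a>(t) from dense Lindblad integration.

    The density matrix is propagated with the exact superoperator
    exponential per sample interval,
    L[rho] = -i[H, rho] + gamma (a rho a† - {a†a, rho}/2); trace
    preservation is checked to 1e-8 at every sample.  Returns
    ``(times, n_mean)``.
    """
    d = spec.dim
    if d > 64:
        raise ValueError("dense Lindblad oracle limited to Hilbert dimension 64")
    ops = spec.operators()
    H, a, num = ops["H"], ops["a"], ops["n"]
    eye = np.eye(d)
    ad = a.conj().T
    ada = num
    liou = (-1j * (np.kron(H, eye) - np.kron(eye, H.T))
            + spec.gamma * (np.kron(a, a.conj())
                            - 0.5 * np.kron(ada, eye)
                            - 0.5 * np.kron(eye, ada.T)))
    prop = expm(liou * spec.sample_dt)
    psi0 = spec.initial_state()
    rho = np.outer(psi0, psi0.conj())
    times = spec.sample_times
    means = np.empty(len(times))
    vec = rho.reshape(-1)
    for i, _t in enumerate(times):
        if i > 0:
            vec = prop @ vec
        rho = vec.reshape(d, d)
        tr = np.trace(rho).real
        if abs(tr - 1.0) > 1e-6:
            raise RuntimeError(
                f"trace drift {abs(tr-1):.2e}; reduce sample_dt")
        if check_positivity:
            herm = 0.5 * (rho + rho.conj().T)
            if np.abs(rho - herm).max() > 1e-8:
                raise RuntimeError("density matrix lost hermiticity")
            if np.linalg.eigvalsh(herm).min() < -1e-8:
                raise RuntimeError("density matrix lost positivity")
        means[i] = np.trace(rho @ num).real / tr
    return times, means
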