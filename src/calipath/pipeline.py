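"""End-to-end orchestration: configuration, the full constrained-retraining
workflow, and ensemble comparison reports.

The full run mirrors the method's workflow: load or simulate a 1-D time
series -> discretize -> train the unconstrained sequence model -> generate
many paths -> evaluate the constrained observables -> solve the
Maximum-Caliber multipliers -> biased subsample -> retrain -> verify.  Every
random stream takes its own named seed derived from a single master seed,
so a run is fully determined by its config.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from . import maxcal, model as _model, observables as obs
from .markov import estimate_kernel, eigenspectrum
from .synthetic import (DoubleWellSpec, QuantumJumpSpec, simulate_double_well,
                        simulate_markov, simulate_quantum_jump)
from .markov import TransitionKernel, default_three_state_kernel
from .trajectory import (BinningSpec, DiscreteTrajectory, PathEnsemble,
                         discretize, read_trajectory, write_ensemble)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunSummary", "run_ps_lstm", "compare_ensembles",
           "mean_transition_times"]


class BinningConfig(BaseModel):
    n_bins: int = 32
    lo: float = -15.0
    hi: float = 15.0

    def build(self) -> BinningSpec:
        return BinningSpec(self.n_bins, self.lo, self.hi)


class GeneratorConfig(BaseModel):
    """Synthetic input in lieu of a trajectory file."""

    system: str  # markov3 | doublewell | qjump
    params: dict = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_system(self):
        if self.system not in {"markov3", "doublewell", "qjump"}:
            raise ValueError(f"unknown generator system {self.system!r}")
        return self


class ObservableConfig(BaseModel):
    kind: str
    name: Optional[str] = None
    params: dict = Field(default_factory=dict)

    def build(self) -> obs.ObservableSpec:
        return obs.ObservableSpec(
            name=self.name or self.kind, kind=self.kind, params=dict(self.params))


class ConstraintConfig(BaseModel):
    observable: ObservableConfig
    target: Optional[float] = None
    target_quantile: Optional[float] = None
    tolerance: float = 0.02

    def build(self) -> maxcal.ConstraintTarget:
        return maxcal.ConstraintTarget(
            observable=self.observable.build(),
            target=self.target,
            target_quantile=self.target_quantile,
            tolerance=self.tolerance,
        )


class ModelSection(BaseModel):
    embed_dim: int = 8
    hidden_dim: int = 64
    n_layers: int = 1
    learning_rate: float = 1e-3
    batch_len: int = 100
    epochs: int = 40
    batch_size: int = 32


class RunSummary(BaseModel):
    """Schema of the machine-readable summary a full run writes."""

    n_states: int
    delta_lambda: List[float]
    targets: List[float]
    achieved_reweighted: List[float]
    ess: float
    occupancy: List[float]
    kernel: Optional[List[List[float]]] = None
    eigenvalue_moduli: Optional[List[float]] = None
    achieved_final: Optional[List[float]] = None
    error_percent: Optional[List[float]] = None


class RunConfig(BaseModel):
    """Validated configuration of a full constrained-retraining run."""

    input_file: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    binning: BinningConfig = Field(default_factory=BinningConfig)
    model: ModelSection = Field(default_factory=ModelSection)
    constraints: List[ConstraintConfig] = Field(default_factory=list)
    n_generate: int = 200
    subset_size: int = 10
    gen_length: Optional[int] = None
    init: Optional[int] = None
    seed: int = 0
    outdir: Optional[str] = None

    @model_validator(mode="after")
    def _check_source(self):
        if (self.input_file is None) == (self.generator is None):
            raise ValueError("exactly one of input_file / generator is required")
        if self.input_file is not None and not Path(self.input_file).exists():
            raise ValueError(f"input file not found: {self.input_file}")
        return self

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _load_input(config: RunConfig, seed: int) -> DiscreteTrajectory:
    binning = config.binning.build()
    if config.input_file is not None:
        data = read_trajectory(config.input_file)
        if isinstance(data, DiscreteTrajectory):
            return data
        return discretize(data, binning)
    gen = config.generator
    params = dict(gen.params)
    if gen.system == "markov3":
        kernel = default_three_state_kernel()
        if "kernel_csv" in params:
            kernel = TransitionKernel.from_csv(params.pop("kernel_csv"))
        length = int(params.pop("length", 10000))
        init = params.pop("init", 0)
        return simulate_markov(kernel, length, init, seed=seed)
    if gen.system == "doublewell":
        spec = DoubleWellSpec(**{**params, "seed": seed})
        series = simulate_double_well(spec)
        return discretize(series, spec.binning)
    if gen.system == "qjump":
        spec = QuantumJumpSpec(**{**params, "seed": seed})
        ens = simulate_quantum_jump(spec, n_paths=1)
        return ens.trajectories[0]
    raise AssertionError("unreachable")


def run_ps_lstm(config: RunConfig) -> dict:
    """Execute the full workflow; returns (and optionally writes) a report.

    The report is deterministic given the config (timestamps excluded from
    the summary payload itself).
    """
    t0 = time.time()
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)
    report: dict = {"seed": config.seed, "stages": []}

    def stage(name: str, start: float) -> None:
        entry = {"stage": name, "wall_s": round(time.time() - start, 3)}
        report["stages"].append(entry)
        logger.info("stage %s done in %.2fs", name, entry["wall_s"])

    s = time.time()
    traj = _load_input(config, seed=int(seeds[0]))
    stage("input", s)
    n_states = traj.binning.n_bins if traj.binning else int(traj.states.max()) + 1

    s = time.time()
    cfg = _model.ModelConfig(n_states=n_states, seed=int(seeds[1]),
                             **config.model.model_dump())
    base_model = _model.train(traj, cfg)
    stage("train", s)
    report["training_loss"] = [base_model.training_loss_history[0],
                               base_model.training_loss_history[-1]]

    length = config.gen_length or len(traj)
    init = config.init if config.init is not None else int(traj.states[0])
    constraints = [c.build() for c in config.constraints]

    s = time.time()
    new_model, solution, subset = maxcal.constrain_pipeline(
        base_model, constraints,
        n_generate=config.n_generate, subset_size=config.subset_size,
        length=length, init=init, seed=int(seeds[2]))
    stage("constrain", s)

    s = time.time()
    final_ens = _model.generate(new_model, config.subset_size, length, init,
                                seed=int(seeds[3]))
    stage("generate_final", s)

    summary = {
        "n_states": n_states,
        "delta_lambda": solution.delta_lambda.tolist(),
        "targets": solution.targets.tolist(),
        "achieved_reweighted": solution.achieved.tolist(),
        "ess": solution.ess,
    }
    if "verified" in solution.diagnostics:
        v = solution.diagnostics["verified"]
        summary["achieved_final"] = list(map(float, v))
        summary["error_percent"] = [
            100.0 * abs(a - t) / max(abs(t), 1e-12)
            for a, t in zip(v, solution.targets)
        ]
    occ = np.bincount(final_ens.states_matrix().ravel(), minlength=n_states)
    summary["occupancy"] = (occ / occ.sum()).tolist()
    try:
        kern = estimate_kernel(final_ens, n_states=n_states)
        summary["kernel"] = kern.matrix.tolist()
        vals, _ts = eigenspectrum(kern)
        summary["eigenvalue_moduli"] = np.abs(vals).tolist()
    except ValueError:
        summary["kernel"] = None
    summary = RunSummary(**summary).model_dump()  # schema check before writing
    report["summary"] = summary
    report["wall_s_total"] = round(time.time() - t0, 3)

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        base_model.save(out / "model_unconstrained.npz")
        new_model.save(out / "model_constrained.npz")
        write_ensemble(subset, out / "subset.csv")
        write_ensemble(final_ens, out / "final_ensemble.csv")
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return report


# ---------------------------------------------------------------------------
# Ensemble comparison
# ---------------------------------------------------------------------------

def mean_transition_times(
    traj: DiscreteTrajectory,
    macro_a: Sequence[int],
    macro_b: Sequence[int],
):
    """Mean entry-to-entry times between two macrostates, in units of dt.

    Scanning the path, each first entry into B after visiting A closes an
    A->B event whose duration is counted from the most recent entry into A
    (and symmetrically for B->A).  Returns ``(tau_ab, tau_ba, n_ab, n_ba)``
    with NaN for unobserved directions.
    """
    a_set, b_set = set(map(int, macro_a)), set(map(int, macro_b))
    if a_set & b_set:
        raise ValueError("macrostates must be disjoint")
    side = None
    anchor = 0
    durations = {"ab": [], "ba": []}
    for t, s in enumerate(traj.states):
        s = int(s)
        if s in a_set:
            if side == "b":
                durations["ba"].append(t - anchor)
            if side != "a":
                side, anchor = "a", t
        elif s in b_set:
            if side == "a":
                durations["ab"].append(t - anchor)
            if side != "b":
                side, anchor = "b", t
    tau_ab = float(np.mean(durations["ab"]) * traj.dt) if durations["ab"] else float("nan")
    tau_ba = float(np.mean(durations["ba"]) * traj.dt) if durations["ba"] else float("nan")
    return tau_ab, tau_ba, len(durations["ab"]), len(durations["ba"])


def compare_ensembles(
    a: PathEnsemble,
    b: PathEnsemble,
    observable_specs: Sequence[obs.ObservableSpec],
    macrostates: Optional[tuple] = None,
) -> dict:
    """Side-by-side report of two ensembles.

    Per observable: mean and standard error on each side plus difference.
    Occupancy histograms, counting-estimated kernels, and (if two
    macrostates are named as bin-label collections) mean entry-to-entry
    transition times.
    """
    bin_a = a.trajectories[0].binning
    bin_b = b.trajectories[0].binning
    if bin_a is not None and bin_b is not None and bin_a != bin_b:
        raise ValueError("ensembles have incompatible binning")

    def side(ens: PathEnsemble) -> dict:
        n_states = (ens.trajectories[0].binning.n_bins
                    if ens.trajectories[0].binning else
                    int(ens.states_matrix().max()) + 1)
        occ = np.bincount(ens.states_matrix().ravel(), minlength=n_states)
        d = {
            "n_paths": ens.n_paths,
            "length": ens.length,
            "ess": maxcal.effective_sample_size(ens.normalized_weights()),
            "occupancy": (occ / occ.sum()).tolist(),
        }
        try:
            d["kernel"] = estimate_kernel(ens, n_states=n_states).matrix.tolist()
        except ValueError:
            d["kernel"] = None
        return d

    report = {"a": side(a), "b": side(b), "observables": {}}
    for spec in observable_specs:
        va, vb = obs.evaluate(spec, a), obs.evaluate(spec, b)
        ma, mb = float(np.mean(va)), float(np.mean(vb))
        report["observables"][spec.name] = {
            "a_mean": ma,
            "a_se": float(np.std(va, ddof=1) / np.sqrt(len(va))) if len(va) > 1 else 0.0,
            "b_mean": mb,
            "b_se": float(np.std(vb, ddof=1) / np.sqrt(len(vb))) if len(vb) > 1 else 0.0,
            "difference": mb - ma,
        }
    if macrostates is not None:
        ma_bins, mb_bins = macrostates
        for label, ens in (("a", a), ("b", b)):
            taus = [mean_transition_times(t, ma_bins, mb_bins) for t in ens]
            ab = [t[0] for t in taus if np.isfinite(t[0])]
            ba = [t[1] for t in taus if np.isfinite(t[1])]
            report[label]["tau_ab"] = float(np.mean(ab)) if ab else float("nan")
            report[label]["tau_ba"] = float(np.mean(ba)) if ba else float("nan")
            report[label]["n_transitions"] = int(sum(t[2] + t[3] for t in taus))
    return report
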