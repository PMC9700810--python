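# calipath

Maximum-Caliber path sampling of recurrent generative models for
one-dimensional molecular and quantum time series.

## The problem

A recurrent sequence model trained on a discretized 1-D time series — a
collective variable of a peptide, the photon count of a leaky cavity, a
Markov state label — learns the *path probability* P(Γ) of the process and
can generate arbitrarily many statistically faithful copies of the
trajectory.  But it also faithfully reproduces every defect of its training
data: under-sampled equilibria, force-field bias, the wrong dissipation
rate.  `calipath` corrects the generated ensemble with prior knowledge
expressed as ensemble-averaged constraints, without ever modifying the loss
function or the architecture.

The machinery is the principle of Maximum Caliber, the path-space analogue
of maximum entropy.  Given a reference path ensemble with probability
P^A(Γ) and a constraint ⟨s(Γ)⟩ = s̄^B on some static or dynamical path
functional s, the closest constrained ensemble is the exponential tilt

    P^B(Γ) ∝ exp(−Δλ · s(Γ)) · P^A(Γ),

where Δλ solves the self-normalized reweighted-average equation over a
sample {Γ_k} drawn from P^A:

    s̄^B = Σ_k s(Γ_k) e^{−Δλ s(Γ_k)} / Σ_k e^{−Δλ s(Γ_k)}.

The workflow is: train a model on the observed series → generate many
paths → solve Δλ → subsample a small subset with probability ∝ the tilted
weights → retrain a fresh model on that subset.  The retrained
("path-sampled") model generates trajectories satisfying the constraint.
Everything — the left-hand side being strictly decreasing in Δλ, the
closed-form tilted Markov kernel p^B_mn ∝ e^{−Δλ·1[(m,n) counted]} p^A_mn,
exact small-system path enumeration — is checked against analytic
Markov-chain oracles shipped in the package.

Supported constraint functionals include pair/nearest-neighbour transition
rates ⟨N⟩ (a diffusivity-like kinetic observable), the two-well population
ratio κ (and its bounded reparametrization, the half-occupancy fraction),
and the windowed squared deviation δn from a classical photon-decay curve
n₀e^{−γt} — plus arbitrary user callables.

## Worked example

Raise the transition rate of a slow 3-state hopping chain.  The shipped
benchmark kernel has an unconstrained {0,1}/{1,2} transition rate of
⟨N⟩ ≈ 0.089; we ask the path-sampled model for ⟨N⟩ = 0.13:

```python
from calipath.benchmarks import three_state_constraint_run

run = three_state_constraint_run(seed=1, target=0.13)
print(f"unconstrained <N>  {run['unconstrained_rate']:.4f}")
print(f"delta_lambda       {run['delta_lambda']:.1f}")
print(f"reweighted <N>     {run['reweighted_rate']:.4f}")
print(f"achieved <N>       {run['achieved_rate']:.4f}")
print(f"error vs target    {run['error_percent']:.1f}%")
```

prints (about 40 s on one CPU core):

```
unconstrained <N>  0.0912
delta_lambda       -94.2
reweighted <N>     0.1300
achieved <N>       0.1353
error vs target    4.1%
```

The model's generated ensemble sits at the training kernel's rate (0.091);
the solved multiplier is negative (raising a rate means tilting toward
transition-rich paths), the reweighted sample average hits the target by
construction, and the *retrained* model — the actual deliverable —
generates fresh trajectories whose rate lands within a few percent of the
target.  `run["kernel_analytic"]` holds the closed-form tilted kernel
e^{−Δλ/L_traj} · p^A (rows renormalized), which agrees with the counting
kernel of the tilted subsample to within binomial error — the analytic
check of the whole pipeline.

The same pattern drives the other studies in `calipath.benchmarks`:
`equilibrium_symmetry_run` restores equal two-well populations (κ: 0.59 →
0.99 against a κ ≈ 0.5 training walk), `dynamical_constraint_run` shows
that lowering ⟨N⟩ lengthens inter-well transition times (the diffusivity
interpretation), and `quantum_dissipation_run` transfers a quantum-jump
ensemble from dissipation rate γ = 0.1 toward the γ = 0.2 decay curve by
constraining δn.

A CLI mirrors the workflow stages for shell use:

```
calipath simulate --system doublewell --length 60000 --seed 1 --out traj.csv
calipath train    --input traj.csv --epochs 120 --seed 2 --out model.npz
calipath generate --model model.npz --n-paths 200 --length 8000 --init 16 \
                  --seed 3 --out ensemble.csv
calipath constrain --model model.npz --observable nn_transition_rate \
                  --target 0.38 --length 2000 --init 16 --seed 4 \
                  --out ps_model.npz --report report.json
calipath run      --config config.yaml --seed 5
```

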