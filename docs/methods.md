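# Methods

## The model and the constraint machinery

`calipath` treats a one-dimensional molecular or quantum time series as a
sequence of discrete states and learns its *path probability* with an
autoregressive sequence model: an embedding layer maps each one-hot state
vector to a dense M-dimensional vector, a (stack of) LSTM cell(s) carries an
L-dimensional hidden state, and a dense softmax head emits the next-state
distribution.  Training minimizes the next-state cross entropy

    J = - sum_t v(t+1) . ln y_hat(t),

whose optimum is the conditional distribution of the data-generating
process; sampling the trained model autoregressively therefore draws
trajectories from (an approximation of) the path ensemble of the training
data.  The log path probability of a trajectory is the sum of its per-step
log scores.

Constraints are imposed by Maximum Caliber, the path-space analogue of
maximum entropy.  If a reference ensemble has path probability P^A and one
asks for a new ensemble whose average of a path functional s(Gamma) equals
a target s_bar^B, the closest constrained ensemble is the exponential tilt

    P^B(Gamma) ∝ exp(-dlambda s(Gamma)) P^A(Gamma),

with dlambda fixed by the self-normalized reweighted average over a sample
{Gamma_k} drawn from P^A:

    s_bar^B = sum_k s_k e^{-dlambda s_k} / sum_k e^{-dlambda s_k}.

That average is strictly decreasing in dlambda (derivative = minus the
tilted variance), so after geometric bracket expansion a Brent root find is
guaranteed to converge; weights are always handled in log space
(log-sum-exp), and the solved root is verified to reproduce the target to
1e-10 relative.  Several constraints are solved jointly by a hybrid Newton
root find (finite-difference Jacobian) on the residual vector, verified to
1e-8.  The constrained ("path-sampled") model is then obtained by drawing a
small subset of the generated paths with probability proportional to the
tilted weights and retraining a fresh model on that subset — constrained
learning without touching the loss function.

A target can only lie strictly inside the open range of the sampled
observable values; the solver raises otherwise, because no reweighting of a
finite sample reaches beyond its support.  For penalty-type observables
whose ideal value (zero) is unreachable — e.g. the decay-curve deviation
delta_n — `ConstraintTarget` accepts a `target_quantile`, which resolves
the target as a low quantile of the sampled values: the faithful
finite-sample version of "push the penalty toward zero".

## Observables

* `pair_transition_rate` / `nn_transition_rate` — transitions per step
  between listed (or all adjacent) state pairs.  The trajectory length
  `L_traj` in the denominator is the number of *steps* (samples minus one),
  so a path that transitions at every step has rate exactly 1.
* `symmetry_kappa` — ratio of lower-half to upper-half bin populations at a
  split index (pooled counts for an ensemble).  The split is a clean
  disjoint partition; for 32 bins the canonical split is 16/16.
* `half_occupancy` — the lower-half occupancy *fraction*
  f = kappa/(1+kappa).  On desk-scale paths the per-path ratio kappa is
  heavy-tailed (a path that barely visits the upper half has kappa of order
  the path length) and a weighted mean of ratios does not control the
  pooled ratio of a subset, so the equilibrium-symmetry workflow constrains
  mean f = 0.5 (equivalent to kappa = 1) and reports kappa.
* `theory_deviation_dn` — windowed squared deviation of photon-number
  paths from the classical decay curve n0 e^{-gamma t}, per unit window.

## Synthetic data: what it emulates and what it does not

**Three-state chain.**  Exact ancestral sampling from a shipped symmetric
kernel calibrated so the unconstrained {0,1}/{1,2} transition rate is
0.0893 — the slow-hopping regime of the three-state constraint experiment.
Being exactly Markov, it admits closed-form oracles for everything the
pipeline estimates.

**Bistable order parameter.**  A Metropolis walk on a discrete quartic
double well, F_i = barrier ((2i/(n-1)-1)^2-1)^2 + asymmetry [i < n/2] in
kT units, standing in for the slow helicity coordinate of a
helix-inverting peptide.  Detailed balance holds exactly, so the
equilibrium kappa is the Boltzmann ratio e^{-asymmetry} up to barrier-bin
corrections.  Proposals move 1–3 bins (weights 0.6/0.25/0.15, direction
symmetric) with attempt probability `diffusion`; multi-bin hops emulate the
several-bin frame-to-frame motion of a real projected order parameter and
set the well-to-well mixing time to a few hundred steps.  Calibrated
defaults (barrier 1.5 kT, diffusion 0.75, asymmetry ln 2) give long-run
kappa 0.50 and nearest-neighbour rate 0.40 on a 2x10^5-step check.  What it
does *not* emulate: the walk is Markov in the 32-bin space, whereas a real
projected coordinate carries memory; passing tests show the resampling
machinery works on a controlled bistable system, not that the sequence
model's memory is exercised by this particular generator.

**Leaky cavity.**  Monte-Carlo wavefunction trajectories of a two-level
atom coupled to a single-mode cavity, H = w1 a†a + w2 s+s- +
g(s- a† + a s+), one photon-loss channel sqrt(gamma) a, initial state
|7> x |up> (natural units, w1 = w2 = 2pi, g = pi/2).  Each path evolves
under the non-Hermitian H - i(gamma/2) a†a via the exact step propagator
(matrix exponential computed once — at Hilbert dimension 18 this is as
cheap as a first-order scheme and exactly norm-consistent); when the
squared norm falls below a uniform threshold a jump a|psi>/||.|| fires and
the threshold is redrawn.  Jump times are resolved to dt = 0.005.  The
photon-number expectation is recorded every 0.1 time units and discretized
into 20 bins on [0, 7].  The truncation at 9 photon levels is exact for
this initial state: the excitation-conserving coupling reaches level 8 and
photon loss only moves down; a warning fires if |top level, atom excited>
ever becomes populated.  The deterministic oracle integrates the Lindblad
master equation with the exact superoperator exponential per sample
interval, checking trace preservation (1e-6) and, on request, hermiticity
and positivity of the density matrix.

## Numerical choices

* Discretization is half-open, [edge_i, edge_{i+1}), out-of-range values
  clamp to the edge bins (counted and logged): total, deterministic,
  monotone.
* The sequence model runs in float32 with full BPTT, Adam (lr 1e-3 default,
  gradient-norm clip 5), overlapping training windows (length 100, stride
  50 by default) with per-window hidden-state reset, and a step
  learning-rate decay (x0.3 at 60% and 85% of epochs) so late iterates
  settle close to the optimum — the stationary distribution of a generated
  chain amplifies residual conditional bias exponentially across bins, so
  the settling matters more than the final loss value.  Embeddings are
  initialized N(0, 0.5) and the output head small-uniform: a zero head with
  tiny embeddings makes gradients nearly cancel on periodic inputs
  (period-2 hidden orbits), visibly stalling training on deterministic
  alternations.
* Sampling temperature is fixed at 1: anything else would change the path
  probability the Maximum-Caliber identities rely on.
* Subsampling is weighted-without-replacement by default (no duplicate
  training sequences); systematic resampling is available and used by the
  benchmark runs for its lower subset-mean variance at subset size 10.
* Tiny retraining subsets (a few thousand tokens) need hundreds of epochs;
  the three-state benchmark retrains for 500 epochs, which is still seconds
  of work.

## Design choices in the benchmark studies

The three-state study follows the published protocol sizes (train length
10^4, 200 generated paths, subset 10) with generated paths of length 200,
chosen so the target rate 0.13 lies inside the sampled per-path range
(about +-2 sigma around 0.09 at that length).  The analytic check tilts the
model's own base kernel entrywise by exp(-dlambda/L_traj) on the counted
transitions (the per-step-rate convention) and compares it with the
counting kernel of the tilted subsample at binomial resolution.

The equilibrium-symmetry study trains on a 6x10^4-step walk, generates 200
paths of 8x10^3 steps and pools five independent subsample-and-retrain
replicates (subset 10 each) for the constrained kappa estimate.  Two scales
matter here.  First, a single tilted subsample carries the population shift
partly in its transition statistics and partly in path-level enrichment;
windows of 400 steps (about the well dwell time) let retraining absorb
both, where 100-step windows recover only the kernel part.  Second, the
equilibrium of any single retrained model has appreciable run-to-run
spread, so the study averages over independent retrainings — the same
averaging the original experiment design calls for.

The dynamical study constrains the nearest-neighbour rate on 2x10^3-step
paths (per-path sd ~0.012, so 0.38 and 0.42 are both reachable from a
200-path sample).  Its training data are a *symmetric, single-hop* walk
(barrier 1.0 kT, attempt rate calibrated to <N> ~ 0.40): when every move
is one bin, <N> is exactly the move rate of the dynamics and carries the
full diffusivity, so the inter-well time scales like 1/<N>.  With
multi-bin moves this breaks down — the exact tilted-kernel first-passage
oracle shows that suppressing only the +-1 entries renormalizes
probability into larger hops and *raises* diffusivity, inverting the
transition-time ordering — so this study does not reuse the multi-hop
equilibrium-study generator.  Transition times are entry-to-entry between
the outer six bins of each well on 20 fresh 2.5x10^4-step trajectories per
replicate, pooled over four subsample-and-retrain replicates per target;
replicates share subsample and initialization seeds across the two targets
(a paired common-random-numbers design) so replicate-level training noise
largely cancels from the comparison.

The dissipation-transfer study trains on 500 gamma = 0.1 photon-number
trajectories, constrains the deviation from the gamma = 0.2 decay curve
over t in (5, 7) to its 2nd-percentile sampled value, retrains on a
20-path subset, and compares both models' window-mean photon number to the
target theory curve.

## Known limitations

* The constrained model reproduces the tilted ensemble only as well as the
  retraining data represent it; with 10-path subsets the result inherits
  subsample noise, which the replicate averaging reduces but does not
  eliminate.
* Equilibrium-type constraints on strongly mixing paths concentrate the
  per-path observable, so far-away targets can fall outside the sampled
  range; the solver reports this rather than extrapolating.  Generating
  more or longer paths is the remedy.
* The quantum generator records the smoothed expectation <a†a> per path, not
  the projective jump-count record; an option exposes the raw values, but
  integer-valued measurement records are not emulated.
* All generators are 1-D by construction; multidimensional order parameters
  are out of scope.
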