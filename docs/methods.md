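# Methods

This note documents the model, the numerical choices, and the design
decisions behind `grnpio`, in the order a reader needs them to interpret the
package's output.

## Model and estimation strategy

Each gene's expression level follows a difference of two power laws
(synthesis minus degradation); the full network is the coupled system of
those N ODEs. Estimation is *decoupled*: gene *i*'s ODE is integrated alone,
with every other gene's trajectory supplied by the observed data. This turns
one (2N² + 2N)-parameter problem into N independent (2 + 2N)-parameter
sub-problems at the cost of treating the measured off-target trajectories as
exact. The per-gene objective is the sum over time points of the squared
*relative* error, so genes expressed at different scales contribute
comparably; the network-level fitness is the mean of the per-gene objectives
across the decoupled sub-problems (mean rather than sum, so values are
comparable across network sizes).

Search ranges are `α, β ∈ [0, 10]` and `g, h ∈ [−3, 3]`. The containers
themselves accept any finite non-negative rate constants, because published
benchmark systems (including the built-in 5-node network, whose first rate
constant is 15) sit outside the search box; the box constrains *inference*,
not representation.

## Integration and sampling

* **Integrator:** fixed-step classical Runge-Kutta (RK4). The scheme is
  deliberately fixed-step so that the batched candidate evaluator, the
  reference simulator and the profile generator are bit-identical; an
  adaptive integrator (scipy `solve_ivp` at rtol 1e-10) serves as an
  independent oracle in the test suite, which requires agreement within
  1e-4 relative error on both benchmarks.
* **Sampling grid:** benchmark profiles are 31 samples spaced 0.01 time
  units (t ∈ [0, 0.3]). With rate constants of order 10 these systems relax
  toward steady state within ~0.1 time units, so a coarser grid would record
  mostly steady state and carry little information about the kinetic
  orders; the dense grid resolves the transient. It also keeps the
  decoupled self-consistency error (below) at the 1e-10 level.
* **Off-target interpolation:** decoupled integration needs off-target
  values between samples (RK4 midpoints). These are taken from a cubic
  spline of the observed profile. With linear interpolation the
  self-consistency error — the residual when the *true* generating
  parameters are scored against their own simulated profile — is about
  1e-6 on the 5-node benchmark; with the cubic spline it is ~7e-11. That
  residual is the method's noise floor: fitted solutions cannot be
  meaningfully better than it.
* **Guards:** states are clamped to a floor of 1e-6 before powers are
  applied (negative bases under fractional exponents are undefined); any
  state above 1e6 marks the candidate as diverged. Inside the optimizer a
  diverged candidate receives a worst-case fitness of 1e12 rather than
  aborting the run; the user-facing simulators raise an error naming the
  gene and time index. Observed values below 1e-6 are floored in the
  relative-error denominator (never triggered on the built-in benchmarks).

## Objectives

With a structure prior, the combined per-gene objective is
`α·MSE + (1−α)·(sp1 + sp2)/2` with `α ∈ [0, 1]` the behavior:structure
weighting. `sp1` is the fraction of prior-zero slots inferred non-zero and
`sp2` the fraction of prior-non-zero slots inferred zero, so the penalty
lies in [0, 1] and is commensurate with the per-gene relative MSE near
convergence. A kinetic order counts as zero when its magnitude is below
0.1 — the same threshold used for structure-accuracy scoring and edge-list
export; regulation strengths in these benchmarks are 0.1–2 in magnitude, so
the cutoff sits well below any real interaction.

## The optimizer

Per generation, particles are ranked by fitness (stable sort, ties by
index); the best ⌈(1−r)·n⌉ with r = 0.5 are refined by a standard PSO update
(inertia 0.7, cognitive = social = 1.5, velocities clamped to ±2 for rate
constants and ±1 for kinetic orders, positions clipped to the active
bounds); the rest are replaced by offspring from size-2 tournaments, BLX-0.5
crossover and Gaussian mutation (rate 0.05, σ = 5% of the legal range). The
PSO constants and GA operators are conventional real-coded choices; all are
configurable. The population best (gbest) is bookkept across every phase
and never worsens — this is asserted property-style in the tests.

The identification phase (every 500 generations) runs m-MPSA around the
current gbest: each parameter is sampled 500 times uniformly in its current
range, one at a time with the remaining parameters held at the anchor
(classic joint sampling is available as a config option). Candidates are
acceptable when their fitness is at most Cr = 3 × the best sampled fitness.
The sensitivity score is the Pearson correlation of the acceptable and
unacceptable cumulative-frequency curves on the common grid of sampled
values; degenerate splits (all acceptable, all unacceptable, zero-variance
curve) score 1, i.e. maximally insensitive, so such parameters are never
prioritized. Parameters at or below the threshold CCR are classified
sensitive and get bounds gbest ± 2 × velocity bound; the others get factor
5; both are clipped to the legal ranges (collapsed intervals are widened to
1e-3 around their center). All particles are then regenerated inside the
new box, local bests are overwritten, and gbest is updated only if improved.
CCR starts at the 25th percentile of the first report's sensitivity
distribution (it is a relative threshold; an absolute override is available)
and grows by ε = 0.01 per phase, capped at 1 since the score is a
correlation. The exploration phase (every 1000 generations) redraws every
particle except the top 1% (⌈0.01·n⌉) within the current bounds.

### Sensitivity reporting

Two sensitivity measurements coexist and must not be confused:

* the *classification* measurement inside each identification phase uses the
  current search ranges and fresh random draws — it drives the algorithm;
* the *history* measurement recorded per phase (and the final report) uses
  the full legal ranges with a per-run fixed seed, i.e. common random
  numbers across phases, so consecutive phases are comparable on one scale.
  Without common draws the phase-to-phase resampling noise (±0.01–0.02)
  swamps the trend.

Monotonicity checks on these Monte Carlo series use a tolerance of 0.005,
about three standard errors of the phase-mean estimator at 500 samples per
parameter. Final sensitivities for with/without-SA comparisons are measured
on the same full-range scale in both arms.

## Seeding

One master seed drives everything. Whole-network inference derives each
gene's child seed from the master seed and the gene's *name* (CRC32-based,
kept below 2³¹), so per-gene runs are independent, reproducible, and stay
attached to genes under column permutation. Repeated-run experiments derive
per-run seeds from the master by a fixed affine map. Exact realization-wise
equivariance under column permutation is not claimed: within a sub-problem
the per-dimension random draws are not permuted with the columns.

## What the synthetic benchmarks do and do not show

The built-in networks are the two standard artificial S-systems printed in
the network-inference literature (5 and 10 nodes; all degradations of the
10-node system are 10·Xi²). Initial conditions are not part of the published
systems; the package fixes all-0.7 for the 5-node system and a frozen
vector drawn once from U(0.1, 1) for the 10-node system, chosen so
trajectories are non-trivial and bounded. Profiles are noiseless
(multiplicative Gaussian noise is available but off by default), uniformly
sampled, and complete — real expression data are none of these, so passing
benchmarks demonstrates correctness of the machinery and the optimizer's
search power, not performance on noisy sparse measurements.

A structural caveat established empirically in this package's tests: a
single trajectory constrains each gene's two power laws only along the 1-D
curve the system traces in state space, so behavior-only fitting reaches
fitness ~1e-6 with *wrong* zero/non-zero structure (~30% slot agreement,
the same level the fit-only benchmark tables report). Structure recovery is
therefore tested with the true topology supplied as a prior through the
combined objective at 1:9 behavior:structure weighting: 2-gene toy systems
then recover the exact structure with behavior MSE < 1e-3 in ≥ 4 of 5
seeds. Recovering structure from data alone would require multiple initial
conditions or perturbation experiments, which are out of scope.

## Desk-scale run sizes

The published experiments use 20–30 independent runs per arm; the package's
acceptance script and benchmark tests use 5 runs per arm, 500 generations
for the plain/structure-weighted arms, and 1500–2500 generations for the
identification-loop arms (3–5 identification phases, 1–2 exploration
phases), population 200 throughout. These sizes are the package's default
desk scale: they keep a full re-run at minutes on one core while leaving
every comparison (with vs without identification, weighted vs behavior-only)
overpowered relative to the observed run-to-run spread. The identification
loop's measured benefit on the 5-node benchmark is small at these budgets
because the plain hybrid is already near the self-consistency floor; the
with-SA arm is consistently no worse under paired seeds.

## Known limitations

* Decoupled estimation trusts the measured off-target trajectories; heavy
  measurement noise propagates into every sub-problem.
* Uniform sampling is required by the batched evaluator (the fixed-step
  grid is precomputed); non-uniform real datasets must be resampled first.
* Protein-level regulation, stochastic dynamics and time-varying inputs are
  outside the model class.
* The structure penalty is piecewise constant in the parameters, so its
  gradient information is zero within a zero/non-zero cell; the GA part of
  the hybrid does the threshold crossing.
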