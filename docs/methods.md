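# Methods

## Model

`dpbtn` infers signed, weighted, possibly cyclic signaling networks from
short time-course measurements taken after systematic perturbations
(RNAi knockdowns, overexpression).  The network on N proteins is a weighted
directed graph W, with w_ij > 0 an activation of node j by node i,
w_ij < 0 an inhibition, and w_ij = 0 no edge.  Each protein is a Boolean
variable ("on"/"off"); model time is discrete and all nodes update
synchronously.  The probability that node i is on at the next step is a
logistic threshold function of its active regulators,

    P(v_i(t+1) = 1 | v(t)) = sigma(gamma * (w0_i + sum_j w_ji v_j(t))),

where sigma is the logistic function, w0_i <= 0 a basal weight (unregulated
proteins tend to stay off), and gamma > 0 a global steepness: small gamma
gives noisy dynamics, large gamma approaches a deterministic threshold
network.  Interventions clamp nodes: a knocked-down node is held at 0 and an
overexpressed node at 1 at every model step; clamping overrides the
dynamics and any conflicting observation.

Measurements are binary (discretized upstream) at T real time points per
experiment; a positive integer vector tau maps real time to model time:
tau_t model steps elapse between consecutive measurement times.
Intermediate steps are unobserved and are marginalized in the likelihood, as
are missing values.

The sampled parameter is Omega = (W, w0, tau).  Priors:

* off-diagonal weights: an L_q kernel, log p(W) = −Σ(|w_ij − mu_ij|/s)^q
  up to a constant — Laplacian (sparsity-inducing) at q = 1, Gaussian at
  q = 2.  mu encodes prior edge knowledge and defaults to 0.
* basal weights: negative-gamma — gamma(shape s0, rate r0) on −w0, mode
  −(s0−1)/r0.  Defaults r0 = 8, s0 = 16 put the mode at −1.875.
* tau: independent binomial(n, p) restricted to tau_t ≥ 1 (a measurement
  interval spans at least one model step).  Defaults n = 20, p = 0.3 give a
  prior mean of 6 steps.

gamma is a fixed hyperparameter (default 1.8), not sampled.  The evidence
normalizer is never needed (Metropolis–Hastings only uses ratios).

## Likelihood

With tau_t = 1 everywhere and complete observations the likelihood is a
product of per-node Bernoulli transition probabilities and is computed
exactly.  Otherwise the per-experiment marginal likelihood is estimated by
forward simulation from the clamped time-0 observation (R = 50 replicate
runs by default).  Two estimators of the same quantity are implemented:

* **Rao-Blackwellized sequential importance sampling** (default).  Runs are
  propagated under the model dynamics; at each measurement time every run is
  weighted by the exact product of per-node Bernoulli probabilities of the
  non-missing observations given the run's previous state, and observed
  nodes are then conditioned on their observed values before the simulation
  continues.  The per-experiment likelihood estimate is the mean weight.
  The estimator is unbiased and integrates the last stochastic step before
  each measurement out analytically, so it never returns an exact zero and
  its variance is far below that of trajectory matching — at R = 50 the
  log-likelihood noise is a fraction of a unit, small enough for stable
  Metropolis sampling.
* **Trajectory matching** (`estimator="matching"`): the fraction of runs
  whose simulated states reproduce every non-missing observation at every
  measurement time; a fraction of zero is floored at 1/(R+1).  This is the
  conceptually simplest estimator and is kept as a cross-check, but its
  likelihood landscape is flat (floored) over most of parameter space at
  practical R, which cripples exploration; it is not recommended for
  inference.

Missing values match anything (implicit marginalization).  A missing time-0
value initializes the node to "off" (signaling molecules are assumed off
without input); `missing_t0="random"` instead randomizes it per replicate
for full marginalization.

Because the current state's cached likelihood estimate is *not* refreshed at
every step (the usual cheap convention for Monte-Carlo-within-Metropolis),
the sampler is approximate rather than pseudo-marginal-exact;
`refresh_current=True` enables the refresh for sensitivity checks.  With the
default estimator the residual noise is small and the prior-only and
1-node-posterior sampling tests show no detectable distortion.

## Sampler

The posterior is explored with a distributed evolutionary Monte Carlo
scheme: m chains in g subpopulations (defaults 3 subpopulations x 4
chains).  Per sweep, with probability `p_crossover` one pair of chains in a
random subpopulation proposes a **crossover** — exchanging the full incoming
regulation set of one node (a column of W plus the matching w0 entry, a
natural block because the likelihood factorizes over target nodes); the
swap is symmetric and accepted jointly on the summed log-posterior change.
Otherwise every chain proposes a **mutation**: each off-diagonal weight is
perturbed with probability `p_mutation` = 0.1 by noise from a two-scale
Gaussian mixture (sd 0.3 with weight 0.7, sd 2.0 with weight 0.3), each
basal weight with sd 0.1, and with probability 0.2 one tau_t takes a ±1
step.  A tau step leaving the support [1, n] proposes the current value,
which keeps the kernel exactly symmetric (a reflecting rule would not be).
The large mutation component matters: under a sparsity prior an edge's
weight must cross a penalty barrier between 0 and its posterior value, and
small-step walks cross it too slowly for desk-scale runs.  Every
`migration_interval` sweeps each subpopulation sends a copy of its best
chain to replace the worst chain of the next subpopulation on a ring.  All
subpopulations target the same posterior (no temperature ladder); that is a
straightforward extension point.

Progress is counted in proposal steps (= likelihood evaluations; a mutation
sweep costs m, a crossover pair 2).  Chains initialize overdispersed by
drawing W, w0 and tau from their priors through independent seeded
substreams; everything is reproducible bit-for-bit from the single run seed.
Convergence is monitored with the Brooks–Gelman potential scale reduction
factor (clamped below at 1.0); the overall acceptance rate is logged and a
warning is emitted outside the 5–80% band.

## Aggregation and evaluation

Posterior draws are summarized three ways.  (1) **Edge scores**: the
elementwise median of sampled W; the sign of the median is the edge's
reported mode of action.  (2) **Clusters** of alternative topologies:
DBSCAN on the flattened (W, w0) vectors, with the neighborhood radius set
to twice the median k-nearest-neighbor distance (the factor keeps
distribution tails attached to their cluster).  This is a deliberately
simple density-based stand-in satisfying the same contract as the
correlation-clustering method it replaces: group similar networks, estimate
their probabilities.  Cluster probabilities divide by *all* samples, so
unclustered noise dilutes every cluster; representatives are within-cluster
elementwise medians (the coordinatewise L1 minimizer); per-edge support is
the member fraction with |w_ij| above 0.1·s.  DOT export renders support
> 0.8 thick, > 0.6 thin, > 0.4 dashed; activations black, inhibitions red.
(3) **Discrete networks**: edge present iff |median| ≥ delta, with a
relative mode delta = c·max|median| (c = 0.65 reproduces the
comparable-edge-count convention used for real-data reporting).

ROC and PR curves sweep delta over all distinct |score| magnitudes plus
+inf; ties enter a single sweep step, so trapezoidal AUC_ROC equals the
tie-corrected Mann–Whitney statistic (tested against scikit-learn).  AUC_PR
uses the step-wise (non-interpolated) convention, Σ precision·Δrecall —
conventions differ across packages, so this is fixed and tested.
Self-edges are excluded from the candidate universe; undirected mode
collapses ordered pairs by max |score|.  Degenerate gold standards
(all-positive/all-negative) are flagged, not silently scored.

## Synthetic data

The generators reproduce a three-part simulation study design:

* **sn1** — a 7-node feedforward reference network: edges
  1→2, 1→3, 2→4, 3→5, 4→5, 5→6, 4→7, 6→7, all weights 1, basal −0.25,
  gamma 10 (near-deterministic dynamics with occasional state flips).  The
  published drawing of this topology was not available to this
  implementation; the edge list above is a reconstruction consistent with
  every stated constraint — node 1 a parentless receptor, an acyclic
  feedforward shape, and convergence nodes with parent sets {3,4} and
  {4,6}, which make the study's combinatorial knockdowns exactly the
  experiments needed to resolve OR-redundant regulation.  The fixture
  (`SN1_EDGES`) is the single source of truth, and the gold standard always
  equals the generating topology, so all benchmark numbers are internally
  consistent whatever the original drawing was.
* The **knockdown protocol**: every node knocked down singly, plus the
  combinations (3,4) and (4,6) — K = 9 experiments.  All proteins start
  "off"; the receptor is stimulated, which we model as a sustained clamp-on
  intervention for the whole experiment (a parentless node would otherwise
  relax back to "off" within a step or two and no signal could reach the
  downstream nodes by measurement time).  Binary observations at model
  steps {0, 6}; tau = (6).
* **sn1a** — the same network and experiment count with overexpression
  (clamp-on) perturbations instead; no receptor stimulation, the clamped
  nodes themselves provide the sustained input.
* **sn2** — the reference network plus an inhibitory feedback edge 7→4,
  closing the negative loop 4→5→6→7→4.  Dynamics are deterministic: a node
  activates iff strictly more activating than inhibiting parents are active
  (ties deactivate).  Noise enters only at measurement: a continuous
  readout drawn Normal(mean, var) with the mean near the active/inactive
  class location (1 resp. 0, sd 0.1) and the variance from a scaled
  inverse-chi-squared(nu = 5, tau² = 0.04); these are calibration knobs,
  config-exposed, since the upstream empirical values are not published.
  Continuous values are discretized at the midpoint of the class locations
  (ties map to "on").  Measurements at steps {0, 4, 6}; tau = (4, 2).
* **Corruption operators**: `inject_noise` flips an exact count
  ⌊fraction·#observed⌋ of distinct observed values; `mask_missing` removes
  *all* observations of ⌊fraction·N⌋ random nodes (16/33/50% of 7 nodes = 1,
  2, 3 nodes).  The receptor is maskable like any node.
* **random_network** draws connected signed directed topologies of given
  density as stand-ins for small pathway-database subnetworks and is used
  with the sn2 measurement protocol.

What the generators do *not* emulate: continuous kinetics, unequal
per-protein noise learned from real arrays, normalization artifacts of
array data, or correlated measurement error.  Passing benchmarks therefore
demonstrate correct recovery under the model's own assumptions (sn1/sn1a)
and under a mismatched deterministic generator (sn2), not performance on
any particular experimental platform.

## Desk-scale study configuration

The original study runs 10^8 proposal steps per inference and 100 replicate
datasets per condition (hours per run).  The package's reference
configuration (`dpbtn.study`) scales this to desk size: 2×10^4 proposal
steps, burn-in 2×10^3, thinning 10, R = 50, 3×4 chains (the feedback study
uses 5×3 chains and 6×10^4 steps, mirroring the original's layout for that
experiment), and 11 replicate datasets for the clean benchmark, 9 for
overexpression, 7 per corruption level, 3 for the feedback study.  One
knockdown inference takes on the order of 15 s on a single CPU.  All
randomness derives from one seed via `SeedSequence` spawning.

Known consequences of the scale-down: medians over 7–11 replicates are
noisier than over 100; the sampler's effective sample size per run is
modest, so per-edge posterior quantiles are rough; and PSRF across chains
of a single run can exceed 1.1 on the hardest (50% corrupted) conditions.
Because the default likelihood estimator integrates each measurement step
out analytically, desk-scale recovery on clean knockdown data is sharp —
its median AUC_ROC typically lands at or slightly above the value the
original full-scale study reports with the trajectory-matching estimator,
while the corrupted-data conditions degrade in the same order and to
similar levels.  The acceptance script reports exactly what these
desk-scale runs produce.

## Numerical choices and edge cases

* Weight matrices keep an exactly zero diagonal (self-loops disabled by
  default; a flag enables them).
* −inf log-priors (positive w0, tau outside [1, n]) short-circuit the
  likelihood; MH rejects −inf proposals outright, and a run whose every
  chain initializes at −inf aborts with a diagnostic.
* The matching estimator's zero fractions floor at 1/(R+1); the
  Rao-Blackwell estimator handles impossible observations via log-space
  accumulation and returns −inf only when every run's weight underflows to
  zero probability.
* Medians of even-sized sample sets follow the numpy midpoint convention.
* Discretization ties (value exactly at threshold) map to "on"; discrete
  edge sets break |median| = delta ties toward inclusion and exact-zero
  scores toward absence.
* Observation tables conflicting with their design's clamps load with a
  warning; clamps win during inference.
* Text formats round-trip exactly (`%.17g`).
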