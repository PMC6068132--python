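# Methods

## Model

An exponential random graph model (ERGM) assigns an undirected graph
`x` on a fixed set of `N` nodes the probability

    pi(x, theta) = exp( sum_A theta_A * z_A(x) ) / k(theta),

where the `z_A` are network statistics (subgraph and attribute counts)
and `k(theta)` is an intractable normalizing constant that this package
never evaluates.  Maximum likelihood coincides with the method-of-moments
condition `E_theta[z_A(x)] = z_A(x_obs)` for every statistic, and
`E_theta[z_A]` is monotonically non-decreasing in its own parameter
`theta_A` — the property every estimator here relies on.

### Statistics

All statistics are exact counts or geometrically damped ("alternating")
sums with decay constant `lambda > 1` (`r = 1 - 1/lambda`; default
`lambda = 2`, the standard choice in the alternating-statistics
literature, configurable per term):

| kind           | value                                                        |
| -------------- | ------------------------------------------------------------ |
| `edge`         | number of edges `L`                                          |
| `isolates`     | number of degree-0 nodes                                     |
| `alt_star`     | `lambda^2 * sum_i [ r^{d_i} - 1 + d_i/lambda ]`              |
| `alt_triangle` | `lambda * sum_{edges (i,j)} [ 1 - r^{SP_ij} ]`               |
| `alt_twopath`  | `lambda * sum_{dyads i<j} [ 1 - r^{SP_ij} ]`                 |
| `activity`     | `sum_{edges} (y_i + y_j)` for a binary attribute `y`         |
| `interaction`  | `sum_{edges} y_i * y_j`                                      |
| `mismatch`     | edges whose endpoints differ on a categorical attribute      |

`d_i` is the degree of node `i` and `SP_ij` the number of shared
partners of `i` and `j`.  The alternating forms are the closed-form
equivalents of the damped alternating series over k-star / k-triangle /
k-two-path censuses; an edge between two flagged nodes contributes 2 to
activity and 1 to interaction.  Change statistics for a single-dyad
toggle are computed locally (cost depends on endpoint degrees and
shared partners, never on `N`) and equal the full-recount difference
exactly; deletions are the exact negation of the corresponding
insertion evaluated on the graph without the edge.

## Samplers

**Basic**: propose a uniformly random dyad toggle; accept with
probability `min{1, exp(theta . dz)}` (log-space, symmetric proposal).

**IFD (improved fixed density)**: the edge count is constrained to
`{L_obs - 1, L_obs}` by proposing a uniform deletion at `L_obs` and a
uniform insertion at `L_obs - 1`.  The proposal ratio is exact:
`q_ratio = L_obs / (D - L_obs + 1)` for deletions (its reciprocal for
insertions), with `D = N(N-1)/2`.  An auxiliary edge parameter
`theta_L` enters the acceptance like an edge term and is adapted every
`m` steps by the signed-square rule applied to the occupancy imbalance
`d = (fraction of steps at L_obs) - 1/2`.  Flow balance makes the fixed
point of this adaptation `theta_L = ln(L_obs / (D - L_obs + 1))` for
the edge-only model — the Bernoulli MLE — which is how the package
reports an edge parameter from fixed-density fits.  The published
description of this sampler is one paragraph; the move pairing, the
exact (not large-`N`-approximate) proposal-count ratio and the
occupancy-balance adaptation are this package's reconstruction, and the
Bernoulli closed form above is unit-tested.

## Estimation

**CD-1 initialization.**  The one-step contrastive-divergence estimate
solves `mean over proposals from x_obs of alpha(theta) * dz = 0` — a
deterministic system once the proposal set is fixed.  All dyads are
enumerated when feasible (up to 10^5 dyads; beyond that a seeded
sample), and the root is found by damped Newton iteration from the
null model (theta = 0) on the one-sided Jacobian
`J_AB = mean[ 1(lp <= 0) e^{lp} dz_A dz_B ]`, which is positive
semi-definite.  Near-null eigendirections of `J` are truncated
(minimum-norm steps) rather than ridge-inverted: when two statistics
are almost collinear the drift system has a long flat valley, and an
exact root chased down that valley is a high-variance pseudo-likelihood
artifact; truncation anchors the unidentified combination at zero and
solves the identified ones exactly.  For dyad-independent models the
root coincides with maximum pseudo-likelihood (verified against a
logistic regression oracle).  Roots escaping to infinity (empty or
complete observed graphs, all-zero attributes) are detected by drift
past 80% of the +/-25 cap and flagged; the capped value stands in.

**Equilibrium expectation (EE).**  A single Metropolis-Hastings chain
starts at the observed network with `theta = theta0`.  Accepted change
statistics accumulate into `dz = z(x) - z(x_obs)` (maintained
incrementally; equal to a recount at all times, which the tests check),
and every `m = 1000` elementary steps each parameter is updated as

    theta_A  <-  theta_A - K_A * sign(dz_A) * dz_A^2 .

By the monotonicity of `E[z_A]` in `theta_A`, the update pushes the
chain toward the joint fixed point where the equilibrium drift and the
statistic gap both vanish — i.e. the MLE.  With `K = 0` the run reduces
to plain MH.  Estimates are trace averages of `theta_A(t)` over the
last half of the checkpoints (`t_B` = 50% by default, overridable); an
optional step-size halving late in the run (as used for very long
chains) shrinks the trace variance without moving its mean.  A
divergence guard aborts when any `|theta_A|` exceeds 50 — parameters of
that size imply degenerate graphs.

**Step sizes `K_A`.**  Two choices are provided:

* `compute_KA` implements the printed heuristic
  `K_A = 1e-4 * (dDeltaZ_A/dtheta_A)^-2`, with the derivative estimated
  from static proposals at `x_obs` as
  `m * mean[ 1(lp<=0) e^{lp} dz_A^2 ]` (the one-sided derivative of the
  expected accepted change, scaled to the update window).
* `calibrate_K` (the pipeline default) runs a short MH probe
  (50 windows of `m` steps; the fixed-density dynamics when the model
  is fixed-density) from the observed network at `theta0` and sets
  `K_A = gain / ( Var_probe(z_A) * SD_probe(w_A) )`, where `w_A` is the
  per-window statistic innovation.  This makes `gain` the approximate
  fraction of a statistic deviation restored per update — a
  dimensionless feedback strength.  Values of `K_A` above roughly
  `1 / (Var(z_A) * SD(w_A))` destabilize the signed-square loop
  (verified on the Bernoulli model, where everything is available in
  closed form), while much smaller values leave the statistics
  unconstrained over a desk-scale run; the defaults (`gain = 0.02` for
  single fits, which holds the t-ratios well inside the convergence
  rule at million-step runs, and `0.002` in the recovery study, where
  the smaller kick minimizes the skew-induced offset discussed below)
  keep one-and-a-half to three decades of stability margin.  Terms
  with no probe variation fall back to a configured floor (`1e-6`).

A known small-sample property of the signed-square rule: its stationary
point balances `E[sign(dz) dz^2]`, not `E[dz]`, so a skewed stationary
distribution of `z_A` (e.g. bursty triangle counts on small graphs)
shifts the estimate by a small amount relative to a moment-matching
update.  The offset shrinks with the step size and with network size;
at the study conditions below it is ~0.005 on parameters of magnitude
0.2-5, well inside Monte Carlo spread, and is measured directly by the
EE-vs-MoM agreement check.

**Method-of-moments baseline.**  Classic three-phase Robbins-Monro
stochastic approximation: phase 1 equilibrates a working copy of the
network and calibrates a diagonal scaling matrix from probe statistic
variances (the exponential-family response `dE[z_A]/dtheta_A =
Var(z_A)`); phase 2 runs subphases of iterations
`theta <- theta - a_r D^-1 (z(x_sim) - z(x_obs))` with gains halving
per subphase and Polyak-Ruppert averaging over the final subphase,
each draw an MH-advanced chain state; phase 3 simulates independently
at the estimate and computes Snijders-style t-statistics (converged
when all `|t| < 0.1`).  The baseline is configured for a single
phase-2/3 round by default in the recovery study; like the published
experience with this estimator at scale, a minority of desk-scale runs
clear the strict t-threshold, and the non-converged flag is reported
rather than retried.

## Diagnostics

* `t_ratio`: `tau_A = (mean z_A(t > t_B) - z_A(x_obs)) / SD(z_A(t > t_B))`,
  sample SD with `n-1`.  Convergence requires `|tau_A| < 0.1` for all
  terms.  A zero-SD column whose mean equals the observed value gives
  `tau = 0`; zero SD off target raises a degenerate-trace error (a
  stuck chain must not pass as converged).
* Parameter-trace stationarity (the automated stand-in for visual
  inspection): the post-burn-in half-trace means must agree within 2
  standard errors — estimated from the scatter of the four quarter
  means, which absorbs autocorrelation at the scale that moves the half
  means — and the fitted linear trend must stay within 3 residual SDs.
  Simulated operating characteristics: 84-99% pass rate on stationary
  but strongly autocorrelated traces, near-certain detection of drifts
  of 5 SD or more.  With trace lengths of only a few mixing times the
  flag is conservative; `tau` remains the primary criterion.
* `estimate_ci`: simulate at `theta_hat`, take the statistic covariance
  `Sigma` as the observed Fisher information (exponential-family
  identity) and report `SE_A = sqrt((Sigma^-1)_AA)` with Wald 95%
  intervals; singular `Sigma` falls back to a pseudo-inverse with a
  warning.  Matches the analytic Bernoulli information and a logistic
  oracle on dyad-independent models.
* `snijders_tstat`: the expensive external check — an independent
  equilibrated simulation at `theta_hat` with threshold `|t| < 0.3`.

## Synthetic data and the recovery study

Networks are generated by MH from the empty graph (deterministic,
standard initial state) for `burnin_factor * D` elementary steps
(default 20 per dyad); the generation trace is recorded so burn-in
sufficiency can be checked by doubling (a test does).  A degeneracy
guard aborts when the chain drifts to a near-empty or near-complete
state.  Attribute generators draw independent binary flags and
categorical labels, emulating the lineage-specific / functional-class
annotations attached to protein-interaction networks.

The frozen study conditions are `N = 300`, `lambda = 2`,
`theta* = (edge -3.0, alt_star -0.5, alt_triangle +0.8)` (mean degree
~3.7 — sparse, with suppressed hubs and strong triadic closure, the
shape of a curated protein-interaction network), 20 replicates, EE
with `M = 2e6` elementary steps.  The conditions are the result of an
explicit identifiability analysis.  At `lambda = 2` the alternating
star satisfies `AS = 4(L - N + isolates)` exactly once nearly all
degrees exceed ~6 (`r^d` vanishes), so in every moderately dense
regime the (edge, alt-star) pair is structurally non-identified — the
measured equilibrium correlation of the two statistics is 0.99999+,
the chain reproduces the observed statistics equally well anywhere
along the corresponding parameter valley, and no estimator can recover
the two weights separately at any run length.  Sparse regimes with
*positive* alt-star weights sit near the model's degenerate transition
at this `N` (bistable, non-equilibrating generation).  Sparse with a
negative (hub-suppressing) alt-star weight is both stable and
identified (statistic correlation ~0.993), which is where the study
lives.  Estimates along the weakly identified direction still carry
most of the between-replicate spread — visible in the recovery table
as a much larger SD for the edge and alt-star terms than for
alt-triangle.

### What the generator does and does not emulate

Generated networks are exact draws from the fitted model family, so
recovery results certify the estimator, not the model: real interaction
networks carry degree heterogeneity, assortativity and measurement
artefacts that no 3-term ERGM reproduces.  Passing tests show the
estimators find the MLE when the model is true; they say nothing about
model adequacy for any particular empirical network.

## Numerical choices

* Single integer seed per run; all kernels are seeded and bit-reproducible.
* Acceptance always computed in log space; `k(theta)` never appears.
* `sign(0) * 0^2 = 0`: a zero accumulator leaves the parameter unchanged.
* Updates use the accumulated `dz` at the update instant (not a
  windowed mean), per the estimator's definition.
* Dense boolean adjacency matrix with maintained degree vector and edge
  counter; comfortable to a few thousand nodes, which covers the
  intended simulation scale.
* Ties in `alt_*` shared-partner work are avoided by evaluating
  deletions on the edge-removed graph, making add/delete exactly
  antisymmetric.

## Limitations

* Curved exponential families (estimating `lambda`) are out of scope;
  `lambda` is a fixed model constant.
* Directed, bipartite, weighted and multi-graphs are not supported.
* The convergence guarantee is empirical: the EE loop has no proof of
  convergence, and the divergence guard plus diagnostics are the
  safety net.
* Goodness-of-fit beyond the fitted statistics (e.g. degree-distribution
  GOF suites) is not provided.
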