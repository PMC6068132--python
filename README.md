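# ergm-ee

Fast maximum-likelihood estimation of exponential random graph model
(ERGM) parameters on undirected networks by **equilibrium expectation
(EE)** — a single-chain stochastic approximation that constrains every
model statistic to its observed value while the chain runs, instead of
repeatedly simulating networks to convergence for each trial parameter
vector.

## Who this is for

ERGMs express the probability of an observed network as

    pi(x, theta)  =  exp( sum_A theta_A z_A(x) ) / k(theta),

where the statistics `z_A(x)` count structural motifs (edges, isolates,
geometrically damped "alternating" stars, triangles and two-paths) and
node-attribute patterns (activity `rho`, interaction `rho_B`,
categorical mismatch).  A fitted `theta_A` significantly above zero
means the motif is over-represented *conditional on everything else in
the model* — the standard way to put an inferential footing under motif
analysis of protein-protein interaction and social networks.  Classical
estimation (MCMC-MLE, Robbins-Monro method of moments) needs many
equilibrated simulations per parameter update and stops scaling beyond
a few thousand nodes; EE gets equivalent estimates from one chain.

The maximum-likelihood condition is the moment equation
`E_theta[z_A(x)] = z_A(x_obs)`.  EE starts a Metropolis-Hastings chain
**at the observed network**, accumulates accepted change statistics
into `dz_A = z_A(x) - z_A(x_obs)`, and every `m = 1000` elementary
steps applies the signed-square update

    theta_A  <-  theta_A  -  K_A * sign(dz_A) * dz_A^2 ,

which is a root-finder for the monotone map `theta_A -> E[z_A]`.  At
the joint fixed point the chain is in equilibrium *and* reproduces the
observed statistics; estimates are trace averages of `theta_A(t)` and
convergence is certified by the t-ratio rule `|tau_A| < 0.1` with
`tau_A = (mean z_A - z_A(x_obs)) / SD(z_A)`.  Initial values come from
a one-step contrastive-divergence (CD-1) solve, step sizes from a short
probe run.  A Robbins-Monro method-of-moments implementation is
included as the baseline, along with a fixed-density (IFD) sampler that
pins the edge count and recovers the edge parameter through an adapted
auxiliary `theta_L`.  See `docs/methods.md` for the full account.

## Worked example

`examples/estimate_synthetic.py` generates a 300-node network from
known parameters and re-estimates them end to end:

```
$ python examples/estimate_synthetic.py
generated N=300 network: 552 edges (density 0.0123)
true theta*: [-3.  -0.5  0.8]
term                         theta      tau       SE                95% CI
edge                       -2.8632    0.027   0.5428   ( -3.927,  -1.799)
alt_star                   -0.5422    0.033   0.1653   ( -0.866,  -0.218)
alt_triangle                0.8094   -0.055   0.0682   (  0.676,   0.943)
converged: True (sampler=basic, m=1000, t_B index=500)
```

Each row is one model term: `theta` is the trace-averaged estimate
(every generating value falls inside its interval), `tau` the
convergence t-ratio (all well inside the `|tau| < 0.1` rule), and the
interval the Wald 95% CI from the simulated Fisher information.  The
positive `alt_triangle` weight is the model's way of saying triangles
are over-represented given the degree structure; the much wider
intervals on `edge` and `alt_star` reflect the near-collinearity of
those two statistics on sparse homogeneous graphs.

Other examples, one per capability: `simulate_network.py` (draw from a
model), `compare_estimators.py` (EE vs method of moments),
`fixed_density_sampler.py` (IFD auxiliary edge parameter),
`attribute_effects.py` (activity/interaction/mismatch terms),
`recovery_study.py` (bias table over replicates).

## Command line

A thin CLI wraps the same pipeline for shell use:

```sh
ergm-ee estimate --config config.yaml --seed 1 --out results/
ergm-ee simulate --config config.yaml -n 100 --out sim/
ergm-ee recover  --config config.yaml --out rec/
```

The YAML config declares the network file (Pajek `.net` or two-column
edge list), optional attribute table (TSV/CSV), the model terms and the
algorithm block; all outputs are TSV with a provenance header (version,
config hash, seed) and an exit status that reflects convergence.  See
the docstring in `src/ergm_ee/cli.py` for the config schema.

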