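"""Parameter estimation: CD-1 initialization, the equilibrium-expectation
(EE) algorithm, its step-size heuristic, and a Robbins-Monro
method-of-moments (MoM) baseline.

The EE algorithm runs a single Metropolis-Hastings chain started at the
observed network and, every ``m`` elementary steps, nudges each
parameter by the signed-square rule

    theta_A  <-  theta_A - K_A * sign(dz_A) * dz_A**2,

where dz_A accumulates the accepted change statistics and therefore
always equals z_A(x) - z_A(x_obs).  Because the expected statistic is
monotonically increasing in its own parameter, this drives the chain
toward the simultaneous fixed point where both the equilibrium drift
and the statistic gap vanish -- the method-of-moments / maximum
likelihood condition E_theta[z(x)] = z(x_obs).  Estimates are trace
averages of theta_A(t) past burn-in.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .diagnostics import check_convergence, estimate_ci, t_ratio
from .graph import Graph
from .model import ModelSpec, encode_terms
from .sampler import mh_run
from .statistics import statistic_vector

logger = logging.getLogger(__name__)

__all__ = [
    "EstimationResult",
    "DivergenceError",
    "cd1_estimate",
    "compute_KA",
    "calibrate_K",
    "ee_fit",
    "ee_update",
    "ee_estimate",
    "mom_estimate",
]

#: Default number of elementary steps between parameter updates.
DEFAULT_M_BETWEEN = 1000
#: Default divergence guard on |theta_A|.
THETA_BOUND = 50.0
#: Finite cap substituted for non-finite CD-1 roots (degenerate data).
CD1_CAP = 25.0


class DivergenceError(RuntimeError):
    """An estimation run left the stable parameter region."""

    def __init__(self, term_label: str, bound: float):
        self.term_label = term_label
        super().__init__(
            f"estimation diverged: |theta[{term_label}]| exceeded {bound}; "
            "the model is likely degenerate for this network"
        )


@dataclass
class EstimationResult:
    """Outcome of an EE or MoM estimation run."""

    theta_hat: np.ndarray
    labels: list[str]
    tau: np.ndarray
    converged: bool
    theta_trace: np.ndarray
    dz_trace: np.ndarray
    z_obs: np.ndarray
    t_B: int
    m: int
    sampler: str
    se: np.ndarray | None = None
    ci95: np.ndarray | None = None
    theta_L: float | None = None
    theta_L_trace: np.ndarray | None = None
    report: str = ""

    def summary(self) -> str:
        lines = [f"{'term':<24s}{'theta':>10s}{'tau':>9s}" + ("" if self.se is None else f"{'SE':>9s}{'95% CI':>22s}")]
        for a, label in enumerate(self.labels):
            row = f"{label:<24s}{self.theta_hat[a]:>10.4f}{self.tau[a]:>9.3f}"
            if self.se is not None:
                lo, hi = self.ci95[a]
                row += f"{self.se[a]:>9.4f}   ({lo:>7.3f}, {hi:>7.3f})"
            lines.append(row)
        if self.theta_L is not None:
            lines.append(f"{'edge (theta_L, aux)':<24s}{self.theta_L:>10.4f}")
        lines.append(f"converged: {self.converged} (sampler={self.sampler}, m={self.m}, t_B index={self.t_B})")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# CD-1 initialization
# ---------------------------------------------------------------------------


def _proposal_drift(dz_batch: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Mean accepted change over proposals from x_obs: (1/B) sum alpha_b dz_b."""
    lp = dz_batch @ theta
    alpha = np.exp(np.minimum(lp, 0.0))
    return (alpha[:, None] * dz_batch).mean(axis=0)


def _sample_dyads(n: int, size: int, rng: np.random.Generator) -> np.ndarray:
    i = rng.integers(0, n, size=size)
    j = rng.integers(0, n - 1, size=size)
    j = np.where(j >= i, j + 1, j)
    return np.column_stack([i, j]).astype(np.int64)


def _all_dyads(n: int) -> np.ndarray:
    iu = np.triu_indices(n, k=1)
    return np.column_stack(iu).astype(np.int64)


def cd1_estimate(
    graph: Graph,
    model: ModelSpec,
    iters: int = 200,
    rng: np.random.Generator | None = None,
    batch: int = 100_000,
    cap: float = CD1_CAP,
    tol: float = 1e-9,
) -> np.ndarray:
    """Contrastive-divergence (one-step) starting values.

    Solves the condition that the expected accepted change over single
    MH proposals from the observed network vanishes for every term:

        g_A(theta) = mean over proposed dyads of alpha(theta) * dz_A = 0.

    All dyads are enumerated when there are at most ``batch`` of them
    (the usual case; the system is then solved exactly), otherwise a
    seeded uniform sample of ``batch`` dyads is used.  The root is found
    by damped Newton iteration on the one-sided Jacobian
    J_AB = mean[1(lp < 0) * exp(lp) * dz_A * dz_B], which is positive
    semi-definite by the exponential-family monotonicity.  The observed
    graph is never modified.  A root escaping to infinity (e.g. an
    empty or complete network with an edge term) is flagged with a
    warning and capped at +/-``cap``.
    """
    rng = np.random.default_rng() if rng is None else rng
    kinds, lams, attrs = encode_terms(graph, model.terms)
    # always start from the null model: the solution along directions the
    # data barely identify is anchored at zero, never at model.theta
    # (which may hold generating values in simulation studies)
    theta = np.zeros(model.n_terms)
    D = graph.num_dyads
    if D <= batch:
        dyads = _all_dyads(graph.n)
    else:
        dyads = _sample_dyads(graph.n, batch, rng)
    dz = _kernels.batch_delta(graph.adj, graph.deg, kinds, lams, attrs, dyads)
    scale = np.maximum((dz**2).mean(axis=0), 1e-12)
    gnorm_prev = np.inf
    for _ in range(iters):
        lp = dz @ theta
        alpha = np.exp(np.minimum(lp, 0.0))
        g = (alpha[:, None] * dz).mean(axis=0)
        gnorm = float(np.abs(g / scale).max())
        if gnorm < tol:
            break
        w = np.where(lp <= 0.0, alpha, 0.0)
        J = (w[:, None] * dz).T @ dz / dz.shape[0]
        # minimum-norm Newton step: directions the drift system barely
        # identifies (near-collinear statistics) are truncated rather than
        # ridge-inverted, so the solution stays anchored at the start
        # instead of running down a flat valley
        ev, U = np.linalg.eigh(J)
        keep = ev > max(ev.max(), 1e-300) * 1e-6
        if not keep.any():
            break
        step = U[:, keep] @ ((U[:, keep].T @ g) / ev[keep])
        damp = 1.0 if gnorm < gnorm_prev else 0.5
        limit = np.abs(step).max()
        if limit > 2.0:  # cap Newton steps in flat (near-degenerate) regions
            step *= 2.0 / limit
        theta = np.clip(theta - damp * step, -cap, cap)
        gnorm_prev = gnorm
    runaway = np.abs(theta) >= 0.8 * cap  # drift far past any stable ERGM scale
    if runaway.any():
        bad = [model.labels[a] for a in np.flatnonzero(runaway)]
        warnings.warn(
            f"CD-1 root is non-finite for term(s) {bad} (degenerate observed "
            f"statistics); capped at +/-{cap}"
        )
        theta = np.clip(theta, -cap, cap)
    return theta


# ---------------------------------------------------------------------------
# EE step size
# ---------------------------------------------------------------------------


def compute_KA(
    graph: Graph,
    model: ModelSpec,
    theta0,
    probe_steps: int = 20000,
    rng: np.random.Generator | None = None,
    m: int = DEFAULT_M_BETWEEN,
    k_scale: float = 1e-4,
    k_floor: float = 1e-6,
) -> np.ndarray:
    """Per-term EE step sizes K_A = k_scale * (d DeltaZ_A / d theta_A)^-2.

    The derivative of the expected per-window accumulated change with
    respect to theta_A is estimated from ``probe_steps`` random
    proposals at the observed network:

        d/dtheta_A ~= m * mean_b[ 1(lp_b <= 0) * exp(lp_b) * dz_{bA}^2 ],

    (lp = theta . dz) which is the one-sided derivative of the expected
    accepted change, guaranteed non-negative, scaled by the m elementary
    steps between parameter updates.  A vanishing estimate falls back to
    the configured floor with a warning.
    """
    rng = np.random.default_rng() if rng is None else rng
    theta0 = np.asarray(theta0, dtype=float)
    if not np.all(np.isfinite(theta0)):
        raise ValueError("theta0 must be finite")
    kinds, lams, attrs = encode_terms(graph, model.terms)
    dyads = _sample_dyads(graph.n, probe_steps, rng)
    dz = _kernels.batch_delta(graph.adj, graph.deg, kinds, lams, attrs, dyads)
    lp = dz @ theta0
    w = np.where(lp <= 0.0, np.exp(np.minimum(lp, 0.0)), 0.0)
    deriv = m * (w[:, None] * dz**2).mean(axis=0)
    K = np.empty(model.n_terms)
    for a in range(model.n_terms):
        if deriv[a] <= 1e-12:
            warnings.warn(
                f"probe produced no variation for term '{model.labels[a]}'; "
                f"using K floor {k_floor}"
            )
            K[a] = k_floor
        else:
            K[a] = k_scale / deriv[a] ** 2
    return K


def calibrate_K(
    graph: Graph,
    model: ModelSpec,
    theta0,
    rng: np.random.Generator | None = None,
    m: int = DEFAULT_M_BETWEEN,
    windows: int = 50,
    gain: float = 0.02,
    k_floor: float = 1e-6,
) -> np.ndarray:
    """Probe-run step-size calibration (the pipeline default).

    Runs a short MH probe (``windows`` update windows of ``m`` steps)
    from a copy of the observed network at ``theta0`` and sets

        K_A = gain / ( Var_probe(z_A) * SD_probe(w_A) ),

    where Var_probe(z_A) is the probe-trace variance of the statistic
    (the exponential-family response dE[z_A]/dtheta_A) and w_A the
    per-window innovation z_A(t) - z_A(t-m).  This makes ``gain`` the
    approximate fraction of a typical statistic deviation restored per
    update window, a dimensionless feedback strength: K values above
    ~1/(Var * SD_w) destabilize the signed-square feedback loop, while
    far smaller values leave the statistics unconstrained over a
    desk-scale run.  The default gain 0.02 keeps about two decades of
    stability margin and holds the convergence t-ratios well inside the
    |tau| < 0.1 rule for million-step runs; repeated-estimation studies
    use a smaller gain (see
    :class:`~ergm_ee.synthetic.RecoveryDesign`), which minimizes the
    small skew-induced offset of the signed-square update at the cost
    of slower mixing.  Terms with no probe variation fall back to
    ``k_floor``.
    """
    rng = np.random.default_rng() if rng is None else rng
    theta0 = np.asarray(theta0, dtype=float)
    g = graph.copy()
    kinds, lams, attrs = encode_terms(g, model.terms)
    z = statistic_vector(g, model)
    seed = int(rng.integers(1, 2**31 - 1))
    if model.fixed_density:
        # probe with the same fixed-density dynamics the estimator will use
        L_obs = g.num_edges
        edges = np.zeros((max(L_obs, 1), 2), dtype=np.int64)
        for k, (i, j) in enumerate(g.edges()):
            edges[k] = (i, j)
        theta_L0 = math.log(L_obs / (g.num_dyads - L_obs + 1.0)) if 0 < L_obs < g.num_dyads else 0.0
        _, dz_tr, _, _ = _kernels.ee_ifd(
            g.adj, g.deg, kinds, lams, attrs, theta0.copy(),
            np.zeros(model.n_terms), edges, L_obs, theta_L0, 0.1,
            windows * m, m, seed, 1e18, 0,
        )
        trace = z[None, :] + dz_tr
    else:
        trace, _ = _kernels.mh_basic(g.adj, g.deg, kinds, lams, attrs,
                                     theta0.copy(), z, windows * m, m, seed)
    var_z = trace.var(axis=0, ddof=1)
    sd_w = np.diff(trace, axis=0).std(axis=0, ddof=1)
    denom = var_z * sd_w
    K = np.empty(model.n_terms)
    for a in range(model.n_terms):
        if denom[a] <= 1e-12:
            warnings.warn(
                f"probe run produced no variation for term '{model.labels[a]}'; "
                f"using K floor {k_floor}"
            )
            K[a] = k_floor
        else:
            K[a] = gain / denom[a]
    return K


def ee_update(theta_A: float, dz_A: float, K_A: float) -> float:
    """One signed-square parameter update: theta_A - K_A*sign(dz_A)*dz_A^2."""
    if K_A <= 0.0:
        raise ValueError("K_A must be positive")
    if dz_A == 0.0:
        return theta_A
    return theta_A - math.copysign(K_A * dz_A * dz_A, dz_A)


# ---------------------------------------------------------------------------
# EE estimation
# ---------------------------------------------------------------------------


def ee_estimate(
    graph: Graph,
    model: ModelSpec,
    theta0,
    K,
    M: int,
    m: int = DEFAULT_M_BETWEEN,
    rng: np.random.Generator | None = None,
    sampler: str = "basic",
    theta_bound: float = THETA_BOUND,
    t_b_frac: float = 0.5,
    k_half_step: int = 0,
    K_L: float = 0.1,
    theta_L0: float | None = None,
    compute_se: bool = False,
    se_sim_steps: int | None = None,
) -> EstimationResult:
    """Equilibrium-expectation estimation (the graph IS modified in place).

    Runs ``M`` elementary sampler steps from the observed network at
    ``theta0``; every accepted move adds its change statistics to the
    accumulator dz = z(x) - z(x_obs), and every ``m`` steps each
    parameter receives the signed-square update scaled by ``K``.  With
    K = 0 the parameter trace is constant and the run is plain MH.
    Estimates are averages of theta_A(t) over t > t_B (last
    ``1 - t_b_frac`` fraction of checkpoints by default); convergence
    requires all |tau_A| < 0.1 plus trace stationarity.

    ``sampler`` is ``"basic"`` or ``"ifd"``; the IFD path holds the edge
    count at its observed value and adapts the auxiliary edge parameter
    theta_L (initialized at the observed-density logit unless given),
    reported in ``result.theta_L``.  ``k_half_step`` > 0 halves all step
    sizes at that elementary step for a lower-variance final phase.
    """
    rng = np.random.default_rng() if rng is None else rng
    if m < 1 or M % m != 0:
        raise ValueError("need m >= 1 and M a multiple of m")
    theta0 = np.asarray(theta0, dtype=float)
    K = np.asarray(K, dtype=float)
    if K.shape == ():
        K = np.full(model.n_terms, float(K))
    if (K < 0).any():
        raise ValueError("K must be non-negative")
    kinds, lams, attrs = encode_terms(graph, model.terms)
    z_obs = statistic_vector(graph, model)
    theta = theta0.copy()
    seed = int(rng.integers(1, 2**31 - 1))
    theta_L_trace = None
    theta_L_hat = None
    if sampler == "basic":
        theta_trace, dz_trace, diverged = _kernels.ee_basic(
            graph.adj, graph.deg, kinds, lams, attrs, theta, K,
            M, m, seed, theta_bound, k_half_step,
        )
    elif sampler == "ifd":
        if any(t.kind == "edge" for t in model.terms):
            raise ValueError("IFD handles the edge count via theta_L; drop the edge term")
        L_obs = graph.num_edges
        if L_obs < 1 or L_obs >= graph.num_dyads:
            raise ValueError("IFD needs 1 <= observed edge count < number of dyads")
        if theta_L0 is None:
            theta_L0 = math.log(L_obs / (graph.num_dyads - L_obs + 1.0))
        edges = np.zeros((L_obs, 2), dtype=np.int64)
        for k, (i, j) in enumerate(graph.edges()):
            edges[k] = (i, j)
        theta_trace, dz_trace, theta_L_trace, diverged = _kernels.ee_ifd(
            graph.adj, graph.deg, kinds, lams, attrs, theta, K,
            edges, L_obs, float(theta_L0), float(K_L),
            M, m, seed, theta_bound, k_half_step,
        )
    else:
        raise ValueError(f"unknown sampler '{sampler}'")
    graph.num_edges = int(graph.deg.sum()) // 2
    if diverged >= 0:
        label = model.labels[diverged] if diverged < model.n_terms else "edge (theta_L)"
        raise DivergenceError(label, theta_bound)

    n_upd = theta_trace.shape[0]
    t_B = int(n_upd * t_b_frac)
    theta_hat = theta_trace[t_B:].mean(axis=0)
    z_trace = z_obs[None, :] + dz_trace
    tau = t_ratio(z_trace[t_B:], z_obs)
    if theta_L_trace is not None:
        theta_L_hat = float(theta_L_trace[t_B:].mean())
    result = EstimationResult(
        theta_hat=theta_hat, labels=list(model.labels), tau=tau, converged=False,
        theta_trace=theta_trace, dz_trace=dz_trace, z_obs=z_obs, t_B=t_B, m=m,
        sampler=sampler, theta_L=theta_L_hat, theta_L_trace=theta_L_trace,
    )
    result.converged, result.report = check_convergence(result)
    if compute_se:
        sim_steps = se_sim_steps if se_sim_steps is not None else max(M // 4, 50 * m)
        se_model = model.with_theta(theta_hat)
        result.se, result.ci95 = estimate_ci(graph, se_model, theta_hat, sim_steps, rng)
    return result


# ---------------------------------------------------------------------------
# Method-of-moments baseline (three-phase Robbins-Monro)
# ---------------------------------------------------------------------------


@dataclass
class MoMSettings:
    """Tuning of the three-phase stochastic-approximation baseline."""

    subphases: int = 4
    iters0: int = 10           # iterations in subphase 1; doubles each subphase
    gain0: float = 0.5         # initial gain a_1; halves each subphase
    burnin_steps: int | None = None    # default 5 * num_dyads
    steps_per_iter: int | None = None  # chain advance per draw; default num_dyads // 2
    n_check: int = 150         # phase-3 sample size
    t_threshold: float = 0.1
    theta_bound: float = THETA_BOUND
    max_rounds: int = 2


def mom_estimate(
    graph: Graph,
    model: ModelSpec,
    theta0,
    rng: np.random.Generator | None = None,
    settings: MoMSettings | None = None,
) -> EstimationResult:
    """Classic three-phase Robbins-Monro method-of-moments estimate.

    Phase 1 calibrates a diagonal scaling matrix D from the statistic
    variances of a probe run at ``theta0``; phase 2 iterates
    theta <- theta - a_r * D^-1 * (z(x_sim) - z(x_obs)) over subphases
    with halving gains, each draw an equilibrated MH state, with
    Polyak-Ruppert averaging over the final subphase; phase 3 simulates
    at the estimate and checks the Snijders t-statistics.  Rounds of
    phases 2-3 repeat up to ``max_rounds`` times; persistent
    non-convergence is reported via ``converged=False`` with the final
    t-statistics.  The observed graph is left unmodified (the chain
    runs on a working copy).
    """
    rng = np.random.default_rng() if rng is None else rng
    s = settings or MoMSettings()
    z_obs = statistic_vector(graph, model)
    work = graph.copy()
    D_dyads = graph.num_dyads
    burnin = s.burnin_steps if s.burnin_steps is not None else 5 * D_dyads
    advance = s.steps_per_iter if s.steps_per_iter is not None else max(1000, D_dyads // 2)
    theta = np.asarray(theta0, dtype=float).copy()

    # phase 1: equilibrate and calibrate the diagonal derivative matrix
    mh_run(work, model.with_theta(theta), burnin, rng=rng)
    probe, _ = mh_run(work, model.with_theta(theta), 40 * max(1, advance // 10),
                      thin=max(1, advance // 10), rng=rng)
    D = probe.var(axis=0, ddof=1)
    D[D <= 0] = 1.0

    theta_rows = []
    tstats = np.full(model.n_terms, np.inf)
    check_trace = None
    for _round in range(s.max_rounds):
        # phase 2: subphases with halving gains
        avg = np.zeros_like(theta)
        n_avg = 0
        for r in range(s.subphases):
            a_r = s.gain0 / 2**r
            iters = s.iters0 * 2**r
            for _ in range(iters):
                trace, _ = mh_run(work, model.with_theta(theta), advance,
                                  thin=advance, rng=rng)
                z_sim = trace[-1]
                theta = np.clip(theta - a_r * (z_sim - z_obs) / D,
                                -s.theta_bound, s.theta_bound)
                theta_rows.append(theta.copy())
                if r == s.subphases - 1:
                    avg += theta
                    n_avg += 1
        theta = avg / n_avg  # Polyak-Ruppert average of the final subphase
        # phase 3: convergence check by independent simulation at theta
        mh_run(work, model.with_theta(theta), burnin, rng=rng)
        check_trace, _ = mh_run(work, model.with_theta(theta), s.n_check * advance,
                                thin=advance, rng=rng)
        diff = check_trace.mean(axis=0) - z_obs
        sd = check_trace.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf
        tstats = diff / sd
        if np.all(np.abs(tstats) < s.t_threshold):
            break
    converged = bool(np.all(np.abs(tstats) < s.t_threshold))
    if not converged:
        logger.warning("MoM did not converge: final t-statistics %s", tstats)
    theta_trace = np.asarray(theta_rows)
    n_upd = theta_trace.shape[0]
    t_B = max(0, n_upd - n_avg)  # average window = final subphase
    return EstimationResult(
        theta_hat=theta, labels=list(model.labels), tau=tstats, converged=converged,
        theta_trace=theta_trace, dz_trace=check_trace - z_obs, z_obs=z_obs,
        t_B=t_B, m=advance, sampler="basic",
    )


# ---------------------------------------------------------------------------
# Convenience pipeline
# ---------------------------------------------------------------------------


def ee_fit(
    graph: Graph,
    model: ModelSpec,
    M: int = 1_000_000,
    m: int = DEFAULT_M_BETWEEN,
    rng: np.random.Generator | None = None,
    sampler: str = "basic",
    gain: float = 0.02,
    copy: bool = True,
    **ee_kwargs,
) -> EstimationResult:
    """CD-1 start, probe-run K calibration, then EE estimation.

    The standard estimation pipeline in one call.  With ``copy=True``
    (default) the observed graph is left untouched; the EE chain runs on
    a working copy.
    """
    rng = np.random.default_rng() if rng is None else rng
    theta0 = cd1_estimate(graph, model, rng=rng)
    K = calibrate_K(graph, model, theta0, rng=rng, m=m, gain=gain)
    work = graph.copy() if copy else graph
    return ee_estimate(work, model, theta0, K, M=M, m=m, rng=rng,
                       sampler=sampler, **ee_kwargs)
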