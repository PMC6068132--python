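"""Convergence assessment and uncertainty quantification.

The primary convergence check is the cheap t-ratio computed on the
estimation run's own statistic trace,

    tau_A = ( mean z_A(t > t_B) - z_A(x_obs) ) / SD( z_A(t > t_B) ),

with a converged fit requiring |tau_A| < 0.1 for every term plus a
stationary parameter trace.  The expensive external check is the
classical t-statistic computed from an independent simulation at the
final estimate (threshold 0.3).  Standard errors come from the
exponential-family identity: at the MLE the observed information equals
the covariance Sigma of the statistic vector under the fitted model, so
SE_A = sqrt( (Sigma^-1)_AA ).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .graph import Graph
from .model import ModelSpec
from .sampler import mh_run
from .statistics import statistic_vector

__all__ = [
    "Trace",
    "DegenerateTraceError",
    "t_ratio",
    "stationarity_gap",
    "trend_excess",
    "check_convergence",
    "estimate_ci",
    "snijders_tstat",
]

#: Convergence threshold on |tau_A|.
TAU_THRESHOLD = 0.1
#: Threshold on the independent-simulation t-statistics.
TSTAT_THRESHOLD = 0.3


class DegenerateTraceError(ValueError):
    """A trace column has zero variation but its mean misses the target:
    the chain is stuck, which must not be mistaken for convergence."""


@dataclass
class Trace:
    """A sequence of per-checkpoint statistic (or parameter) vectors."""

    values: np.ndarray  # (n_checkpoints, n_terms)
    t_B: int = 0
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not 0 <= self.t_B < self.values.shape[0]:
            raise ValueError(f"t_B={self.t_B} out of range for trace of length {self.values.shape[0]}")
        if self.labels and len(self.labels) != self.values.shape[1]:
            raise ValueError("labels do not align with trace columns")

    @property
    def post(self) -> np.ndarray:
        return self.values[self.t_B:]


def t_ratio(trace, z_obs) -> np.ndarray:
    """Per-term tau_A = (mean z_A(t > t_B) - z_A(x_obs)) / SD(z_A(t > t_B)).

    ``trace`` may be a :class:`Trace` or a plain (n, p) array (t_B = 0).
    Sample SD uses the n-1 denominator.  A column with zero SD whose
    mean equals the observed value yields tau = 0; zero SD with a
    mismatched mean raises :class:`DegenerateTraceError`.
    """
    vals = trace.post if isinstance(trace, Trace) else np.atleast_2d(np.asarray(trace, float))
    z_obs = np.asarray(z_obs, dtype=float)
    if vals.shape[0] < 2:
        raise ValueError("need at least 2 post-burn-in checkpoints")
    diff = vals.mean(axis=0) - z_obs
    sd = vals.std(axis=0, ddof=1)
    tau = np.zeros_like(diff)
    zero = sd == 0.0
    if np.any(zero & (diff != 0.0)):
        bad = int(np.flatnonzero(zero & (diff != 0.0))[0])
        raise DegenerateTraceError(
            f"trace column {bad} is constant but off target by {diff[bad]:g} (stuck chain)"
        )
    tau[~zero] = diff[~zero] / sd[~zero]
    return tau


def stationarity_gap(trace_col: np.ndarray) -> tuple[float, float]:
    """Half-trace mean gap and its standard error for one parameter series.

    Returns (|mean(second half) - mean(first half)|, SE of the
    difference).  The SE comes from the scatter of the four quarter
    means, which absorbs autocorrelation at the scale that actually
    moves the half means (a strongly autocorrelated but stationary
    trace gets an honestly wide error rather than a spurious drift
    flag).
    """
    x = np.asarray(trace_col, dtype=float)
    half = len(x) // 2
    gap = abs(x[half:].mean() - x[:half].mean())
    nq = len(x) // 4 * 4
    if nq < 4:
        return gap, 0.0
    q = x[:nq].reshape(4, -1).mean(axis=1)
    se_half = float(q.std(ddof=1)) / np.sqrt(2.0)  # a half is two quarters
    return gap, float(se_half * np.sqrt(2.0))


def trend_excess(trace_col: np.ndarray) -> float:
    """Fitted linear trend over the trace, in units of the residual SD.

    A stationary (possibly slowly wandering) trace keeps this below ~3;
    a systematically drifting one grows without bound.
    """
    x = np.asarray(trace_col, dtype=float)
    n = len(x)
    if n < 4:
        return 0.0
    t = np.arange(n, dtype=float)
    slope, intercept = np.polyfit(t, x, 1)
    resid_sd = float((x - intercept - slope * t).std(ddof=1))
    if resid_sd == 0.0:
        return 0.0 if slope == 0.0 else np.inf
    return float(abs(slope) * n / resid_sd)


def check_convergence(result) -> tuple[bool, str]:
    """Assess an :class:`~ergm_ee.estimation.EstimationResult`.

    Converged iff (i) all |tau_A| < 0.1 and (ii) every parameter trace
    is stationary past burn-in: the half-trace means differ by less
    than 2 standard errors of the difference AND the fitted linear
    trend stays within 3 residual SDs over the averaging window.
    Always returns (flag, report).
    """
    lines = []
    ok = True
    labels = result.labels
    for a, label in enumerate(labels):
        tau = result.tau[a]
        tau_ok = abs(tau) < TAU_THRESHOLD
        theta_post = result.theta_trace[result.t_B:, a]
        gap, se = stationarity_gap(theta_post)
        trend = trend_excess(theta_post)
        stat_ok = (bool(gap < 2.0 * se) if se > 0 else bool(gap == 0.0)) and trend < 3.0
        ok &= tau_ok and stat_ok
        flagwords = []
        if not tau_ok:
            flagwords.append(f"|tau|={abs(tau):.3f} >= {TAU_THRESHOLD}")
        if not stat_ok:
            flagwords.append(
                f"theta drift: half-gap {gap:.4g} vs 2*SE {2 * se:.4g}, "
                f"trend {trend:.2f} (limit 3)"
            )
        status = "ok" if tau_ok and stat_ok else "FAIL " + "; ".join(flagwords)
        lines.append(f"  {label:<24s} tau={tau:+.4f}  {status}")
    header = "converged" if ok else "NOT converged"
    return ok, f"{header} (|tau| < {TAU_THRESHOLD} and stationary theta required)\n" + "\n".join(lines)


def _simulate_stats(
    graph: Graph,
    model: ModelSpec,
    theta,
    sim_steps: int,
    rng: np.random.Generator,
    burnin_frac: float = 0.2,
    n_samples: int = 500,
) -> np.ndarray:
    """Equilibrated statistic sample at ``theta`` from a copy of ``graph``."""
    g = graph.copy()
    burnin = int(sim_steps * burnin_frac)
    thin = max(1, (sim_steps - burnin) // n_samples)
    trace, _ = mh_run(g, model.with_theta(theta), sim_steps, burnin=burnin, thin=thin, rng=rng)
    return trace


def estimate_ci(
    graph: Graph,
    model: ModelSpec,
    theta_hat,
    sim_steps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated-information standard errors and 95% intervals at theta_hat.

    Simulates at theta_hat, takes the statistic covariance Sigma as the
    observed Fisher information (exponential-family identity) and
    returns (se, ci95) with se_A = sqrt((Sigma^-1)_AA) and
    ci95 = theta_hat +/- 1.96 * se.  A singular Sigma falls back to the
    pseudo-inverse with a warning.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    if not np.all(np.isfinite(theta_hat)):
        raise ValueError("theta_hat must be finite")
    sample = _simulate_stats(graph, model, theta_hat, sim_steps, rng)
    sigma = np.atleast_2d(np.cov(sample, rowvar=False))
    try:
        info_inv = np.linalg.inv(sigma)
    except np.linalg.LinAlgError:
        warnings.warn("singular statistic covariance; using pseudo-inverse")
        info_inv = np.linalg.pinv(sigma)
    diag = np.diag(info_inv).copy()
    if np.any(diag < 0):
        warnings.warn("non-positive variance estimate; using pseudo-inverse")
        diag = np.abs(np.diag(np.linalg.pinv(sigma)))
    se = np.sqrt(diag)
    ci95 = np.column_stack([theta_hat - 1.96 * se, theta_hat + 1.96 * se])
    return se, ci95


def snijders_tstat(
    graph_obs: Graph,
    model: ModelSpec,
    theta_hat,
    sim_steps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Independent-simulation t-statistics at theta_hat.

    t_A = (mean simulated z_A - z_A(x_obs)) / SD(simulated z_A); the
    expensive external convergence check (threshold 0.3), simulated by
    MH from a copy of the observed graph.
    """
    z_obs = statistic_vector(graph_obs, model)
    sample = _simulate_stats(graph_obs, model, theta_hat, sim_steps, rng)
    return t_ratio(sample, z_obs)
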