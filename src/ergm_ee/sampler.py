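"""Metropolis-Hastings simulation of pi(x, theta).

Two proposal distributions are provided:

* **Basic** -- toggle a dyad drawn uniformly from all N(N-1)/2 dyads
  (symmetric, q-ratio 1).
* **IFD** (improved fixed density) -- the edge count is constrained to
  {L_obs - 1, L_obs} by alternating uniform deletions (at L_obs) and
  uniform insertions (at L_obs - 1), with the exact proposal-count
  q-ratio and an adapted auxiliary edge parameter theta_L.

Acceptance is computed in log space from the change statistics; the
normalizing constant k(theta) never appears.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .graph import Graph
from .model import ModelSpec, encode_terms
from .statistics import change_statistics, statistic_vector

__all__ = [
    "SamplerOutcome",
    "propose_basic",
    "acceptance_probability",
    "mh_run",
    "ifd_step",
    "ifd_run",
]


@dataclass
class SamplerOutcome:
    """Record of one elementary sampler step."""

    dyads: list[tuple[int, int]]
    delta_z: np.ndarray
    alpha: float
    accepted: bool
    q_ratio: float = 1.0


def propose_basic(graph: Graph, rng: np.random.Generator) -> tuple[int, int]:
    """Uniformly draw one of the N(N-1)/2 dyads (symmetric proposal)."""
    n = graph.n
    if n < 2:
        raise ValueError("basic proposal needs at least 2 nodes")
    i = int(rng.integers(n))
    j = int(rng.integers(n - 1))
    if j >= i:
        j += 1
    return (i, j)


def acceptance_probability(delta_z, theta, q_ratio: float = 1.0) -> float:
    """MH acceptance min{1, q_ratio * exp(theta . delta_z)}, in log space."""
    delta_z = np.asarray(delta_z, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if delta_z.shape != theta.shape:
        raise ValueError(f"shape mismatch: delta_z {delta_z.shape} vs theta {theta.shape}")
    lp = math.log(q_ratio) + float(theta @ delta_z)
    return 1.0 if lp >= 0.0 else math.exp(lp)


def mh_run(
    graph: Graph,
    model: ModelSpec,
    steps: int,
    burnin: int = 0,
    thin: int = 1,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, Graph]:
    """Run ``steps`` Basic-sampler steps, evolving ``graph`` in place.

    Returns the statistic trace ``z_A(t)`` recorded every ``thin`` steps
    for t > burnin (one row per record, columns ordered as the model
    terms) together with the evolved graph.  Expected statistics under
    pi(x, theta) are estimable as column means of the trace.
    """
    if not (steps >= burnin >= 0):
        raise ValueError(f"need steps >= burnin >= 0, got {steps}, {burnin}")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    if graph.n < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng() if rng is None else rng
    kinds, lams, attrs = encode_terms(graph, model.terms)
    z = statistic_vector(graph, model)
    seed = int(rng.integers(1, 2**31 - 1))
    trace, _ = _kernels.mh_basic(
        graph.adj, graph.deg, kinds, lams, attrs,
        np.asarray(model.theta, dtype=float), z, steps, thin, seed,
    )
    graph.num_edges = int(graph.deg.sum()) // 2
    keep = (np.arange(1, trace.shape[0] + 1) * thin) > burnin
    return trace[keep], graph


def ifd_step(
    graph: Graph,
    model: ModelSpec,
    theta_L: float,
    L_obs: int,
    rng: np.random.Generator,
    k_adapt: float = 0.0,
) -> tuple[SamplerOutcome, float]:
    """One elementary IFD step; evolves ``graph`` in place.

    A deletion over the current edges is proposed when L = L_obs and an
    insertion over the current non-edges when L = L_obs - 1; theta_L
    enters the acceptance as an edge term.  With ``k_adapt`` > 0 the
    auxiliary parameter is nudged by the signed-square rule applied to
    the post-move occupancy indicator (at L_obs counts +1/2, below
    counts -1/2), whose long-run fixed point balances time between the
    two levels.
    """
    L = graph.num_edges
    if L not in (L_obs, L_obs - 1):
        raise ValueError(f"IFD requires edge count in {{{L_obs - 1}, {L_obs}}}, got {L}")
    D = graph.num_dyads
    q_del = L_obs / (D - L_obs + 1.0)
    if L == L_obs:
        ii, jj = np.nonzero(np.triu(graph.adj, k=1))
        idx = int(rng.integers(len(ii)))
        i, j = int(ii[idx]), int(jj[idx])
        dL = -1.0
        q_ratio = q_del
    else:
        while True:
            i = int(rng.integers(graph.n))
            j = int(rng.integers(graph.n))
            if i != j and not graph.adj[i, j]:
                break
        dL = 1.0
        q_ratio = 1.0 / q_del
    dz = change_statistics(graph, model, i, j)
    lp = math.log(q_ratio) + float(model.theta @ dz) + theta_L * dL
    alpha = 1.0 if lp >= 0.0 else math.exp(lp)
    accepted = bool(rng.random() < alpha)
    if accepted:
        graph.toggle_edge(i, j)
    if k_adapt > 0.0:
        d_occ = 0.5 if graph.num_edges == L_obs else -0.5
        theta_L -= k_adapt * math.copysign(d_occ * d_occ, d_occ)
    return SamplerOutcome([(i, j)], dz, alpha, accepted, q_ratio), theta_L


def ifd_run(
    graph: Graph,
    model: ModelSpec,
    steps: int,
    rng: np.random.Generator,
    theta_L0: float | None = None,
    K_L: float = 0.1,
    m: int = 1000,
) -> tuple[np.ndarray, np.ndarray, Graph]:
    """Run the IFD sampler at fixed theta with adapted theta_L.

    The graph's current edge count is taken as the constrained L_obs.
    Returns (z_trace, theta_L_trace, graph) with one row per ``m``
    elementary steps.  The trace average of theta_L estimates the edge
    parameter consistent with the observed density.
    """
    if model.n_terms and any(t.kind == "edge" for t in model.terms):
        raise ValueError("IFD handles the edge count via theta_L; drop the edge term")
    L_obs = graph.num_edges
    if L_obs < 1 or L_obs >= graph.num_dyads:
        raise ValueError("IFD needs 1 <= L_obs < number of dyads")
    if theta_L0 is None:
        theta_L0 = math.log(L_obs / (graph.num_dyads - L_obs + 1.0))
    kinds, lams, attrs = encode_terms(graph, model.terms)
    z_obs = statistic_vector(graph, model)
    edges = np.zeros((L_obs, 2), dtype=np.int64)
    for k, (i, j) in enumerate(graph.edges()):
        edges[k, 0] = i
        edges[k, 1] = j
    seed = int(rng.integers(1, 2**31 - 1))
    theta = np.asarray(model.theta, dtype=float).copy()
    K = np.zeros(model.n_terms)
    _, dz_trace, thetaL_trace, diverged = _kernels.ee_ifd(
        graph.adj, graph.deg, kinds, lams, attrs, theta, K,
        edges, L_obs, float(theta_L0), float(K_L),
        steps, m, seed, 1e18, 0,
    )
    graph.num_edges = int(graph.deg.sum()) // 2
    return z_obs + dz_trace, thetaL_trace, graph
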