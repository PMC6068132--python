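"""Numba-jitted elementary-step kernels for the samplers and estimators.

All kernels operate on the flat encoding produced by
:func:`ergm_ee.model.encode_terms`:

* ``adj``   -- (N, N) boolean adjacency matrix (modified in place),
* ``deg``   -- (N,) int64 degree vector (kept in sync),
* ``kinds`` -- int64 statistic codes (see ``model.KINDS`` order),
* ``lams``  -- float64 decay constants (0 where unused),
* ``attrs`` -- (n_terms, N) int64 attribute rows (0 where unused).

Change statistics are computed locally: the cost of a toggle depends on
the degrees and shared partners of the two endpoints, never on a full
recount.  The kernels seed numpy's legacy RNG internally, so every run
is reproducible from a single integer seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# statistic codes, matching model.KINDS order
EDGE = 0
ISOLATES = 1
ALT_STAR = 2
ALT_TWOPATH = 3
ALT_TRIANGLE = 4
ACTIVITY = 5
INTERACTION = 6
MISMATCH = 7


@njit(cache=True)
def _shared_partners(adj, u, v):
    n = adj.shape[0]
    c = 0
    for k in range(n):
        if adj[u, k] and adj[v, k]:
            c += 1
    return c


@njit(cache=True)
def delta_add(adj, deg, i, j, kinds, lams, attrs, out):
    """Change in each statistic when the absent edge {i, j} is added.

    ``adj`` must not contain the edge; it is not modified.
    """
    n = adj.shape[0]
    for t in range(kinds.shape[0]):
        k = kinds[t]
        if k == EDGE:
            out[t] = 1.0
        elif k == ISOLATES:
            d = 0.0
            if deg[i] == 0:
                d -= 1.0
            if deg[j] == 0:
                d -= 1.0
            out[t] = d
        elif k == ALT_STAR:
            lam = lams[t]
            r = 1.0 - 1.0 / lam
            out[t] = lam * (2.0 - r ** deg[i] - r ** deg[j])
        elif k == ALT_TWOPATH:
            lam = lams[t]
            r = 1.0 - 1.0 / lam
            s = 0.0
            for kk in range(n):
                if adj[j, kk] and kk != i:
                    s += r ** _shared_partners(adj, i, kk)
                if adj[i, kk] and kk != j:
                    s += r ** _shared_partners(adj, j, kk)
            out[t] = s
        elif k == ALT_TRIANGLE:
            lam = lams[t]
            r = 1.0 - 1.0 / lam
            sp_ij = 0
            s = 0.0
            for kk in range(n):
                if adj[i, kk] and adj[j, kk]:
                    sp_ij += 1
                    s += r ** _shared_partners(adj, i, kk)
                    s += r ** _shared_partners(adj, j, kk)
            out[t] = lam * (1.0 - r ** sp_ij) + s
        elif k == ACTIVITY:
            out[t] = attrs[t, i] + attrs[t, j]
        elif k == INTERACTION:
            out[t] = attrs[t, i] * attrs[t, j]
        else:  # MISMATCH
            out[t] = 1.0 if attrs[t, i] != attrs[t, j] else 0.0


@njit(cache=True)
def delta_toggle(adj, deg, i, j, kinds, lams, attrs, out):
    """Change in each statistic for toggling dyad {i, j} from its current state.

    Adding a missing edge gives the positive contributions; removing an
    existing edge gives the exact negation evaluated on the graph
    without the edge.  ``adj``/``deg`` are restored before returning.
    """
    p = kinds.shape[0]
    if adj[i, j]:
        adj[i, j] = False
        adj[j, i] = False
        deg[i] -= 1
        deg[j] -= 1
        delta_add(adj, deg, i, j, kinds, lams, attrs, out)
        for t in range(p):
            out[t] = -out[t]
        adj[i, j] = True
        adj[j, i] = True
        deg[i] += 1
        deg[j] += 1
    else:
        delta_add(adj, deg, i, j, kinds, lams, attrs, out)


@njit(cache=True)
def batch_delta(adj, deg, kinds, lams, attrs, dyads):
    """Toggle change statistics for each dyad in ``dyads`` (B, 2); graph unchanged."""
    B = dyads.shape[0]
    p = kinds.shape[0]
    out = np.empty((B, p))
    row = np.empty(p)
    for b in range(B):
        delta_toggle(adj, deg, dyads[b, 0], dyads[b, 1], kinds, lams, attrs, row)
        for t in range(p):
            out[b, t] = row[t]
    return out


@njit(cache=True)
def mh_basic(adj, deg, kinds, lams, attrs, theta, z, steps, record_every, seed):
    """Metropolis-Hastings with the Basic single-toggle proposal.

    Evolves ``adj``/``deg``/``z`` in place for ``steps`` elementary
    steps; records ``z`` every ``record_every`` steps.  Returns the
    (steps // record_every, p) statistic trace and the accept count.
    """
    np.random.seed(seed)
    n = adj.shape[0]
    p = kinds.shape[0]
    n_rec = steps // record_every
    trace = np.empty((n_rec, p))
    dz = np.empty(p)
    r = 0
    accepts = 0
    for step in range(steps):
        i = np.random.randint(0, n)
        j = np.random.randint(0, n)
        while j == i:
            j = np.random.randint(0, n)
        if adj[i, j]:
            adj[i, j] = False
            adj[j, i] = False
            deg[i] -= 1
            deg[j] -= 1
            delta_add(adj, deg, i, j, kinds, lams, attrs, dz)
            lp = 0.0
            for t in range(p):
                lp -= theta[t] * dz[t]
            if lp >= 0.0 or np.random.random() < np.exp(lp):
                accepts += 1
                for t in range(p):
                    z[t] -= dz[t]
            else:
                adj[i, j] = True
                adj[j, i] = True
                deg[i] += 1
                deg[j] += 1
        else:
            delta_add(adj, deg, i, j, kinds, lams, attrs, dz)
            lp = 0.0
            for t in range(p):
                lp += theta[t] * dz[t]
            if lp >= 0.0 or np.random.random() < np.exp(lp):
                accepts += 1
                adj[i, j] = True
                adj[j, i] = True
                deg[i] += 1
                deg[j] += 1
                for t in range(p):
                    z[t] += dz[t]
        if (step + 1) % record_every == 0:
            for t in range(p):
                trace[r, t] = z[t]
            r += 1
    return trace, accepts


@njit(cache=True)
def ee_basic(adj, deg, kinds, lams, attrs, theta, K, M, m, seed, theta_bound, k_half_step):
    """Equilibrium-expectation run with the Basic sampler.

    Starts from the current graph state (the observed network) at
    ``theta``; accumulates accepted change statistics into ``dz`` and
    every ``m`` elementary steps applies the signed-square update
    ``theta_A -= K_A * sign(dz_A) * dz_A**2``.  ``K`` is halved once at
    elementary step ``k_half_step`` if that is > 0.  With K = 0 the
    parameter trace stays constant and the run is plain MH.

    Returns (theta_trace, dz_trace, diverged_term) where traces have
    M // m rows (NaN beyond a divergence point) and diverged_term is -1
    on a clean run, else the index of the term whose |theta| crossed
    ``theta_bound``.
    """
    np.random.seed(seed)
    n = adj.shape[0]
    p = kinds.shape[0]
    n_upd = M // m
    theta_trace = np.full((n_upd, p), np.nan)
    dz_trace = np.full((n_upd, p), np.nan)
    dzacc = np.zeros(p)
    dz = np.empty(p)
    Kcur = K.copy()
    diverged = -1
    upd = 0
    for step in range(M):
        if k_half_step > 0 and step == k_half_step:
            for t in range(p):
                Kcur[t] *= 0.5
        i = np.random.randint(0, n)
        j = np.random.randint(0, n)
        while j == i:
            j = np.random.randint(0, n)
        removing = adj[i, j]
        if removing:
            adj[i, j] = False
            adj[j, i] = False
            deg[i] -= 1
            deg[j] -= 1
        delta_add(adj, deg, i, j, kinds, lams, attrs, dz)
        if removing:
            for t in range(p):
                dz[t] = -dz[t]
        lp = 0.0
        for t in range(p):
            lp += theta[t] * dz[t]
        accept = lp >= 0.0 or np.random.random() < np.exp(lp)
        if accept:
            if not removing:
                adj[i, j] = True
                adj[j, i] = True
                deg[i] += 1
                deg[j] += 1
            for t in range(p):
                dzacc[t] += dz[t]
        elif removing:
            adj[i, j] = True
            adj[j, i] = True
            deg[i] += 1
            deg[j] += 1
        if (step + 1) % m == 0:
            for t in range(p):
                d = dzacc[t]
                if d > 0.0:
                    theta[t] -= Kcur[t] * d * d
                elif d < 0.0:
                    theta[t] += Kcur[t] * d * d
                theta_trace[upd, t] = theta[t]
                dz_trace[upd, t] = dzacc[t]
                if np.abs(theta[t]) > theta_bound and diverged < 0:
                    diverged = t
            upd += 1
            if diverged >= 0:
                break
    return theta_trace, dz_trace, diverged


@njit(cache=True)
def ee_ifd(adj, deg, kinds, lams, attrs, theta, K, edges, L_obs, theta_L0, K_L,
           M, m, seed, theta_bound, k_half_step):
    """Equilibrium-expectation run with the improved-fixed-density sampler.

    The edge count is constrained to {L_obs - 1, L_obs}: a uniform
    deletion is proposed when L = L_obs and a uniform insertion when
    L = L_obs - 1, with the exact proposal-ratio correction
    q_ratio = L_obs / (D - L_obs + 1) for deletions (its inverse for
    insertions).  The auxiliary edge parameter theta_L enters the
    acceptance like an edge term and is adapted every ``m`` steps by the
    signed-square rule applied to the window occupancy imbalance
    d = (fraction of steps at L_obs) - 1/2, whose fixed point for the
    edge-only model is ln(L_obs / (D - L_obs + 1)) ~ logit(density).

    ``edges`` is an (L_obs, 2) int64 scratch array whose first L rows
    list the current edges.  Returns (theta_trace, dz_trace,
    thetaL_trace, diverged_term).
    """
    np.random.seed(seed)
    n = adj.shape[0]
    p = kinds.shape[0]
    D = n * (n - 1) // 2
    n_upd = M // m
    theta_trace = np.full((n_upd, p), np.nan)
    dz_trace = np.full((n_upd, p), np.nan)
    thetaL_trace = np.full(n_upd, np.nan)
    dzacc = np.zeros(p)
    dz = np.empty(p)
    Kcur = K.copy()
    theta_L = theta_L0
    KL_cur = K_L
    log_q_del = np.log(L_obs / (D - L_obs + 1.0))
    L = L_obs
    at_obs_count = 0
    diverged = -1
    upd = 0
    for step in range(M):
        if k_half_step > 0 and step == k_half_step:
            for t in range(p):
                Kcur[t] *= 0.5
            KL_cur *= 0.5
        if L == L_obs:
            # deletion proposal: uniform over current edges
            idx = np.random.randint(0, L)
            i = edges[idx, 0]
            j = edges[idx, 1]
            adj[i, j] = False
            adj[j, i] = False
            deg[i] -= 1
            deg[j] -= 1
            delta_add(adj, deg, i, j, kinds, lams, attrs, dz)
            lp = log_q_del - theta_L
            for t in range(p):
                dz[t] = -dz[t]
                lp += theta[t] * dz[t]
            if lp >= 0.0 or np.random.random() < np.exp(lp):
                edges[idx, 0] = edges[L - 1, 0]
                edges[idx, 1] = edges[L - 1, 1]
                L -= 1
                for t in range(p):
                    dzacc[t] += dz[t]
            else:
                adj[i, j] = True
                adj[j, i] = True
                deg[i] += 1
                deg[j] += 1
        else:
            # insertion proposal: uniform over non-edges (rejection sampling)
            i = np.random.randint(0, n)
            j = np.random.randint(0, n)
            while j == i or adj[i, j]:
                i = np.random.randint(0, n)
                j = np.random.randint(0, n)
            delta_add(adj, deg, i, j, kinds, lams, attrs, dz)
            lp = -log_q_del + theta_L
            for t in range(p):
                lp += theta[t] * dz[t]
            if lp >= 0.0 or np.random.random() < np.exp(lp):
                adj[i, j] = True
                adj[j, i] = True
                deg[i] += 1
                deg[j] += 1
                edges[L, 0] = i
                edges[L, 1] = j
                L += 1
                for t in range(p):
                    dzacc[t] += dz[t]
        if L == L_obs:
            at_obs_count += 1
        if (step + 1) % m == 0:
            d_occ = at_obs_count / m - 0.5
            if d_occ > 0.0:
                theta_L -= KL_cur * d_occ * d_occ
            elif d_occ < 0.0:
                theta_L += KL_cur * d_occ * d_occ
            at_obs_count = 0
            for t in range(p):
                d = dzacc[t]
                if d > 0.0:
                    theta[t] -= Kcur[t] * d * d
                elif d < 0.0:
                    theta[t] += Kcur[t] * d * d
                theta_trace[upd, t] = theta[t]
                dz_trace[upd, t] = dzacc[t]
                if np.abs(theta[t]) > theta_bound and diverged < 0:
                    diverged = t
            thetaL_trace[upd] = theta_L
            upd += 1
            if diverged >= 0 or np.abs(theta_L) > theta_bound:
                if np.abs(theta_L) > theta_bound and diverged < 0:
                    diverged = p  # sentinel: the auxiliary edge parameter
                break
    return theta_trace, dz_trace, thetaL_trace, diverged
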