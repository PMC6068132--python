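"""Network statistics z_A(x) and single-toggle change statistics.

Full values are computed with dense numpy linear algebra; change
statistics go through the same local jitted routine used by the
samplers, so incremental and recomputed values agree exactly (up to
floating-point addition order).

The alternating statistics follow the standard geometrically-weighted
definitions with decay constant lambda > 1 (r = 1 - 1/lambda):

* alternating k-star      AS  = lambda^2 * sum_i [ r**d_i - 1 + d_i/lambda ]
                              = sum_{k>=2} (-1)^k S_k / lambda^(k-2),
* alternating k-triangle  AT  = lambda * sum_{edges (i,j)} [ 1 - r**SP_ij ],
* alternating two-path    A2P = lambda * sum_{dyads i<j} [ 1 - r**SP_ij ],

where S_k is the number of k-stars and SP_ij the number of shared
partners of i and j.  The attribute statistics on a binary flag y are
activity rho = sum_{edges} (y_i + y_j) (an edge between two flagged
nodes contributes 2) and interaction rho_B = sum_{edges} y_i * y_j;
mismatch counts edges whose endpoints differ on a categorical
attribute.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .graph import Graph
from .model import ModelSpec, StatisticDescriptor, encode_terms

__all__ = ["statistic_value", "statistic_vector", "change_statistics"]


def statistic_value(graph: Graph, d: StatisticDescriptor) -> float:
    """Exact value of the statistic described by ``d`` on ``graph``."""
    kind = d.kind
    if kind == "edge":
        return float(graph.num_edges)
    if kind == "isolates":
        return float(np.count_nonzero(graph.deg == 0))
    if kind == "alt_star":
        lam = d.lam
        r = 1.0 - 1.0 / lam
        deg = graph.deg.astype(np.float64)
        return float(lam * lam * np.sum(r**deg - 1.0 + deg / lam))
    if kind in ("alt_triangle", "alt_twopath"):
        lam = d.lam
        r = 1.0 - 1.0 / lam
        a = graph.adj.astype(np.int64)
        sp = a @ a  # shared-partner counts for every pair
        iu = np.triu_indices(graph.n, k=1)
        weights = 1.0 - r ** sp[iu].astype(np.float64)
        if kind == "alt_triangle":
            weights = weights * graph.adj[iu]
        return float(lam * weights.sum())
    if kind == "activity":
        y = _binary(graph, d)
        return float(np.dot(y, graph.deg))
    if kind == "interaction":
        y = _binary(graph, d)
        return float(y @ graph.adj @ y / 2.0)
    if kind == "mismatch":
        c = _categorical(graph, d)
        diff = c[:, None] != c[None, :]
        return float(np.count_nonzero(graph.adj & diff) / 2.0)
    raise ValueError(f"unknown kind {kind!r}")  # pragma: no cover


def _binary(graph: Graph, d: StatisticDescriptor) -> np.ndarray:
    try:
        return graph.binary_attrs[d.attr_name]
    except KeyError:
        raise KeyError(f"binary attribute '{d.attr_name}' not found on graph") from None


def _categorical(graph: Graph, d: StatisticDescriptor) -> np.ndarray:
    try:
        return graph.cat_attrs[d.attr_name]
    except KeyError:
        raise KeyError(f"categorical attribute '{d.attr_name}' not found on graph") from None


def statistic_vector(graph: Graph, model) -> np.ndarray:
    """Values of all model statistics, ordered as the model's terms."""
    terms = model.terms if isinstance(model, ModelSpec) else list(model)
    return np.array([statistic_value(graph, d) for d in terms])


def change_statistics(graph: Graph, model, i: int, j: int) -> np.ndarray:
    """Change vector z(x') - z(x) for toggling dyad {i, j}.

    The sign follows the actual toggle direction: positive contributions
    when adding a missing edge, the exact negation when removing an
    existing one.  The graph is left unmodified.
    """
    graph._check_dyad(i, j)
    terms = model.terms if isinstance(model, ModelSpec) else list(model)
    kinds, lams, attrs = encode_terms(graph, terms)
    out = np.empty(len(terms))
    _kernels.delta_toggle(graph.adj, graph.deg, i, j, kinds, lams, attrs, out)
    return out
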