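"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from math import comb

import numpy as np
import pytest

from ergm_ee import Graph, ModelSpec, StatisticDescriptor


def make_er_graph(n: int, p: float, seed: int, with_attrs: bool = False) -> Graph:
    """Erdos-Renyi-style fixture with optional random node attributes."""
    rng = np.random.default_rng(seed)
    g = Graph(n)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.toggle_edge(i, j)
    if with_attrs:
        g.set_binary_attr("flag", rng.integers(0, 2, n))
        g.set_cat_attr("cls", rng.integers(0, 3, n))
    return g


@pytest.fixture
def er50():
    return make_er_graph(50, 0.12, seed=1, with_attrs=True)


@pytest.fixture
def er30():
    return make_er_graph(30, 0.2, seed=2, with_attrs=True)


@pytest.fixture
def all_kind_terms():
    return [
        StatisticDescriptor("edge"),
        StatisticDescriptor("isolates"),
        StatisticDescriptor("alt_star", lam=2.0),
        StatisticDescriptor("alt_triangle", lam=2.0),
        StatisticDescriptor("alt_twopath", lam=2.0),
        StatisticDescriptor("activity", attr_name="flag"),
        StatisticDescriptor("interaction", attr_name="flag"),
        StatisticDescriptor("mismatch", attr_name="cls"),
    ]


@pytest.fixture
def edge_model():
    return ModelSpec([StatisticDescriptor("edge")])


# ---------------------------------------------------------------------------
# Independent brute-force oracles (written from the published alternating
# series; they enumerate subgraph counts directly and sum term by term)
# ---------------------------------------------------------------------------


def degrees(g: Graph) -> list[int]:
    return [len(g.neighbors(i)) for i in range(g.n)]


def shared_partner_count(g: Graph, i: int, j: int) -> int:
    return len(set(g.neighbors(i).tolist()) & set(g.neighbors(j).tolist()))


def alt_star_series(g: Graph, lam: float) -> float:
    """AS = sum_{k>=2} (-1)^k S_k / lam^(k-2), S_k the k-star census."""
    total = 0.0
    for k in range(2, g.n):
        s_k = sum(comb(d, k) for d in degrees(g))
        total += (-1) ** k * s_k / lam ** (k - 2)
    return total


def alt_triangle_series(g: Graph, lam: float) -> float:
    """AT = sum_{k>=1} (-1)^(k+1) lam^(1-k) T_k, with T_k the census of
    edges having k shared partners chosen among their common neighbours."""
    total = 0.0
    for k in range(1, g.n - 1):
        t_k = sum(comb(shared_partner_count(g, i, j), k) for i, j in g.edges())
        total += (-1) ** (k + 1) * lam ** (1 - k) * t_k
    return total


def alt_twopath_series(g: Graph, lam: float) -> float:
    """A2P = sum_{k>=1} (-1)^(k+1) lam^(1-k) P_k over all dyads."""
    total = 0.0
    for k in range(1, g.n - 1):
        p_k = 0
        for i in range(g.n):
            for j in range(i + 1, g.n):
                p_k += comb(shared_partner_count(g, i, j), k)
        total += (-1) ** (k + 1) * lam ** (1 - k) * p_k
    return total


def oracle_statistics(g: Graph, terms) -> np.ndarray:
    """Statistic vector computed by direct enumeration, per kind."""
    vals = []
    for d in terms:
        if d.kind == "edge":
            vals.append(g.num_edges)
        elif d.kind == "isolates":
            vals.append(sum(1 for deg in degrees(g) if deg == 0))
        elif d.kind == "alt_star":
            vals.append(alt_star_series(g, d.lam))
        elif d.kind == "alt_triangle":
            vals.append(alt_triangle_series(g, d.lam))
        elif d.kind == "alt_twopath":
            vals.append(alt_twopath_series(g, d.lam))
        elif d.kind == "activity":
            y = g.binary_attrs[d.attr_name]
            vals.append(sum(int(y[i]) + int(y[j]) for i, j in g.edges()))
        elif d.kind == "interaction":
            y = g.binary_attrs[d.attr_name]
            vals.append(sum(int(y[i]) * int(y[j]) for i, j in g.edges()))
        elif d.kind == "mismatch":
            c = g.cat_attrs[d.attr_name]
            vals.append(sum(1 for i, j in g.edges() if c[i] != c[j]))
        else:  # pragma: no cover
            raise ValueError(d.kind)
    return np.asarray(vals, dtype=float)


def enumerate_graphs_n4():
    """All 64 labelled graphs on 4 nodes, as edge subsets of the 6 dyads."""
    dyads = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    graphs = []
    for mask in range(64):
        g = Graph(4)
        for b, (i, j) in enumerate(dyads):
            if mask >> b & 1:
                g.toggle_edge(i, j)
        graphs.append(g)
    return graphs


def exact_expectations_n4(terms, theta):
    """Exact E[z] on N=4 by enumerating all 64 graphs (oracle path)."""
    theta = np.asarray(theta, dtype=float)
    zs = np.array([oracle_statistics(g, terms) for g in enumerate_graphs_n4()])
    logw = zs @ theta
    w = np.exp(logw - logw.max())
    w /= w.sum()
    return w @ zs, zs, w
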