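"""Undirected graph data model, node attributes, and file I/O.

The graph is stored as a dense boolean adjacency matrix together with a
degree vector and a maintained edge counter.  This representation keeps
single-dyad toggles O(1) and lets the Monte Carlo kernels address the
adjacency structure directly; it is comfortable up to a few thousand
nodes, which covers simulation-study scale.

Node ids are 0-based internally.  Pajek files use 1-based ids (converted
on read/write, per the Pajek convention); plain edge lists are 0-based.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "read_pajek",
    "write_pajek",
    "read_edgelist",
    "write_edgelist",
    "read_attributes",
]


class Graph:
    """Simple undirected graph with optional binary/categorical node attributes.

    Parameters
    ----------
    n : int
        Number of nodes (>= 1).  Nodes are labelled ``0 .. n-1``.

    Attributes
    ----------
    adj : (n, n) bool ndarray
        Symmetric adjacency matrix, zero diagonal.
    deg : (n,) int64 ndarray
        Node degrees (kept consistent with ``adj``).
    num_edges : int
        Number of undirected edges; the edge statistic ``L``.
    binary_attrs : dict[str, ndarray]
        Per-node {0,1} attribute vectors (int64).
    cat_attrs : dict[str, ndarray]
        Per-node dense category ids (int64, >= 0).
    cat_labels : dict[str, list]
        Original labels for each categorical attribute, indexed by id.
    """

    __slots__ = ("n", "adj", "deg", "num_edges", "binary_attrs", "cat_attrs", "cat_labels")

    def __init__(self, n: int):
        if n < 1:
            raise ValueError(f"node count must be >= 1, got {n}")
        self.n = int(n)
        self.adj = np.zeros((n, n), dtype=np.bool_)
        self.deg = np.zeros(n, dtype=np.int64)
        self.num_edges = 0
        self.binary_attrs: dict[str, np.ndarray] = {}
        self.cat_attrs: dict[str, np.ndarray] = {}
        self.cat_labels: dict[str, list] = {}

    # -- construction ---------------------------------------------------

    @classmethod
    def from_edges(cls, n: int, edges: Sequence[tuple[int, int]]) -> "Graph":
        g = cls(n)
        for i, j in edges:
            g._check_dyad(i, j)
            if not g.adj[i, j]:
                g.toggle_edge(i, j)
        return g

    def copy(self) -> "Graph":
        g = Graph.__new__(Graph)
        g.n = self.n
        g.adj = self.adj.copy()
        g.deg = self.deg.copy()
        g.num_edges = self.num_edges
        g.binary_attrs = {k: v.copy() for k, v in self.binary_attrs.items()}
        g.cat_attrs = {k: v.copy() for k, v in self.cat_attrs.items()}
        g.cat_labels = {k: list(v) for k, v in self.cat_labels.items()}
        return g

    # -- basic queries --------------------------------------------------

    def _check_dyad(self, i: int, j: int) -> None:
        if i == j:
            raise ValueError(f"self-loop on node {i} is not allowed")
        if not (0 <= i < self.n and 0 <= j < self.n):
            raise ValueError(f"node id out of range for N={self.n}: ({i}, {j})")

    def has_edge(self, i: int, j: int) -> bool:
        self._check_dyad(i, j)
        return bool(self.adj[i, j])

    def neighbors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.adj[i])

    def edges(self) -> Iterator[tuple[int, int]]:
        """Yield edges as (i, j) with i < j."""
        ii, jj = np.nonzero(np.triu(self.adj, k=1))
        return zip(ii.tolist(), jj.tolist())

    @property
    def num_dyads(self) -> int:
        return self.n * (self.n - 1) // 2

    @property
    def density(self) -> float:
        return self.num_edges / self.num_dyads if self.n > 1 else 0.0

    # -- mutation -------------------------------------------------------

    def toggle_edge(self, i: int, j: int) -> "Graph":
        """Flip the presence of edge {i, j} in place; returns self."""
        self._check_dyad(i, j)
        if self.adj[i, j]:
            self.adj[i, j] = False
            self.adj[j, i] = False
            self.deg[i] -= 1
            self.deg[j] -= 1
            self.num_edges -= 1
        else:
            self.adj[i, j] = True
            self.adj[j, i] = True
            self.deg[i] += 1
            self.deg[j] += 1
            self.num_edges += 1
        return self

    # -- attributes -----------------------------------------------------

    def set_binary_attr(self, name: str, values) -> None:
        v = np.asarray(values)
        if v.shape != (self.n,):
            raise ValueError(f"attribute '{name}' has {v.shape[0] if v.ndim else 0} values, expected {self.n}")
        if not np.isin(v, [0, 1]).all():
            raise ValueError(f"binary attribute '{name}' contains values outside {{0, 1}}")
        self.binary_attrs[name] = v.astype(np.int64)

    def set_cat_attr(self, name: str, values) -> None:
        v = list(values)
        if len(v) != self.n:
            raise ValueError(f"attribute '{name}' has {len(v)} values, expected {self.n}")
        codes, labels = pd.factorize(np.asarray(v, dtype=object))
        if (codes < 0).any():  # NaN slots become their own "NA" category
            labels = list(labels) + ["NA"]
            codes = np.where(codes < 0, len(labels) - 1, codes)
        else:
            labels = list(labels)
        self.cat_attrs[name] = codes.astype(np.int64)
        self.cat_labels[name] = labels

    # -- invariants -----------------------------------------------------

    def validate(self) -> None:
        """Raise AssertionError if any structural invariant is violated."""
        assert not self.adj.diagonal().any(), "self-loop present"
        assert (self.adj == self.adj.T).all(), "adjacency not symmetric"
        assert (self.deg == self.adj.sum(axis=1)).all(), "degree vector stale"
        assert self.num_edges == int(self.adj.sum()) // 2, "edge counter stale"
        for name, v in self.binary_attrs.items():
            assert v.shape == (self.n,), f"binary attr {name} wrong length"
        for name, v in self.cat_attrs.items():
            assert v.shape == (self.n,) and (v >= 0).all(), f"cat attr {name} invalid"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Graph(n={self.n}, edges={self.num_edges})"


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_pajek(path) -> Graph:
    """Read an undirected network from a Pajek .net file.

    ``*Edges`` and ``*Arcs`` sections are both accepted; arcs are
    symmetrized (with a warning) since the model is undirected.
    Duplicate and reversed edge lines collapse to a single edge.
    """
    n = None
    g = None
    section = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if low.startswith("*vertices"):
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"line {lineno}: malformed *Vertices header")
                n = int(parts[1])
                g = Graph(n)
                section = "vertices"
                continue
            if low.startswith("*edges") or low.startswith("*arcs"):
                if g is None:
                    raise ValueError(f"line {lineno}: *Edges before *Vertices header")
                if low.startswith("*arcs"):
                    warnings.warn("Pajek *Arcs section symmetrized to undirected edges")
                section = "edges"
                continue
            if line.startswith("*"):
                section = "other"
                continue
            if section == "edges":
                parts = line.replace(",", " ").split()
                i, j = int(parts[0]) - 1, int(parts[1]) - 1
                if i == j:
                    raise ValueError(f"line {lineno}: self-loop on vertex {i + 1}")
                if not (0 <= i < n and 0 <= j < n):
                    raise ValueError(f"line {lineno}: vertex id out of range 1..{n}")
                if not g.adj[i, j]:
                    g.toggle_edge(i, j)
    if g is None:
        raise ValueError("missing *Vertices header")
    return g


def write_pajek(graph: Graph, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for h in header_lines:
            fh.write(f"% {h}\n")
        fh.write(f"*Vertices {graph.n}\n")
        fh.write("*Edges\n")
        for i, j in graph.edges():
            fh.write(f"{i + 1} {j + 1}\n")


def read_edgelist(path, n_nodes: int | None = None) -> Graph:
    """Read a plain two-column edge list with 0-based node ids.

    Lines starting with ``#`` or ``%`` are comments.  Columns may be
    separated by whitespace or commas.  ``n_nodes`` fixes N; otherwise
    N = 1 + max id seen (at least 1).
    """
    pairs = []
    max_id = -1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line[0] in "#%":
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: expected two node ids")
            i, j = int(parts[0]), int(parts[1])
            if i < 0 or j < 0:
                raise ValueError(f"line {lineno}: negative node id")
            if i == j:
                raise ValueError(f"line {lineno}: self-loop on node {i}")
            if n_nodes is not None and (i >= n_nodes or j >= n_nodes):
                raise ValueError(f"line {lineno}: node id >= n_nodes={n_nodes}")
            pairs.append((i, j))
            max_id = max(max_id, i, j)
    n = n_nodes if n_nodes is not None else max(max_id + 1, 1)
    return Graph.from_edges(n, pairs)


def write_edgelist(graph: Graph, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for h in header_lines:
            fh.write(f"# {h}\n")
        for i, j in graph.edges():
            fh.write(f"{i} {j}\n")


def read_attributes(path, graph: Graph) -> Graph:
    """Attach node attributes from a TSV/CSV table to ``graph`` (in place).

    The delimiter is sniffed.  The header row names columns; rows must be
    in node-id order, one per node.  A column whose non-missing values
    all lie in {0, 1} is treated as binary (missing values rejected);
    any other column is categorical, with missing values mapped to their
    own "NA" category.
    """
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        sep = "\t"
    elif "," in first:
        sep = ","
    else:
        sep = r"\s+"
    df = pd.read_csv(path, sep=sep, engine="python")
    if len(df) != graph.n:
        raise ValueError(f"attribute table has {len(df)} rows, graph has {graph.n} nodes")
    for col in df.columns:
        s = df[col]
        numeric = pd.to_numeric(s, errors="coerce")
        non_missing = numeric.dropna()
        if len(non_missing) == len(s.dropna()) and non_missing.isin([0, 1]).all() and len(non_missing) > 0:
            if s.isna().any():
                raise ValueError(f"binary attribute column '{col}' has missing values")
            graph.set_binary_attr(col, numeric.astype(int).to_numpy())
        else:
            vals = s.astype(object).where(s.notna(), other=np.nan)
            graph.set_cat_attr(col, vals.to_numpy())
    return graph
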