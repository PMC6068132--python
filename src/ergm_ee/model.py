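"""Model specification: statistic descriptors, parameter vectors, encoding.

An ERGM assigns probability pi(x, theta) proportional to
exp(sum_A theta_A * z_A(x)); a model here is an ordered list of
statistic descriptors together with the aligned parameter vector theta.
The normalizing constant is never computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StatisticDescriptor", "ModelSpec", "KINDS", "KIND_CODES", "encode_terms"]

#: Statistic kinds, in kernel-code order.
KINDS = (
    "edge",
    "isolates",
    "alt_star",
    "alt_twopath",
    "alt_triangle",
    "activity",
    "interaction",
    "mismatch",
)
KIND_CODES = {name: code for code, name in enumerate(KINDS)}

_ALT_KINDS = frozenset({"alt_star", "alt_triangle", "alt_twopath"})
_BINARY_ATTR_KINDS = frozenset({"activity", "interaction"})
_CAT_ATTR_KINDS = frozenset({"mismatch"})

#: Default decay constant for alternating statistics.
DEFAULT_LAMBDA = 2.0


@dataclass(frozen=True)
class StatisticDescriptor:
    """One model term: a network statistic z_A.

    Parameters
    ----------
    kind : str
        One of ``edge``, ``isolates``, ``alt_star``, ``alt_triangle``,
        ``alt_twopath``, ``activity``, ``interaction``, ``mismatch``.
    lam : float, optional
        Decay constant lambda > 1; required for (and only for) the
        alternating kinds.  Defaults to 2.0 for those kinds.
    attr_name : str, optional
        Node-attribute name; required for (and only for) the
        attribute-based kinds.  ``activity`` / ``interaction`` use a
        binary attribute, ``mismatch`` a categorical one.
    """

    kind: str
    lam: float | None = None
    attr_name: str | None = None

    def __post_init__(self):
        if self.kind not in KIND_CODES:
            raise ValueError(f"unknown statistic kind '{self.kind}'")
        if self.kind in _ALT_KINDS:
            lam = DEFAULT_LAMBDA if self.lam is None else float(self.lam)
            if lam <= 1.0:
                raise ValueError(f"{self.kind}: decay constant lambda must be > 1, got {lam}")
            object.__setattr__(self, "lam", lam)
        elif self.lam is not None:
            raise ValueError(f"{self.kind} does not take a lambda")
        needs_attr = self.kind in _BINARY_ATTR_KINDS or self.kind in _CAT_ATTR_KINDS
        if needs_attr and not self.attr_name:
            raise ValueError(f"{self.kind} requires attr_name")
        if not needs_attr and self.attr_name is not None:
            raise ValueError(f"{self.kind} does not take an attribute")

    @property
    def label(self) -> str:
        parts = [self.kind]
        if self.attr_name:
            parts.append(self.attr_name)
        return ":".join(parts)


@dataclass
class ModelSpec:
    """An ordered list of statistics with an aligned parameter vector.

    ``fixed_density=True`` selects the IFD sampler: the edge count is
    held at its observed value and the edge parameter theta_L is an
    adapted auxiliary parameter, so the term list must then contain no
    free ``edge`` term.
    """

    terms: list[StatisticDescriptor]
    theta: np.ndarray = field(default=None)  # type: ignore[assignment]
    fixed_density: bool = False

    def __post_init__(self):
        if not self.terms and not self.fixed_density:
            # an empty term list is only meaningful under the IFD sampler,
            # where the edge count itself is the (auxiliary) model
            raise ValueError("model must have at least one term")
        if self.theta is None:
            self.theta = np.zeros(len(self.terms))
        self.theta = np.asarray(self.theta, dtype=np.float64)
        if self.theta.shape != (len(self.terms),):
            raise ValueError(
                f"theta has shape {self.theta.shape}, expected ({len(self.terms)},)"
            )
        labels = [t.label for t in self.terms]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate statistic names: {labels}")
        n_edge = sum(1 for t in self.terms if t.kind == "edge")
        if n_edge > 1:
            raise ValueError("at most one edge term allowed")
        if self.fixed_density and n_edge:
            raise ValueError("fixed-density model must not contain a free edge term")

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.terms]

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def with_theta(self, theta) -> "ModelSpec":
        return ModelSpec(list(self.terms), np.asarray(theta, dtype=float), self.fixed_density)


def encode_terms(graph, terms: list[StatisticDescriptor]):
    """Encode terms into flat arrays consumed by the numba kernels.

    Returns ``(kinds, lams, attrs)`` where ``kinds`` are integer codes,
    ``lams`` the decay constants (0 where unused) and ``attrs`` an
    ``(n_terms, N)`` int64 matrix holding the binary flag / category id
    vector for attribute-based terms (zeros otherwise).
    """
    p = len(terms)
    kinds = np.empty(p, dtype=np.int64)
    lams = np.zeros(p, dtype=np.float64)
    attrs = np.zeros((p, graph.n), dtype=np.int64)
    for t, d in enumerate(terms):
        kinds[t] = KIND_CODES[d.kind]
        if d.kind in _ALT_KINDS:
            lams[t] = d.lam
        elif d.kind in _BINARY_ATTR_KINDS:
            if d.attr_name not in graph.binary_attrs:
                raise KeyError(
                    f"binary attribute '{d.attr_name}' not found on graph "
                    f"(have {sorted(graph.binary_attrs)})"
                )
            attrs[t] = graph.binary_attrs[d.attr_name]
        elif d.kind in _CAT_ATTR_KINDS:
            if d.attr_name not in graph.cat_attrs:
                raise KeyError(
                    f"categorical attribute '{d.attr_name}' not found on graph "
                    f"(have {sorted(graph.cat_attrs)})"
                )
            attrs[t] = graph.cat_attrs[d.attr_name]
    return kinds, lams, attrs
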