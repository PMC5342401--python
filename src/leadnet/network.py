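"""Weighted undirected gene interaction network.

The container wraps a :class:`networkx.Graph` whose edges carry a single
``score`` attribute: the combined confidence of the protein-protein
association on the unit scale, constrained to ``(0, 1]``.  Gene symbols are
case-normalised to upper case on entry, self-loops are rejected, and a
duplicate edge collapses to the maximum of the two scores (conservative and
order-independent).
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable

import networkx as nx

from .errors import ValidationError

logger = logging.getLogger("leadnet")


def normalize_symbol(symbol: str) -> str:
    """Upper-case and strip a gene symbol; reject empty symbols."""
    s = str(symbol).strip().upper()
    if not s:
        raise ValidationError("empty gene symbol")
    return s


class InteractionNetwork:
    """Undirected gene graph with per-edge confidence scores in (0, 1].

    Parameters
    ----------
    edges : iterable of (gene_a, gene_b, score), optional
        Edge list; duplicate unordered pairs collapse keeping the maximum
        score, self-loops raise.
    nodes : iterable of str, optional
        Extra nodes to include even when isolated.
    """

    def __init__(self, edges: Iterable[tuple] = (), nodes: Iterable[str] = ()):
        self._g = nx.Graph()
        for n in nodes:
            self.add_node(n)
        for a, b, s in edges:
            self.add_edge(a, b, s)

    # -- construction ------------------------------------------------------

    def add_node(self, symbol: str) -> str:
        sym = normalize_symbol(symbol)
        self._g.add_node(sym)
        return sym

    def add_edge(self, a: str, b: str, score: float, *, collapse: str = "max") -> None:
        a, b = normalize_symbol(a), normalize_symbol(b)
        if a == b:
            raise ValidationError(f"self-loop on {a!r} is not allowed")
        score = float(score)
        if not (0.0 < score <= 1.0) or not math.isfinite(score):
            raise ValidationError(f"edge score {score} outside (0, 1] for {a}-{b}")
        if self._g.has_edge(a, b):
            if collapse == "max":
                score = max(score, self._g[a][b]["score"])
            else:
                raise ValidationError(f"duplicate edge {a}-{b}")
        self._g.add_edge(a, b, score=score)

    @classmethod
    def from_networkx(cls, g: nx.Graph, score_attr: str = "score") -> "InteractionNetwork":
        net = cls(nodes=(str(n) for n in g.nodes))
        for a, b, d in g.edges(data=True):
            net.add_edge(str(a), str(b), d[score_attr])
        return net

    # -- views -------------------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        """The underlying :class:`networkx.Graph` (edges carry ``score``)."""
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    def edges(self) -> list[tuple[str, str, float]]:
        """Canonically ordered edge list ``(min, max, score)`` sorted by pair."""
        out = [(min(a, b), max(a, b), d["score"]) for a, b, d in self._g.edges(data=True)]
        return sorted(out)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def degree(self, node: str) -> int:
        return self._g.degree[node]

    def score(self, a: str, b: str) -> float:
        return self._g[a][b]["score"]

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(normalize_symbol(a), normalize_symbol(b))

    def subnetwork(self, nodes: Iterable[str]) -> "InteractionNetwork":
        """Induced subnetwork on ``nodes`` (unknown nodes kept as isolated)."""
        keep = {normalize_symbol(n) for n in nodes}
        net = InteractionNetwork(nodes=keep)
        for a, b, s in self.edges():
            if a in keep and b in keep:
                net.add_edge(a, b, s)
        return net

    def copy(self) -> "InteractionNetwork":
        net = InteractionNetwork()
        net._g = self._g.copy()
        return net

    # -- comparison --------------------------------------------------------

    def equals(self, other: "InteractionNetwork", tol: float = 1e-12) -> bool:
        """Structural equality: same nodes, same edge set, scores within tol."""
        if self.nodes != other.nodes:
            return False
        mine, theirs = self.edges(), other.edges()
        if len(mine) != len(theirs):
            return False
        return all(
            a1 == a2 and b1 == b2 and abs(s1 - s2) <= tol
            for (a1, b1, s1), (a2, b2, s2) in zip(mine, theirs)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"InteractionNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"
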