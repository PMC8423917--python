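"""Weighted semantic networks and the geometric-mean weighted clustering coefficient.

Nodes are words (optionally carrying a language tag); an edge connects two
words iff the cosine similarity of their vectors is strictly positive, and
the cosine is the edge weight.  Negative (and exactly zero) cosines mark
dissimilarity and are non-edges, so all weights lie in (0, 1].

The local clustering coefficient of node *u* is

    C_u = 2 / (deg(u) (deg(u) - 1)) * sum_{v,w} (Ŵ_uv Ŵ_uw Ŵ_vw)^(1/3)

where the sum runs over unordered neighbor pairs {v, w}, Ŵ = W / max(w) is
the edge weight normalized by the maximum weight of the whole network, and a
missing (v, w) edge contributes Ŵ_vw = 0.  Nodes of degree < 2 have C_u = 0.
C_u is invariant under a uniform rescaling of all weights and reduces to the
unweighted closed-triple fraction when all weights are equal.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Hashable, Sequence

import networkx as nx
import numpy as np

from .embedding import EmbeddingTable

logger = logging.getLogger(__name__)


class SemanticNetwork:
    """Undirected weighted graph over word nodes with positive cosine weights."""

    def __init__(self, graph: nx.Graph):
        for u, v, w in graph.edges(data="weight"):
            if u == v:
                raise ValueError("self-loops are not allowed")
            if w is None or w <= 0:
                raise ValueError(f"edge ({u!r}, {v!r}) has nonpositive weight {w}")
        self.graph = graph
        self._maxw: float | None = None

    @property
    def maxw(self) -> float:
        """Maximum edge weight of the network (normalization constant)."""
        if self._maxw is None:
            if self.graph.number_of_edges() == 0:
                raise ValueError("maxw undefined for an edgeless network")
            self._maxw = max(w for _, _, w in self.graph.edges(data="weight"))
        return self._maxw

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, u: Hashable) -> int:
        return self.graph.degree(u)

    def weight(self, u: Hashable, v: Hashable) -> float:
        """Edge weight, or 0.0 when (u, v) is not an edge."""
        data = self.graph.get_edge_data(u, v)
        return 0.0 if data is None else data["weight"]


def build_network(
    words: Sequence[Hashable],
    table: EmbeddingTable,
    block_size: int = 512,
) -> SemanticNetwork:
    """Build the semantic network over ``words`` from an embedding table.

    ``words`` may be plain forms or (form, tag) tuples; tuples look their
    vector up by form and store the tag as a ``lang`` node attribute.  Words
    absent from the table (or with zero-norm vectors) are dropped with a
    logged count — fewer than two usable words is an error.  Pairwise cosines
    are computed blockwise so peak memory is one block of the similarity
    matrix, not the full |V|^2.
    """
    entries: list[tuple[Hashable, str]] = []
    for w in words:
        form = w[0] if isinstance(w, tuple) else w
        entries.append((w, form))
    usable: list[tuple[Hashable, str]] = []
    dropped = 0
    for node, form in entries:
        vec = table.get(form)
        if vec is None or not np.any(vec):
            dropped += 1
            continue
        usable.append((node, form))
    if dropped:
        logger.info("build_network: dropped %d words without usable vectors", dropped)
    if len(usable) < 2:
        raise ValueError("need at least 2 words with vectors to build a network")

    mat = np.vstack([table[form] for _, form in usable])
    norms = np.linalg.norm(mat, axis=1, keepdims=True)
    unit = mat / norms

    graph = nx.Graph()
    for node, _ in usable:
        if isinstance(node, tuple):
            graph.add_node(node, lang=node[1])
        else:
            graph.add_node(node)

    n = len(usable)
    node_list = [node for node, _ in usable]
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        sims = unit[start:stop] @ unit.T  # (block, n)
        for bi in range(stop - start):
            i = start + bi
            row = sims[bi, i + 1 :]
            for off in np.nonzero(row > 0.0)[0]:
                j = i + 1 + int(off)
                graph.add_edge(node_list[i], node_list[j], weight=float(min(row[off], 1.0)))
    return SemanticNetwork(graph)


def clustering_coefficient(net: SemanticNetwork, u: Hashable) -> float:
    """Weighted local clustering coefficient of a single node (see module docs)."""
    if u not in net.graph:
        raise KeyError(f"node {u!r} not in network")
    nbrs = list(net.graph[u])
    deg = len(nbrs)
    if deg < 2:
        return 0.0
    maxw = net.maxw
    total = 0.0
    for a in range(deg):
        v = nbrs[a]
        w_uv = net.graph[u][v]["weight"] / maxw
        for b in range(a + 1, deg):
            w = nbrs[b]
            data = net.graph.get_edge_data(v, w)
            if data is None:
                continue
            w_uw = net.graph[u][w]["weight"] / maxw
            w_vw = data["weight"] / maxw
            total += (w_uv * w_uw * w_vw) ** (1.0 / 3.0)
    return 2.0 * total / (deg * (deg - 1))


def clustering_coefficients(net: SemanticNetwork) -> dict[Hashable, float]:
    """Weighted clustering coefficient for every node, computed densely.

    Uses the identity that the sum of geometric means around *u* equals the
    *u*-th diagonal entry of (Ŵ^(1/3))^3 divided by two, which turns the
    triple enumeration into matrix products — worthwhile for the dense
    networks that positive-cosine pruning produces.
    """
    nodes = list(net.graph.nodes)
    n = len(nodes)
    if n == 0:
        return {}
    if net.graph.number_of_edges() == 0:
        return {u: 0.0 for u in nodes}
    idx = {u: i for i, u in enumerate(nodes)}
    a = np.zeros((n, n))
    maxw = net.maxw
    for u, v, w in net.graph.edges(data="weight"):
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = (w / maxw) ** (1.0 / 3.0)
    deg = (a > 0).sum(axis=1)
    # ordered-pair sum of geometric means = diag(A^3)
    tri = np.einsum("ij,ji->i", a @ a, a)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(deg >= 2, tri / np.maximum(deg * (deg - 1), 1), 0.0)
    return {u: float(c[idx[u]]) for u in nodes}


# ---------------------------------------------------------------------------
# import / export
# ---------------------------------------------------------------------------

def _node_to_str(node: Hashable) -> str:
    if isinstance(node, tuple):
        return "␟".join(str(p) for p in node)  # unit separator, not in forms
    return str(node)


def write_edgelist_tsv(net: SemanticNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, w in net.graph.edges(data="weight"):
            fh.write(f"{_node_to_str(u)}\t{_node_to_str(v)}\t{w:.10g}\n")


def read_edgelist_tsv(path: str | Path) -> SemanticNetwork:
    graph = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            u, v = parts[0], parts[1]
            u = tuple(u.split("␟")) if "␟" in u else u
            v = tuple(v.split("␟")) if "␟" in v else v
            graph.add_edge(u, v, weight=float(parts[2]))
    return SemanticNetwork(graph)


def write_graphml(net: SemanticNetwork, path: str | Path) -> None:
    """GraphML export for interoperability; tuple nodes are flattened to strings."""
    g = nx.Graph()
    for node, data in net.graph.nodes(data=True):
        g.add_node(_node_to_str(node), **data)
    for u, v, w in net.graph.edges(data="weight"):
        g.add_edge(_node_to_str(u), _node_to_str(v), weight=w)
    nx.write_graphml(g, path)
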