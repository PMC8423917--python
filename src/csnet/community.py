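"""Louvain community detection, weighted modularity, and composition summaries.

Modularity of a weighted partition is the Newman–Girvan quantity

    Q = (1/2m) * sum_uv [ W_uv - s_u s_v / (2m) ] * delta(c_u, c_v)

with s_u the weighted strength of node u and 2m twice the total edge weight.
The Louvain heuristic greedily moves nodes to the neighboring community with
the largest modularity gain (phase 1), then aggregates communities into
super-nodes and repeats (phase 2) until a phase improves Q by less than a
tolerance.  Node visit order is a seeded shuffle; a tie in gain keeps the
node in its current community, so runs are deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Mapping

import numpy as np
import pandas as pd

from .semnet import SemanticNetwork

logger = logging.getLogger(__name__)


@dataclass
class CommunityPartition:
    """Node -> community assignment with its modularity.

    Community ids are contiguous from 0 and relabeled by community size
    (node count) descending; ``q_history`` records modularity after each
    Louvain phase, which is non-decreasing by construction.
    """

    assignment: dict[Hashable, int]
    Q: float
    q_history: list[float] = field(default_factory=list)
    seed: int | None = None

    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, cid: int) -> list[Hashable]:
        return [n for n, c in self.assignment.items() if c == cid]


def modularity(
    net: SemanticNetwork,
    assignment: Mapping[Hashable, int],
    resolution: float = 1.0,
) -> float:
    """Weighted modularity Q of an assignment covering every node."""
    for node in net.graph.nodes:
        if node not in assignment:
            raise ValueError(f"node {node!r} missing from assignment")
    m2 = 2.0 * sum(w for _, _, w in net.graph.edges(data="weight"))
    if m2 == 0:
        raise ValueError("modularity undefined for an edgeless network")
    internal: dict[int, float] = {}
    strength: dict[int, float] = {}
    for node in net.graph.nodes:
        c = assignment[node]
        strength[c] = strength.get(c, 0.0) + sum(
            d["weight"] for d in net.graph[node].values()
        )
    for u, v, w in net.graph.edges(data="weight"):
        if assignment[u] == assignment[v]:
            internal[assignment[u]] = internal.get(assignment[u], 0.0) + w
    q = 0.0
    for c, s in strength.items():
        q += 2.0 * internal.get(c, 0.0) / m2 - resolution * (s / m2) ** 2
    return q


# -- internal Louvain machinery on index-based adjacency --------------------


def _one_level(
    adj: list[dict[int, float]],
    self_loops: list[float],
    m2: float,
    rng: np.random.Generator,
    resolution: float,
) -> list[int]:
    """Phase 1: greedy local moves until no single move improves Q."""
    n = len(adj)
    node2com = list(range(n))
    # strength includes self-loops twice (both endpoints)
    strength = [sum(nb.values()) + 2.0 * self_loops[i] for i, nb in enumerate(adj)]
    com_tot = strength.copy()

    order = np.arange(n)
    rng.shuffle(order)
    improved = True
    while improved:
        improved = False
        for i in order:
            i = int(i)
            com_i = node2com[i]
            k_i = strength[i]
            # weights from i to each neighboring community
            links: dict[int, float] = {}
            for j, w in adj[i].items():
                links[node2com[j]] = links.get(node2com[j], 0.0) + w
            com_tot[com_i] -= k_i
            base = links.get(com_i, 0.0) - resolution * com_tot[com_i] * k_i / m2
            best_com, best_gain = com_i, base
            for com, wsum in links.items():
                if com == com_i:
                    continue
                gain = wsum - resolution * com_tot[com] * k_i / m2
                if gain > best_gain + 1e-15:
                    best_com, best_gain = com, gain
            com_tot[best_com] += k_i
            if best_com != com_i:
                node2com[i] = best_com
                improved = True
    return node2com


def _aggregate(
    adj: list[dict[int, float]],
    self_loops: list[float],
    node2com: list[int],
) -> tuple[list[dict[int, float]], list[float], list[int]]:
    """Phase 2: build the graph whose nodes are the communities."""
    coms = sorted(set(node2com))
    relabel = {c: i for i, c in enumerate(coms)}
    k = len(coms)
    new_adj: list[dict[int, float]] = [{} for _ in range(k)]
    new_self = [0.0] * k
    for i, nb in enumerate(adj):
        ci = relabel[node2com[i]]
        new_self[ci] += self_loops[i]
        for j, w in nb.items():
            if j < i:
                continue  # each undirected edge once
            cj = relabel[node2com[j]]
            if ci == cj:
                new_self[ci] += w
            else:
                new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
                new_adj[cj][ci] = new_adj[cj].get(ci, 0.0) + w
    return new_adj, new_self, [relabel[c] for c in node2com]


def louvain(
    net: SemanticNetwork,
    seed: int = 0,
    resolution: float = 1.0,
    tol: float = 1e-7,
) -> CommunityPartition:
    """Louvain community detection on a weighted semantic network.

    Iterates local-move and aggregation phases until a full phase improves
    modularity by less than ``tol``.  Deterministic given ``seed``; the
    reported ``Q`` is recomputed from scratch on the returned assignment.
    """
    if net.graph.number_of_edges() == 0:
        raise ValueError("community detection requires at least one edge")
    nodes = list(net.graph.nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    adj0 = [dict() for _ in nodes]
    for u, v, w in net.graph.edges(data="weight"):
        adj0[idx[u]][idx[v]] = adj0[idx[u]].get(idx[v], 0.0) + w
        adj0[idx[v]][idx[u]] = adj0[idx[v]].get(idx[u], 0.0) + w
    self_loops = [0.0] * len(nodes)
    m2 = 2.0 * sum(w for _, _, w in net.graph.edges(data="weight"))

    rng = np.random.default_rng(seed)
    membership = list(range(len(nodes)))  # original node -> current super-node
    adj, self_l = adj0, self_loops
    q_history: list[float] = []
    q_prev = -np.inf
    while True:
        node2com = _one_level(adj, self_l, m2, rng, resolution)
        adj, self_l, node2com = _aggregate(adj, self_l, node2com)
        membership = [node2com[c] for c in membership]
        q = modularity(net, {nodes[i]: membership[i] for i in range(len(nodes))}, resolution)
        q_history.append(q)
        if q - q_prev < tol:
            break
        q_prev = q

    # relabel community ids by size descending (ties: first appearance)
    sizes: dict[int, int] = {}
    for c in membership:
        sizes[c] = sizes.get(c, 0) + 1
    order = sorted(sizes, key=lambda c: (-sizes[c], c))
    relabel = {c: i for i, c in enumerate(order)}
    assignment = {nodes[i]: relabel[membership[i]] for i in range(len(nodes))}
    q_final = modularity(net, assignment, resolution)
    logger.info(
        "louvain: %d communities, Q=%.4f after %d phases",
        len(order), q_final, len(q_history),
    )
    return CommunityPartition(
        assignment=assignment, Q=q_final, q_history=q_history, seed=seed
    )


@dataclass(frozen=True)
class CompositionRow:
    community: int
    n: int
    pct_l1: float
    pct_l2: float
    pct_other: float


def community_composition(
    partition: CommunityPartition,
    tags: Mapping[Hashable, str],
    l1: str = "L1",
    l2: str = "L2",
) -> pd.DataFrame:
    """Per-community language composition, one row per community.

    ``tags`` maps every node to a language label; labels equal to ``l1`` or
    ``l2`` are counted as those languages and anything else as "other"
    (ambiguous identities).  Rows are sorted by community size descending.
    """
    for node in partition.assignment:
        if node not in tags:
            raise ValueError(f"node {node!r} missing from tags")
    rows = []
    for cid in sorted(set(partition.assignment.values())):
        members = partition.members(cid)
        n = len(members)
        n1 = sum(1 for m in members if tags[m] == l1)
        n2 = sum(1 for m in members if tags[m] == l2)
        rows.append(
            CompositionRow(
                community=cid,
                n=n,
                pct_l1=100.0 * n1 / n,
                pct_l2=100.0 * n2 / n,
                pct_other=100.0 * (n - n1 - n2) / n,
            )
        )
    rows.sort(key=lambda r: (-r.n, r.community))
    return pd.DataFrame([r.__dict__ for r in rows])
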