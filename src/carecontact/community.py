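"""Weighted modularity and Louvain community detection.

Subcommunity structure is delineated by maximizing Newman-Girvan
modularity with the two-phase greedy heuristic of Blondel et al.: local
single-node moves to a strict-improvement fixed point, then aggregation
of communities into supernodes, repeated while modularity improves.

The implementation is fully deterministic: nodes are scanned in sorted-ID
order, the best strictly modularity-increasing move is accepted with ties
broken by smallest community id, and a level terminates when no move
improves Q by more than 1e-12.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

_EPS = 1e-12


@dataclass
class CommunityPartition:
    """Node → community labels with the partition's modularity Q."""

    labels: dict[str, int]
    q: float
    n_communities: int = 0
    community_density: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.n_communities:
            self.n_communities = len(set(self.labels.values()))

    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, c in self.labels.items():
            out.setdefault(c, []).append(node)
        return {c: sorted(members) for c, members in out.items()}


def modularity(
    net: nx.Graph, labels: dict[str, int], resolution: float = 1.0
) -> float:
    """Weighted modularity Q = Σ_c [w_in(c)/W − γ·(s_c / 2W)²].

    W is the total edge weight, w_in(c) the weight inside community c,
    s_c the summed strength of its nodes.  Q of an edgeless graph is 0
    by convention.
    """
    w_tot = net.size(weight="weight")
    if w_tot == 0:
        return 0.0
    strength = dict(net.degree(weight="weight"))
    w_in: dict[int, float] = {}
    s_c: dict[int, float] = {}
    for node in net:
        c = labels[node]
        s_c[c] = s_c.get(c, 0.0) + strength[node]
    for u, v, w in net.edges(data="weight", default=1):
        if labels[u] == labels[v]:
            w_in[labels[u]] = w_in.get(labels[u], 0.0) + w
    q = 0.0
    for c, s in s_c.items():
        q += w_in.get(c, 0.0) / w_tot - resolution * (s / (2 * w_tot)) ** 2
    return q


def _one_level(
    g: nx.Graph,
    resolution: float,
    order: list | None = None,
    init: dict | None = None,
) -> tuple[dict, bool]:
    """Phase 1: local moves on (possibly aggregated) graph ``g``.

    ``g`` may carry self-loops from aggregation; their weight counts in
    the total and in node strength but never moves between communities.
    ``order`` fixes the node scan order (sorted IDs by default); ``init``
    seeds the starting partition (singletons by default), which lets the
    caller refine an aggregated solution at node granularity.
    Returns (node → community, any_move_made).
    """
    nodes = order if order is not None else sorted(g.nodes())
    m2 = 2.0 * g.size(weight="weight")  # 2W, > 0 ensured by caller
    strength = dict(g.degree(weight="weight"))
    if init is None:
        comm = {v: i for i, v in enumerate(nodes)}
    else:
        comm = {v: init[v] for v in g.nodes()}
    s_tot: dict = {}
    for v in g.nodes():
        s_tot[comm[v]] = s_tot.get(comm[v], 0.0) + strength[v]

    improved_ever = False
    improved = True
    while improved:
        improved = False
        for v in nodes:
            c_old = comm[v]
            k_v = strength[v]
            # weight from v to each neighbouring community (self-loops excluded)
            w_to: dict[int, float] = {}
            for u, data in g[v].items():
                if u == v:
                    continue
                w_to[comm[u]] = w_to.get(comm[u], 0.0) + data.get("weight", 1)
            w_old = w_to.get(c_old, 0.0)
            base_remove = -w_old / (m2 / 2) + resolution * k_v * (
                s_tot[c_old] - k_v
            ) / (m2 * m2 / 2)
            # best strictly-improving move; ties broken by smallest
            # community id (deterministic)
            best_gain, best_c = _EPS, None
            for c_new in sorted(w_to):
                if c_new == c_old:
                    continue
                gain = (
                    base_remove
                    + w_to[c_new] / (m2 / 2)
                    - resolution * k_v * s_tot[c_new] / (m2 * m2 / 2)
                )
                if gain > best_gain:
                    best_gain, best_c = gain, c_new
            if best_c is not None:
                s_tot[c_old] -= k_v
                s_tot[best_c] += k_v
                comm[v] = best_c
                improved = True
                improved_ever = True
    return comm, improved_ever


def _aggregate(g: nx.Graph, comm: dict) -> nx.Graph:
    agg = nx.Graph()
    agg.add_nodes_from(sorted(set(comm.values())))
    for u, v, w in g.edges(data="weight", default=1):
        cu, cv = comm[u], comm[v]
        if agg.has_edge(cu, cv):
            agg[cu][cv]["weight"] += w
        else:
            agg.add_edge(cu, cv, weight=w)
    return agg


def _community_densities(net: nx.Graph, labels: dict[str, int]) -> dict[int, float]:
    """Induced-subgraph density per community; singletons → 0."""
    out: dict[int, float] = {}
    for c, members in CommunityPartition(labels, 0.0).communities().items():
        if len(members) < 2:
            out[c] = 0.0
        else:
            out[c] = nx.density(net.subgraph(members))
    return out


def _louvain_once(
    net: nx.Graph, resolution: float, rng: "object | None"
) -> dict:
    """One full Louvain run; ``rng`` shuffles scan order.

    Alternates node-granularity local moves on the original graph
    (seeded from the current partition) with aggregated-level rounds:
    plain aggregation can trap a node inside a supernode even when moving
    it alone would still raise Q, and the fine-level refinement pass
    releases it.  Terminates when neither pass improves Q by > 1e-12.
    """
    fine = nx.Graph()
    fine.add_nodes_from(net.nodes())
    fine.add_weighted_edges_from(
        (u, v, d.get("weight", 1)) for u, v, d in net.edges(data=True)
    )

    def scan_order(graph: nx.Graph) -> list:
        order = sorted(graph.nodes())
        if rng is not None:
            rng.shuffle(order)
        return order

    labels = {v: v for v in fine.nodes()}
    best_q = modularity(net, labels, resolution)  # singleton floor

    while True:
        # fine-level moves starting from the current partition
        labels, _ = _one_level(fine, resolution, scan_order(fine), init=labels)
        # aggregated rounds
        g = _aggregate(fine, labels)
        mapping = dict(labels)
        while True:
            comm, moved = _one_level(g, resolution, scan_order(g))
            if not moved:
                break
            mapping = {node: comm[mapping[node]] for node in mapping}
            g = _aggregate(g, comm)
        labels = mapping
        q = modularity(net, labels, resolution)
        if q - best_q <= _EPS:
            break
        best_q = q
    return labels


def louvain_partition(
    net: nx.Graph,
    resolution: float = 1.0,
    seed: int | None = 0,
    n_restarts: int = 8,
) -> CommunityPartition:
    """Two-phase Louvain modularity optimization on edge weights.

    Greedy local moves are sensitive to node scan order, so the search is
    restarted ``n_restarts`` times: the first pass scans nodes in sorted-ID
    order, the rest in permutations drawn from a generator seeded with
    ``seed``; the highest-Q partition wins (first encountered on ties).
    Fully deterministic given ``seed``.  An edgeless graph partitions
    into singletons with Q = 0.  The returned Q is never below the
    singleton-partition Q.
    """
    if net.number_of_edges() == 0:
        labels = {v: i for i, v in enumerate(sorted(net.nodes()))}
        return CommunityPartition(labels, 0.0,
                                  community_density=_community_densities(net, labels))

    import random as _random

    rng = _random.Random(seed if seed is not None else 0)
    best_labels: dict | None = None
    best_q = float("-inf")
    for restart in range(max(1, n_restarts)):
        labels = _louvain_once(net, resolution, None if restart == 0 else rng)
        q = modularity(net, labels, resolution)
        if q > best_q + _EPS:
            best_q, best_labels = q, labels
    assert best_labels is not None

    # relabel communities 0..k-1 by their smallest member ID
    groups: dict[int, list[str]] = {}
    for node, c in best_labels.items():
        groups.setdefault(c, []).append(node)
    order = sorted(groups, key=lambda c: min(groups[c]))
    remap = {c: i for i, c in enumerate(order)}
    final = {node: remap[c] for node, c in best_labels.items()}
    q = modularity(net, final, resolution)
    return CommunityPartition(
        final, q, community_density=_community_densities(net, final)
    )


def adjusted_rand_index(a: dict[str, int], b: dict[str, int]) -> float:
    """Chance-corrected agreement between two partitions of the same nodes.

    Used to score recovery of planted units; 1 means identical up to
    label permutation, 0 is the chance level.
    """
    nodes = sorted(a)
    if sorted(b) != nodes:
        raise ValueError("partitions must label the same node set")
    n = len(nodes)
    if n <= 1:
        return 1.0
    from collections import Counter

    pairs = Counter((a[v], b[v]) for v in nodes)
    row = Counter(a[v] for v in nodes)
    col = Counter(b[v] for v in nodes)

    def c2(x: int) -> float:
        return x * (x - 1) / 2.0

    sum_pairs = sum(c2(x) for x in pairs.values())
    sum_row = sum(c2(x) for x in row.values())
    sum_col = sum(c2(x) for x in col.values())
    total = c2(n)
    expected = sum_row * sum_col / total
    max_index = (sum_row + sum_col) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_pairs - expected) / (max_index - expected)
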