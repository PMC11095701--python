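"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive — exhaustive enumeration over
paths, partitions and gap splits — and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import datetime as dt
from itertools import combinations

import networkx as nx


def all_shortest_paths_brute(g: nx.Graph, s, t) -> list[list]:
    """All geodesics s→t by exhaustive simple-path enumeration."""
    paths = list(nx.all_simple_paths(g, s, t)) if s != t else [[s]]
    if not paths:
        return []
    shortest = min(len(p) for p in paths)
    return [p for p in paths if len(p) == shortest]


def betweenness_brute(g: nx.Graph) -> dict:
    """Unnormalized betweenness: even split over equal-length geodesics."""
    out = {v: 0.0 for v in g}
    for s, t in combinations(sorted(g.nodes()), 2):
        geos = all_shortest_paths_brute(g, s, t)
        if not geos:
            continue
        for path in geos:
            for v in path[1:-1]:
                out[v] += 1.0 / len(geos)
    return out


def harmonic_closeness_brute(g: nx.Graph) -> dict:
    """Harmonic closeness / (n-1) from enumerated path lengths."""
    n = g.number_of_nodes()
    out = {}
    for v in g:
        total = 0.0
        for u in g:
            if u == v:
                continue
            geos = all_shortest_paths_brute(g, v, u)
            if geos:
                total += 1.0 / (len(geos[0]) - 1)
        out[v] = total / (n - 1) if n > 1 else 0.0
    return out


def modularity_brute(g: nx.Graph, labels: dict, resolution: float = 1.0) -> float:
    """Direct Q = (1/2W) Σ_ij [A_ij − γ k_i k_j / 2W] δ(c_i, c_j)."""
    nodes = sorted(g.nodes())
    w2 = 2.0 * sum(d.get("weight", 1) for _, _, d in g.edges(data=True))
    if w2 == 0:
        return 0.0
    k = {v: sum(d.get("weight", 1) for _, _, d in g.edges(v, data=True)) for v in nodes}
    q = 0.0
    for i in nodes:
        for j in nodes:
            if labels[i] != labels[j]:
                continue
            if g.has_edge(i, j):
                a_ij = g[i][j].get("weight", 1)
            else:
                a_ij = 0.0
            q += a_ij - resolution * k[i] * k[j] / w2
    return q / w2


def set_partitions(items: list):
    """All set partitions (Bell enumeration) of a list."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1:]
        yield [[first]] + smaller


def best_modularity_brute(g: nx.Graph, resolution: float = 1.0) -> float:
    """Exhaustive-search optimal Q over every partition of the node set."""
    nodes = sorted(g.nodes())
    best = float("-inf")
    for blocks in set_partitions(nodes):
        labels = {v: i for i, block in enumerate(blocks) for v in block}
        best = max(best, modularity_brute(g, labels, resolution))
    return best


def sessionize_brute(times: list[dt.datetime], max_gap_s: float) -> list[tuple[int, int]]:
    """Episodes for one dyad by pairwise gap scan.

    Splits the time-sorted ping list wherever the gap strictly exceeds
    max_gap_s; returns (start_time, end_time, n_pings) per episode.
    """
    order = sorted(range(len(times)), key=lambda i: times[i])
    runs: list[tuple[int, int]] = []
    start = 0
    for pos in range(1, len(order)):
        gap = (times[order[pos]] - times[order[pos - 1]]).total_seconds()
        if gap > max_gap_s:
            runs.append((start, pos - 1))
            start = pos
    if order:
        runs.append((start, len(order) - 1))
    return [(times[order[a]], times[order[b]], b - a + 1) for a, b in runs]
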