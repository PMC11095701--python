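"""Weighted undirected contact networks and their SNA metrics.

The contact network for an analysis window has one node per rostered
person (isolates retained) and one edge per dyad with at least one
episode overlapping the window.  Edge weight ``w`` is the episode count
— tie strength as contact frequency — with total contact minutes and
mean RSSI carried alongside.

Shortest-path metrics treat the graph as unweighted: weights encode tie
strength, not traversal cost.  Closeness defaults to the harmonic form,
which stays finite on the disconnected graphs that sparsely-present
agency staff produce.
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .episodes import InteractionEpisode
from .ingest import Roster


class RosterMismatchError(ValueError):
    """Episodes mention devices absent from the roster."""


def build_network(
    episodes: Sequence[InteractionEpisode],
    roster: Roster,
    window: tuple[dt.datetime, dt.datetime] | None = None,
) -> nx.Graph:
    """Aggregate episodes into a weighted undirected contact graph.

    ``window`` is half-open ``[start, end)``; ``None`` keeps every
    episode.  Edge attributes: ``weight`` (episode count), ``total_minutes``
    (summed overlap with the window), ``mean_rssi`` (ping-weighted).
    Every rostered person appears as a node even with no contacts.
    """
    missing = sorted(
        {d for e in episodes for d in e.dyad if d not in roster}
    )
    if missing:
        raise RosterMismatchError(
            f"devices in episodes but not in roster: {missing}"
        )

    g = nx.Graph()
    for device in roster.devices():
        entry = roster.entries[device]
        g.add_node(device, role=entry.role, home=entry.home, unit=entry.unit or "")
    if window is not None:
        g.graph["window_start"] = window[0].isoformat()
        g.graph["window_end"] = window[1].isoformat()

    for e in episodes:
        if window is not None:
            if not e.overlaps(window[0], window[1]):
                continue
            lo = max(e.start, window[0])
            hi = min(e.end, window[1])
            overlap_min = max((hi - lo).total_seconds() / 60.0, 0.0)
        else:
            overlap_min = e.duration_min
        a, b = e.dyad
        if g.has_edge(a, b):
            data = g[a][b]
            data["weight"] += 1
            data["total_minutes"] += overlap_min
            if e.mean_rssi is not None:
                data["_rssi_sum"] += e.mean_rssi * e.n_pings
                data["_rssi_n"] += e.n_pings
        else:
            g.add_edge(
                a, b, weight=1, total_minutes=overlap_min,
                _rssi_sum=(e.mean_rssi or 0.0) * e.n_pings,
                _rssi_n=e.n_pings if e.mean_rssi is not None else 0,
            )
    for _, _, data in g.edges(data=True):
        n = data.pop("_rssi_n", 0)
        s = data.pop("_rssi_sum", 0.0)
        data["mean_rssi"] = s / n if n else float("nan")
        data["total_minutes"] = round(data["total_minutes"], 6)
    return g


def degree_centrality(net: nx.Graph) -> dict[str, int]:
    """Raw contact-partner counts (unnormalized degree)."""
    return {n: d for n, d in net.degree()}


def weighted_degree(net: nx.Graph) -> dict[str, float]:
    """Strength: sum of incident edge weights per node."""
    return {n: d for n, d in net.degree(weight="weight")}


def closeness_centrality(net: nx.Graph, kind: str = "harmonic") -> dict[str, float]:
    """Closeness on unweighted hop distances.

    ``harmonic``: mean reciprocal distance to every other node
    (unreachable pairs contribute 0), i.e. harmonic centrality divided by
    n − 1.  ``classic``: (n − 1)/Σd, computed per connected component
    with the standard reachable-fraction scaling.  Single-node graph → 0.
    """
    n = net.number_of_nodes()
    if n <= 1:
        return {v: 0.0 for v in net}
    if kind == "harmonic":
        h = nx.harmonic_centrality(net)
        return {v: h[v] / (n - 1) for v in net}
    if kind == "classic":
        return nx.closeness_centrality(net)
    raise ValueError(f"unknown closeness kind {kind!r}")


def betweenness_centrality(net: nx.Graph) -> dict[str, float]:
    """Unnormalized geodesic betweenness with even split over ties."""
    return nx.betweenness_centrality(net, normalized=False, weight=None)


def eigenvector_centrality(
    net: nx.Graph, tol: float = 1e-9, max_iter: int = 10_000
) -> dict[str, float]:
    """Principal eigenvector of the weighted adjacency, L2-normalized.

    Power iteration on A + I (the shift guarantees convergence on
    bipartite graphs); entries are nonnegative.  Undefined on an edgeless
    graph.
    """
    if net.number_of_edges() == 0:
        raise ValueError("eigenvector centrality undefined on an edgeless graph")
    nodes = sorted(net.nodes())
    a = nx.to_numpy_array(net, nodelist=nodes, weight="weight")
    x = np.ones(len(nodes)) / np.sqrt(len(nodes))
    shifted = a + np.eye(len(nodes))
    for _ in range(max_iter):
        y = shifted @ x
        y /= np.linalg.norm(y)
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    x = np.abs(x)
    x /= np.linalg.norm(x)
    return dict(zip(nodes, x.tolist()))


def density(net: nx.Graph) -> float:
    """2E / N(N−1); zero for fewer than two nodes."""
    if net.number_of_nodes() < 2:
        return 0.0
    return nx.density(net)


def clustering_coefficient(net: nx.Graph) -> tuple[dict[str, float], float]:
    """Local (unweighted) clustering per node and its mean; 0 for k < 2."""
    local = nx.clustering(net, weight=None)
    mean = sum(local.values()) / len(local) if local else 0.0
    return local, mean


def degree_centralization(net: nx.Graph) -> float:
    """Freeman degree centralization: Σ(k_max − k_i) / ((N−1)(N−2)).

    1 for a star, 0 for any regular graph; 0 by convention for N < 3.
    """
    n = net.number_of_nodes()
    if n < 3:
        return 0.0
    degrees = [d for _, d in net.degree()]
    k_max = max(degrees)
    return sum(k_max - k for k in degrees) / ((n - 1) * (n - 2))


def role_assortativity(net: nx.Graph, attribute: str = "role") -> float:
    """Newman's categorical assortativity on a node attribute.

    r = (tr e − Σ a_i b_i) / (1 − Σ a_i b_i) from the normalized mixing
    matrix e.  When every edge joins like with like and only one category
    carries edges, the denominator vanishes; that perfectly assortative
    limit is returned as 1.0.
    """
    if net.number_of_edges() == 0:
        raise ValueError("assortativity undefined on an edgeless graph")
    cats = sorted({net.nodes[v][attribute] for v in net})
    idx = {c: i for i, c in enumerate(cats)}
    e = np.zeros((len(cats), len(cats)))
    for u, v in net.edges():
        i, j = idx[net.nodes[u][attribute]], idx[net.nodes[v][attribute]]
        e[i, j] += 1
        e[j, i] += 1
    e /= e.sum()
    a = e.sum(axis=1)
    trace = np.trace(e)
    ab = float(a @ a)
    if abs(1.0 - ab) < 1e-12:
        return 1.0
    return float((trace - ab) / (1.0 - ab))


def reciprocity(net) -> float:
    """Not supported: BLE co-presence yields undirected ties.

    Reciprocity is defined on directed networks only; proximity data
    cannot say who initiated a contact, so there is no directed edge set
    to compare against its transpose.
    """
    raise NotImplementedError(
        "reciprocity requires directed relationship data; BLE proximity "
        "networks are undirected, so reciprocity is not computable here"
    )


def time_windowed_networks(
    episodes: Sequence[InteractionEpisode],
    roster: Roster,
    bin_width: dt.timedelta,
) -> list[tuple[dt.datetime, nx.Graph]]:
    """One contact network per half-open time bin [t, t + bin).

    Bins tile the episode span starting at the first episode's start
    floored to a whole bin; an episode contributes to every bin it
    overlaps.  Empty episode list → empty sequence.
    """
    if bin_width <= dt.timedelta(0):
        raise ValueError("bin width must be positive")
    if not episodes:
        return []
    t0 = min(e.start for e in episodes)
    t1 = max(e.end for e in episodes)
    epoch = t0.replace(hour=0, minute=0, second=0, microsecond=0)
    offset = int(((t0 - epoch) // bin_width)) * bin_width
    start = epoch + offset
    out = []
    t = start
    while t <= t1:
        out.append((t, build_network(episodes, roster, window=(t, t + bin_width))))
        t += bin_width
    return out


def export_network(net: nx.Graph, base_path, formats: Iterable[str] = ("graphml", "gexf")) -> list:
    """Write the network as GraphML and/or GEXF (Gephi interchange)."""
    from pathlib import Path

    base = Path(base_path)
    written = []
    g = net.copy()
    for _, data in g.nodes(data=True):
        for k, v in list(data.items()):
            if v is None:
                data[k] = ""
    for _, _, data in g.edges(data=True):
        for k, v in list(data.items()):
            if isinstance(v, float) and not np.isfinite(v):
                data[k] = 0.0
    for fmt in formats:
        path = base.with_suffix(f".{fmt}")
        if fmt == "graphml":
            nx.write_graphml(g, path)
        elif fmt == "gexf":
            nx.write_gexf(g, path)
        else:
            raise ValueError(f"unknown export format {fmt!r}")
        written.append(path)
    return written
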