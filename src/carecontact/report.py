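"""Quality-improvement report surfaces and the end-to-end pipeline.

Produces the analysis tables a care-home QI report is built from:
per-home tie-strength and duration summaries, centrality distributions by
home and role, the role-pair contingency of long (>2 min) interactions,
unique-vs-total interaction counts, hour-of-day temporal profiles,
location frequencies and connectedness rankings — plus
:func:`run_pipeline`, which drives ingest → filter → sessionize →
network → metrics → communities → reports deterministically and writes
every artefact to disk.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import network as netm
from .community import CommunityPartition, louvain_partition
from .config import AnalysisConfig
from .episodes import (
    InteractionEpisode,
    attribute_locations,
    long_episodes,
    sessionize,
    write_episodes,
)
from .ingest import (
    Roster,
    filter_proximate,
    read_roster,
    read_sightings,
    write_rejects,
)

ROLES = ["agency", "resident", "staff"]
PAIR3 = ["res-res", "res-staff", "staff-staff"]


def _quantile(values: Sequence[float], q: float) -> float:
    """Linear-interpolation quantile (NumPy default rule)."""
    return float(np.quantile(np.asarray(values, dtype=float), q))


def _iqr(values: Sequence[float]) -> float:
    return _quantile(values, 0.75) - _quantile(values, 0.25)


def collapse_pair3(role_a: str, role_b: str) -> str:
    """Three-category relationship view with agency folded into staff."""
    fold = lambda r: "staff" if r == "agency" else r  # noqa: E731
    a, b = sorted((fold(role_a), fold(role_b)))
    return {"resident-resident": "res-res",
            "resident-staff": "res-staff",
            "staff-staff": "staff-staff"}[f"{a}-{b}"]


def strength_duration_summary(
    net: nx.Graph, episodes: Sequence[InteractionEpisode], roster: Roster
) -> pd.DataFrame:
    """Median/IQR of edge weights and episode durations per home.

    A home with no edges or episodes yields a row of nulls, never a
    missing row.
    """
    homes = sorted({e.home for e in roster.entries.values()})
    weight_by_home: dict[str, list[float]] = {h: [] for h in homes}
    for u, v, w in net.edges(data="weight", default=1):
        weight_by_home[roster.home(u)].append(float(w))
    dur_by_home: dict[str, list[float]] = {h: [] for h in homes}
    for e in episodes:
        dur_by_home[roster.home(e.dyad[0])].append(e.duration_min)
    rows = []
    for h in homes:
        w, d = weight_by_home[h], dur_by_home[h]
        rows.append(
            {
                "home": h,
                "weight_median": _quantile(w, 0.5) if w else np.nan,
                "weight_iqr": _iqr(w) if w else np.nan,
                "duration_median_min": _quantile(d, 0.5) if d else np.nan,
                "duration_iqr_min": _iqr(d) if d else np.nan,
            }
        )
    return pd.DataFrame(rows)


def centrality_by_role(net: nx.Graph, roster: Roster) -> pd.DataFrame:
    """n, mean and 5th/95th percentiles of degree and strength by home × role."""
    k = netm.degree_centrality(net)
    s = netm.weighted_degree(net)
    homes = sorted({e.home for e in roster.entries.values()})
    rows = []
    for home in homes:
        for role in ROLES:
            members = [
                d for d, e in roster.entries.items()
                if e.home == home and e.role == role
            ]
            kk = [float(k[m]) for m in members]
            ss = [float(s[m]) for m in members]
            if members:
                rows.append(
                    {
                        "home": home, "role": role, "n": len(members),
                        "mean_degree": float(np.mean(kk)),
                        "degree_p5": _quantile(kk, 0.05),
                        "degree_p95": _quantile(kk, 0.95),
                        "mean_weighted_degree": float(np.mean(ss)),
                        "weighted_degree_p5": _quantile(ss, 0.05),
                        "weighted_degree_p95": _quantile(ss, 0.95),
                    }
                )
            else:
                rows.append(
                    {
                        "home": home, "role": role, "n": 0,
                        "mean_degree": np.nan, "degree_p5": np.nan,
                        "degree_p95": np.nan, "mean_weighted_degree": np.nan,
                        "weighted_degree_p5": np.nan, "weighted_degree_p95": np.nan,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class Contingency:
    """Role-pair contingency of long interactions with margin arithmetic."""

    counts: pd.DataFrame  # 3×3, rows = role of first (canonical) device
    row_totals: pd.Series
    col_totals: pd.Series
    grand_total: int
    col_pct: pd.Series  # column total as % of grand total, 1 dp


def contingency_summary(counts: pd.DataFrame) -> Contingency:
    """Margins and column percentages for a role-pair count matrix.

    Column percentages are each column total over the grand total,
    rounded to one decimal place.
    """
    counts = counts.reindex(index=ROLES, columns=ROLES, fill_value=0).astype(int)
    row_totals = counts.sum(axis=1)
    col_totals = counts.sum(axis=0)
    grand = int(counts.to_numpy().sum())
    if grand > 0:
        pct = (100.0 * col_totals / grand).round(1)
    else:
        pct = col_totals.astype(float) * np.nan
    return Contingency(counts, row_totals, col_totals, grand, pct)


def role_contingency(
    episodes: Sequence[InteractionEpisode], symmetric: bool = False
) -> Contingency:
    """Count long episodes per ordered (canonical-dyad) role pair.

    Cell (r1, r2) counts episodes whose first device (lexicographically
    smaller ID) has role r1 and second has role r2; ``symmetric=True``
    folds (r1, r2) and (r2, r1) together into the upper triangle of the
    sorted pair.
    """
    counts = pd.DataFrame(0, index=ROLES, columns=ROLES, dtype=int)
    for e in episodes:
        if e.role_pair is None:
            raise ValueError("episodes must carry role pairs (sessionize with a roster)")
        r1, r2 = e.role_pair
        if symmetric:
            r1, r2 = sorted((r1, r2))
        counts.loc[r1, r2] += 1
    return contingency_summary(counts)


def unique_interactions(
    episodes: Sequence[InteractionEpisode], roster: Roster
) -> pd.DataFrame:
    """Unique partners vs total interactions per role.

    Individuals counted are those observed in at least one episode (role
    headcounts come from the data, not the roster).  The percentage is
    the ratio of mean unique partners to mean total episodes.
    """
    partners: dict[str, set[str]] = {}
    totals: dict[str, int] = {}
    for e in episodes:
        a, b = e.dyad
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
        totals[a] = totals.get(a, 0) + 1
        totals[b] = totals.get(b, 0) + 1
    rows = []
    for role in ROLES:
        people = sorted(p for p in partners if roster.role(p) == role)
        uniq = [len(partners[p]) for p in people]
        tot = [totals[p] for p in people]
        if people:
            mean_u, mean_t = float(np.mean(uniq)), float(np.mean(tot))
            rows.append(
                {
                    "role": role, "n_individuals": len(people),
                    "mean_unique": mean_u,
                    "sd_unique": float(np.std(uniq, ddof=1)) if len(people) > 1 else 0.0,
                    "mean_total": mean_t,
                    "sd_total": float(np.std(tot, ddof=1)) if len(people) > 1 else 0.0,
                    "unique_pct_of_total": round(100.0 * mean_u / mean_t, 1)
                    if mean_t else 0.0,
                }
            )
        else:
            rows.append(
                {
                    "role": role, "n_individuals": 0, "mean_unique": 0.0,
                    "sd_unique": 0.0, "mean_total": 0.0, "sd_total": 0.0,
                    "unique_pct_of_total": 0.0,
                }
            )
    return pd.DataFrame(rows)


def temporal_profile(
    episodes: Sequence[InteractionEpisode],
    bin_hours: float = 1.0,
    tz_offset_min: int = 0,
) -> pd.DataFrame:
    """Episode counts and minutes per time bin × relationship class.

    Bins are half-open ``[t, t + bin)`` aligned to local midnight; an
    episode is counted in every bin it overlaps (one spanning midnight
    lands in the last bin of one day and the first of the next).  Roles
    collapse to res-res / res-staff / staff-staff with agency treated as
    staff.
    """
    if bin_hours <= 0:
        raise ValueError("bin width must be positive")
    tz = dt.timezone(dt.timedelta(minutes=tz_offset_min))
    binw = dt.timedelta(hours=bin_hours)
    rows = []
    for e in episodes:
        if e.role_pair is None:
            raise ValueError("episodes must carry role pairs")
        pair = collapse_pair3(*e.role_pair)
        start_local = e.start.astimezone(tz)
        midnight = start_local.replace(hour=0, minute=0, second=0, microsecond=0)
        t = midnight + ((start_local - midnight) // binw) * binw
        while t <= e.end.astimezone(tz):
            rows.append(
                {
                    "bin_start": t, "hour": t.hour, "pair": pair,
                    "duration_min": e.duration_min,
                }
            )
            t += binw
    if not rows:
        return pd.DataFrame(columns=["bin_start", "hour", "pair", "n", "total_min"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["bin_start", "hour", "pair"], as_index=False)
        .agg(n=("pair", "size"), total_min=("duration_min", "sum"))
    )
    return out.sort_values(["bin_start", "pair"]).reset_index(drop=True)


def temporal_heatmap(
    episodes: Sequence[InteractionEpisode],
    bin_hours: float = 1.0,
    tz_offset_min: int = 0,
) -> pd.DataFrame:
    """Hour-of-day × relationship heat map (episode counts).

    Collapses the binned temporal profile over days; rows are local
    hours 0–23, columns res-res / res-staff / staff-staff.
    """
    prof = temporal_profile(episodes, bin_hours, tz_offset_min)
    grid = pd.DataFrame(0, index=range(24), columns=PAIR3)
    if not prof.empty:
        pivot = prof.groupby(["hour", "pair"])["n"].sum().unstack(fill_value=0)
        for col in pivot.columns:
            grid.loc[pivot.index, col] = pivot[col]
    grid.index.name = "hour"
    return grid


def location_frequency(episodes: Sequence[InteractionEpisode]) -> dict[str, int]:
    """Episode count per attributed location, 'unknown' included."""
    out: dict[str, int] = {}
    for e in episodes:
        out[e.location] = out.get(e.location, 0) + 1
    return dict(sorted(out.items(), key=lambda kv: (-kv[1], kv[0])))


def connectedness_ranking(net: nx.Graph) -> pd.DataFrame:
    """Nodes ranked by weighted degree (most connected first).

    Ties break by degree, then node ID.  Nodes at or below the 10th
    percentile of weighted degree are flagged least-connected — the
    at-risk-of-isolation watch list.
    """
    k = netm.degree_centrality(net)
    s = netm.weighted_degree(net)
    nodes = sorted(net.nodes(), key=lambda v: (-s[v], -k[v], v))
    df = pd.DataFrame(
        {
            "device_id": nodes,
            "role": [net.nodes[v].get("role", "") for v in nodes],
            "home": [net.nodes[v].get("home", "") for v in nodes],
            "weighted_degree": [s[v] for v in nodes],
            "degree": [k[v] for v in nodes],
        }
    )
    df["rank"] = range(1, len(df) + 1)
    if len(df):
        cutoff = _quantile(df["weighted_degree"].tolist(), 0.10)
        df["least_connected"] = df["weighted_degree"] <= cutoff
    else:
        df["least_connected"] = pd.Series(dtype=bool)
    return df


@dataclass
class ReportBundle:
    """Everything the QI report renders, as plain tables and dicts."""

    strength_duration: pd.DataFrame
    centrality: pd.DataFrame
    contingency: Contingency
    unique: pd.DataFrame
    heatmap: pd.DataFrame
    temporal: pd.DataFrame
    locations: dict[str, int]
    ranking: pd.DataFrame
    partition: CommunityPartition
    network_stats: dict[str, float]
    n_sightings: int = 0
    n_rejects: int = 0
    n_filtered: int = 0
    n_episodes: int = 0
    n_long_episodes: int = 0
    manifest: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        c = self.contingency
        return {
            "counts": {
                "sightings_read": self.n_sightings,
                "sightings_rejected": self.n_rejects,
                "sightings_proximate": self.n_filtered,
                "episodes": self.n_episodes,
                "long_episodes": self.n_long_episodes,
            },
            "strength_duration": self.strength_duration.to_dict(orient="records"),
            "centrality_by_role": self.centrality.to_dict(orient="records"),
            "contingency": {
                "counts": c.counts.to_dict(),
                "row_totals": c.row_totals.to_dict(),
                "col_totals": c.col_totals.to_dict(),
                "grand_total": c.grand_total,
                "col_pct": c.col_pct.to_dict(),
            },
            "unique_interactions": self.unique.to_dict(orient="records"),
            "hour_heatmap": self.heatmap.to_dict(orient="index"),
            "locations": self.locations,
            "ranking": self.ranking.to_dict(orient="records"),
            "communities": {
                "labels": self.partition.labels,
                "q": self.partition.q,
                "n_communities": self.partition.n_communities,
                "density": {str(k): v for k, v in
                            self.partition.community_density.items()},
            },
            "network": self.network_stats,
            "manifest": self.manifest,
        }


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def analyze(
    sightings_path: str | Path,
    roster_path: str | Path,
    config: AnalysisConfig | None = None,
    louvain_seed: int = 0,
):
    """Run ingest → filter → sessionize → network → metrics → communities.

    Returns ``(bundle, net, episodes, rejects)``; :func:`run_pipeline`
    adds the on-disk artefacts.
    """
    config = config or AnalysisConfig()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # re-raise with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    roster = stage("read_roster", read_roster, roster_path)
    records, rejects = stage("read_sightings", read_sightings, sightings_path, roster)
    proximate = stage("filter_proximate", filter_proximate, records, config)
    episodes = stage("sessionize", sessionize, proximate, config, roster)
    episodes = stage("attribute_locations", attribute_locations,
                     episodes, proximate, config)
    net = stage("build_network", netm.build_network, episodes, roster)
    longs = long_episodes(episodes, config)
    partition = stage("louvain", louvain_partition, net, 1.0, louvain_seed)

    _, mean_clust = netm.clustering_coefficient(net)
    stats = {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "density": netm.density(net),
        "degree_centralization": netm.degree_centralization(net),
        "mean_clustering": mean_clust,
        "modularity_q": partition.q,
        "n_communities": partition.n_communities,
    }
    if net.number_of_edges() > 0:
        stats["role_assortativity"] = netm.role_assortativity(net)

    bundle = ReportBundle(
        strength_duration=strength_duration_summary(net, episodes, roster),
        centrality=centrality_by_role(net, roster),
        contingency=role_contingency(longs),
        unique=unique_interactions(episodes, roster),
        heatmap=temporal_heatmap(episodes, config.hour_bins,
                                 config.report_tz_offset_min),
        temporal=temporal_profile(episodes, config.hour_bins,
                                  config.report_tz_offset_min),
        locations=location_frequency(episodes),
        ranking=connectedness_ranking(net),
        partition=partition,
        network_stats=stats,
        n_sightings=len(records) + len(rejects),
        n_rejects=len(rejects),
        n_filtered=len(proximate),
        n_episodes=len(episodes),
        n_long_episodes=len(longs),
    )
    return bundle, net, episodes, rejects


def run_pipeline(
    config: AnalysisConfig | None,
    sightings_path: str | Path,
    roster_path: str | Path,
    out_dir: str | Path,
    louvain_seed: int = 0,
) -> ReportBundle:
    """End-to-end deterministic run writing every report artefact.

    Writes one CSV per table, the JSON bundle, GraphML/GEXF networks, the
    episode list, the rejects report and a run manifest (config hash,
    input digests, row and reject counts).  Identical inputs and config
    produce byte-identical outputs.
    """
    config = config or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle, net, episodes, rejects = analyze(
        sightings_path, roster_path, config, louvain_seed
    )

    cfg_json = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    bundle.manifest = {
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "inputs": {
            "sightings": {"path": str(sightings_path),
                          "sha256": _sha256(sightings_path)},
            "roster": {"path": str(roster_path), "sha256": _sha256(roster_path)},
        },
        "rows_read": bundle.n_sightings,
        "rows_rejected": bundle.n_rejects,
        "rows_proximate": bundle.n_filtered,
        "rssi_threshold": config.rssi_threshold,
        "rssi_keep_rule": config.rssi_keep_rule,
        "max_gap_s": config.max_gap_s,
        "long_interaction_min": config.long_interaction_min,
    }

    bundle.strength_duration.to_csv(out / "strength_duration.csv", index=False)
    bundle.centrality.to_csv(out / "centrality_by_role.csv", index=False)
    bundle.contingency.counts.to_csv(out / "role_contingency.csv")
    bundle.unique.to_csv(out / "unique_interactions.csv", index=False)
    bundle.heatmap.to_csv(out / "hour_heatmap.csv")
    bundle.temporal.to_csv(out / "temporal_profile.csv", index=False)
    pd.DataFrame(
        list(bundle.locations.items()), columns=["location", "n_episodes"]
    ).to_csv(out / "location_frequency.csv", index=False)
    bundle.ranking.to_csv(out / "connectedness_ranking.csv", index=False)
    write_episodes(episodes, out / "episodes.csv")
    write_rejects(rejects, out / "rejects.csv")

    for node, comm in bundle.partition.labels.items():
        net.nodes[node]["community"] = comm
    netm.export_network(net, out / "network")

    with open(out / "bundle.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.to_json_dict(), fh, indent=2, sort_keys=True, default=str)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
    return bundle
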