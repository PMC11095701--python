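"""Sessionizing proximity sightings into interaction episodes.

Consecutive sightings of the same dyad separated by gaps of at most
``max_gap_s`` seconds are merged into one *interaction episode* — a maximal
contact bout with a start, end, duration, ping count and an attributed
location.  A single isolated ping is an episode of duration zero: the data
carry no evidence of contact beyond that instant.
"""

from __future__ import annotations

import csv
import datetime as dt
from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

from .config import AnalysisConfig, role_pair_key
from .ingest import Roster, SightingRecord, canonical_dyad

EPISODE_HEADER = [
    "dyad_a", "dyad_b", "start", "end", "duration_min",
    "n_pings", "location", "role_a", "role_b",
]


@dataclass(frozen=True)
class InteractionEpisode:
    """A maximal merged run of proximate sightings for one dyad."""

    dyad: tuple[str, str]
    start: dt.datetime
    end: dt.datetime
    n_pings: int
    location: str = "unknown"
    role_pair: tuple[str, str] | None = None  # follows canonical dyad order
    mean_rssi: float | None = None

    @property
    def duration_min(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0

    def overlaps(self, win_start: dt.datetime, win_end: dt.datetime) -> bool:
        """True if the episode intersects the half-open window [start, end)."""
        return self.start < win_end and self.end >= win_start


def sessionize(
    records: Sequence[SightingRecord],
    config: AnalysisConfig,
    roster: Roster | None = None,
) -> list[InteractionEpisode]:
    """Greedy gap-merge of dyad sightings into episodes.

    Per canonical dyad, time-sorted pings are merged while the inter-ping
    gap is ≤ ``max_gap_s`` (strictly greater gaps split).  The result
    partitions the input: every dyad ping lands in exactly one episode and
    ping counts are conserved.  Location records are ignored here (see
    :func:`attribute_location`).  Invariant to input row order.
    """
    by_dyad: dict[tuple[str, str], list[SightingRecord]] = defaultdict(list)
    for r in records:
        if r.kind != "dyad":
            continue
        by_dyad[canonical_dyad(r.device_a, r.device_b)].append(r)

    max_gap = dt.timedelta(seconds=config.max_gap_s)
    episodes: list[InteractionEpisode] = []
    for dyad in sorted(by_dyad):
        pings = sorted(by_dyad[dyad], key=lambda r: r.timestamp)
        runs: list[list[SightingRecord]] = [[pings[0]]]
        for ping in pings[1:]:
            if ping.timestamp - runs[-1][-1].timestamp <= max_gap:
                runs[-1].append(ping)
            else:
                runs.append([ping])
        role_pair = None
        if roster is not None:
            role_pair = (roster.role(dyad[0]), roster.role(dyad[1]))
        for run in runs:
            rssi_mean = sum(p.rssi for p in run) / len(run)
            episodes.append(
                InteractionEpisode(
                    dyad=dyad,
                    start=run[0].timestamp,
                    end=run[-1].timestamp,
                    n_pings=len(run),
                    role_pair=role_pair,
                    mean_rssi=rssi_mean,
                )
            )
    episodes.sort(key=lambda e: (e.start, e.dyad))
    return episodes


def attribute_location(
    episode: InteractionEpisode,
    location_sightings: Sequence[SightingRecord],
    config: AnalysisConfig,
) -> str:
    """Modal location marker seen by either device around the episode.

    Counts location pings from both devices inside ``[start - max_gap,
    end + max_gap]``; the most frequent marker wins, ties broken by the
    marker observed earliest in the window; ``"unknown"`` if none.
    """
    pad = dt.timedelta(seconds=config.max_gap_s)
    lo, hi = episode.start - pad, episode.end + pad
    counts: Counter[str] = Counter()
    first_seen: dict[str, dt.datetime] = {}
    for r in location_sightings:
        if r.kind != "location" or r.device_a not in episode.dyad:
            continue
        if lo <= r.timestamp <= hi:
            counts[r.device_b] += 1
            if r.device_b not in first_seen or r.timestamp < first_seen[r.device_b]:
                first_seen[r.device_b] = r.timestamp
    if not counts:
        return "unknown"
    best = max(counts.values())
    tied = [m for m, c in counts.items() if c == best]
    return min(tied, key=lambda m: (first_seen[m], m))


def attribute_locations(
    episodes: Sequence[InteractionEpisode],
    records: Sequence[SightingRecord],
    config: AnalysisConfig,
) -> list[InteractionEpisode]:
    """Attach modal locations to every episode.

    Location pings are pre-indexed by device so the per-episode scan only
    touches candidate rows.
    """
    by_device: dict[str, list[SightingRecord]] = defaultdict(list)
    for r in records:
        if r.kind == "location":
            by_device[r.device_a].append(r)
    for pings in by_device.values():
        pings.sort(key=lambda r: r.timestamp)

    import bisect

    out = []
    pad = dt.timedelta(seconds=config.max_gap_s)
    for ep in episodes:
        lo, hi = ep.start - pad, ep.end + pad
        window: list[SightingRecord] = []
        for dev in ep.dyad:
            pings = by_device.get(dev, [])
            times = [p.timestamp for p in pings]
            i = bisect.bisect_left(times, lo)
            j = bisect.bisect_right(times, hi)
            window.extend(pings[i:j])
        label = attribute_location(ep, window, config)
        out.append(replace(ep, location=label))
    return out


def long_episodes(
    episodes: Sequence[InteractionEpisode], config: AnalysisConfig
) -> list[InteractionEpisode]:
    """Episodes strictly longer than the long-interaction threshold.

    "Over two minutes" is read strictly: an episode of exactly 2.0 min is
    not over two minutes.
    """
    return [e for e in episodes if e.duration_min > config.long_interaction_min]


def write_episodes(
    episodes: Sequence[InteractionEpisode], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EPISODE_HEADER)
        for e in episodes:
            role_a, role_b = e.role_pair if e.role_pair else ("", "")
            writer.writerow(
                [
                    e.dyad[0], e.dyad[1],
                    e.start.isoformat(), e.end.isoformat(),
                    f"{e.duration_min:.4f}", e.n_pings, e.location,
                    role_a, role_b,
                ]
            )


def symmetric_role_pair(role_a: str, role_b: str) -> tuple[str, str]:
    """Collapse an ordered role pair to its unordered canonical form."""
    return role_pair_key(role_a, role_b)
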