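"""Synthetic care-home proximity streams with known ground truth.

The simulator emulates the data a BLE-wearable deployment produces in a
care home: dyad sightings (wearable saw wearable) and device-location
sightings (wearable saw a static marker), each with a timestamp and an
RSSI drawn from a log-distance path-loss model.  Contact episodes arise
from an inhomogeneous Poisson process per dyad whose rate is a base
role-pair rate modulated by piecewise-constant temporal factors:

* staff-involving dyads interact only inside staff shift windows;
* staff-staff rates spike in short handover windows at shift start,
  middle and end;
* staff-resident and staff-staff rates rise in a 10:00-15:00 midday
  window;
* dyads sharing a planted unit interact ``within_unit_bias`` times more,
  which plants recoverable subcommunities.

Every emitted sighting derives from exactly one true episode (or is a
decoy far-distance ping, off by default), so the returned
:class:`GroundTruth` is an exact oracle for sessionization, network
weights and community recovery.
"""

from __future__ import annotations

import csv
import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import DurationModel, HomeConfig, RssiModel, pair_key_str
from .ingest import Roster, RosterEntry, SightingRecord, canonical_dyad

TRUTH_EPISODE_HEADER = ["dyad_a", "dyad_b", "start", "end", "location"]
TRUTH_COMMUNITY_HEADER = ["device_id", "unit"]

# relative preference for where a given kind of pair meets; labels not in
# the config's location list are ignored, unknown labels weighted 1
_LOCATION_PREFS: dict[str, dict[str, float]] = {
    "resident-resident": {"lounge": 4, "dining": 3, "corridor": 1,
                          "staff-room": 0.01, "smoking-shelter": 0.2},
    "resident-staff": {"lounge": 3, "dining": 2.5, "corridor": 1.5,
                       "staff-room": 0.05, "smoking-shelter": 0.2},
    "staff-staff": {"lounge": 1, "dining": 1, "corridor": 2,
                    "staff-room": 3, "smoking-shelter": 0.5},
}


@dataclass(frozen=True)
class TrueEpisode:
    dyad: tuple[str, str]
    start: dt.datetime
    end: dt.datetime
    location: str

    @property
    def duration_min(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0


@dataclass
class GroundTruth:
    """Oracle for every downstream stage.

    ``realized_rates`` holds episodes per effective dyad-hour of exposure
    per role pair (exposure is weighted by the temporal boosts and unit
    bias, so each entry estimates the corresponding base rate_matrix
    entry); it is derived data and is not round-tripped by
    :func:`write_truth`.
    """

    episodes: list[TrueEpisode] = field(default_factory=list)
    communities: dict[str, int] = field(default_factory=dict)
    realized_rates: dict[str, float] = field(default_factory=dict)
    exposure_dyad_hours: dict[str, float] = field(default_factory=dict)

    def episode_counts_by_dyad(self) -> dict[tuple[str, str], int]:
        counts: dict[tuple[str, str], int] = {}
        for e in self.episodes:
            counts[e.dyad] = counts.get(e.dyad, 0) + 1
        return counts


def rssi_from_distance(d_m: float, model: RssiModel, noise_draw: float = 0.0) -> float:
    """Log-distance path loss: rssi_at_1m − 10·n·log10(d) + noise.

    Strictly decreasing in distance at zero noise; anchored so that
    ``rssi(1 m) = rssi_at_1m`` exactly.
    """
    if d_m <= 0:
        raise ValueError(f"distance must be positive, got {d_m}")
    return model.rssi_at_1m - 10.0 * model.exponent * math.log10(d_m) + noise_draw


def _clock_s(hhmm: str) -> float:
    h, m = hhmm.split(":")
    return int(h) * 3600 + int(m) * 60


def _merge_spans(spans: list[tuple[float, float]]) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    for lo, hi in sorted(spans):
        if out and lo <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def _handover_spans(cfg: HomeConfig) -> list[tuple[float, float]]:
    half = cfg.handover_min * 60 / 2
    spans = []
    for start, end in cfg.shift_windows:
        s, e = _clock_s(start), _clock_s(end)
        mid = (s + e) / 2
        spans.extend([(s, s + 2 * half), (mid - half, mid + half), (e - 2 * half, e)])
    return _merge_spans(spans)


def _pair_activity_spans(cfg: HomeConfig, pair: str) -> list[tuple[float, float]]:
    """Seconds-of-day spans in which a role pair can interact."""
    if pair == "resident-resident":
        return [(_clock_s(cfg.resident_day[0]), _clock_s(cfg.resident_day[1]))]
    return _merge_spans(
        [(_clock_s(s), _clock_s(e)) for s, e in cfg.shift_windows]
    )


def _pair_segments(cfg: HomeConfig, pair: str) -> list[tuple[float, float, float]]:
    """Piecewise-constant (start_s, end_s, multiplier) segments for a pair.

    Staff-staff handover spans multiply by ``handover_boost``; the
    10:00-15:00 midday window multiplies staff-staff and staff-resident
    (agency counted as staff) by ``midday_boost``; boosts compound where
    windows overlap.
    """
    activity = _pair_activity_spans(cfg, pair)
    staffish = {"agency", "staff"}
    roles = set(pair.split("-"))
    midday_applies = bool(roles & staffish)  # staff-resident, staff-staff, agency mixes
    handover_applies = pair == "staff-staff"

    cuts: set[float] = set()
    for lo, hi in activity:
        cuts.update((lo, hi))
    handovers = _handover_spans(cfg) if handover_applies else []
    for lo, hi in handovers:
        cuts.update((lo, hi))
    if midday_applies:
        cuts.update((_clock_s("10:00"), _clock_s("15:00")))

    bounds = sorted(cuts)
    segments: list[tuple[float, float, float]] = []
    for lo, hi in zip(bounds, bounds[1:]):
        mid = (lo + hi) / 2
        if not any(a <= mid < b for a, b in activity):
            continue
        mult = 1.0
        if handover_applies and any(a <= mid < b for a, b in handovers):
            mult *= cfg.handover_boost
        if midday_applies and _clock_s("10:00") <= mid < _clock_s("15:00"):
            mult *= cfg.midday_boost
        segments.append((lo, hi, mult))
    return segments


def make_roster(cfg: HomeConfig) -> Roster:
    """Roster for the simulated population (device → role/home/unit)."""
    units = cfg.units()
    entries: dict[str, RosterEntry] = {}
    for device in cfg.resident_ids():
        entries[device] = RosterEntry("resident", cfg.home, f"unit-{units[device]}")
    for device in cfg.staff_ids():
        entries[device] = RosterEntry("staff", cfg.home, f"unit-{units[device]}")
    for device in cfg.agency_ids():
        entries[device] = RosterEntry("agency", cfg.home, None)
    return Roster(entries)


def _location_weights(cfg: HomeConfig, pair: str) -> np.ndarray:
    if pair.startswith("agency"):
        pair = pair.replace("agency", "staff")
        a, b = sorted(pair.split("-"))
        pair = f"{a}-{b}"
    prefs = _LOCATION_PREFS.get(pair, {})
    w = np.array([prefs.get(loc, 1.0) for loc in cfg.locations], dtype=float)
    if w.sum() == 0 or len(w) == 0:
        return np.ones(max(len(w), 1)) / max(len(w), 1)
    return w / w.sum()


def emit_episode_pings(
    dyad: tuple[str, str],
    start: dt.datetime,
    end: dt.datetime,
    location: str | None,
    cfg: HomeConfig,
    rng: np.random.Generator,
) -> list[SightingRecord]:
    """Pings for one ongoing episode at the configured scan cadence.

    Scan times form a grid ``start + k·ping_interval_s`` for every k with
    the time still ≤ end (a 10-minute episode at 60 s cadence yields 11
    dyad pings).  The pair's separation is drawn once per episode from
    U(0.3, 1.5) m, so at zero noise all pings of an episode share one
    RSSI.  Each scheduled scan — dyad and location alike — is dropped
    independently with ``ping_miss_prob``.
    """
    a, b = canonical_dyad(*dyad)
    interval = cfg.ping_interval_s
    n_pings = int(math.floor((end - start).total_seconds() / interval + 1e-9)) + 1
    d_pair = rng.uniform(0.3, 1.5)
    d_loc = {dev: rng.uniform(0.3, 3.0) for dev in (a, b)}
    out: list[SightingRecord] = []
    for k in range(n_pings):
        t = start + dt.timedelta(seconds=k * interval)
        if rng.random() >= cfg.ping_miss_prob:
            noise = rng.normal(0.0, cfg.rssi_model.noise_sd) if cfg.rssi_model.noise_sd else 0.0
            out.append(SightingRecord(a, b, t, rssi_from_distance(d_pair, cfg.rssi_model, noise), "dyad"))
        if location:
            for dev in (a, b):
                if rng.random() >= cfg.ping_miss_prob:
                    noise = rng.normal(0.0, cfg.rssi_model.noise_sd) if cfg.rssi_model.noise_sd else 0.0
                    out.append(
                        SightingRecord(
                            dev, location, t,
                            rssi_from_distance(d_loc[dev], cfg.rssi_model, noise),
                            "location",
                        )
                    )
    return out


def _draw_duration_s(model: DurationModel, rng: np.random.Generator) -> float:
    return model.median_min * 60.0 * math.exp(model.sigma * rng.standard_normal())


def simulate_home(cfg: HomeConfig) -> tuple[list[SightingRecord], GroundTruth]:
    """Simulate ``sim_days`` of sighting traffic for one home.

    Deterministic given ``cfg.seed``.  Returns the time-sorted sighting
    stream and the ground truth (true episodes after merging bouts closer
    than one ping interval, planted unit labels, realized role-pair
    rates).
    """
    rng = np.random.default_rng(cfg.seed)
    tz = cfg.tzinfo()
    units = cfg.units()
    roles = {d: "resident" for d in cfg.resident_ids()}
    roles.update({d: "staff" for d in cfg.staff_ids()})
    roles.update({d: "agency" for d in cfg.agency_ids()})
    people = sorted(roles)

    # agency presence: Bernoulli per agency worker per day
    agency = cfg.agency_ids()
    presence = {
        d: rng.random(cfg.sim_days) < cfg.agency_presence_prob for d in agency
    }

    # group dyads by (role-pair, same planted unit)
    groups: dict[tuple[str, bool], list[tuple[str, str]]] = {}
    for i, a in enumerate(people):
        for b in people[i + 1:]:
            pair = pair_key_str(roles[a], roles[b])
            same_unit = a in units and b in units and units[a] == units[b]
            groups.setdefault((pair, same_unit), []).append((a, b))

    segments_by_pair = {
        pair: _pair_segments(cfg, pair)
        for pair in {p for p, _ in groups}
    }
    loc_weights = {pair: _location_weights(cfg, pair) for pair in segments_by_pair}
    locations = cfg.locations or [None]

    raw_episodes: dict[tuple[str, str], list[tuple[dt.datetime, dt.datetime, str]]] = {}
    exposure: dict[str, float] = {}

    for day in range(cfg.sim_days):
        day_start = dt.datetime.combine(
            cfg.start_date + dt.timedelta(days=day), dt.time(0, 0), tzinfo=tz
        )
        for (pair, same_unit), dyads in sorted(groups.items()):
            active = [
                (a, b) for a, b in dyads
                if (roles[a] != "agency" or presence[a][day])
                and (roles[b] != "agency" or presence[b][day])
            ]
            if not active:
                continue
            base = cfg.rate_matrix.get(pair, 0.0)
            bias = cfg.within_unit_bias if same_unit else 1.0
            dmodel = cfg.duration_model.get(
                pair, DurationModel(median_min=0.5, sigma=0.7)
            )
            for lo, hi, mult in segments_by_pair[pair]:
                hours = (hi - lo) / 3600.0
                lam = base * mult * bias * hours
                exposure[pair] = exposure.get(pair, 0.0) + mult * bias * hours * len(active)
                if lam <= 0:
                    continue
                counts = rng.poisson(lam, size=len(active))
                for dyad, n in zip(active, counts):
                    for _ in range(int(n)):
                        t0 = day_start + dt.timedelta(
                            seconds=float(rng.uniform(lo, hi))
                        )
                        t1 = t0 + dt.timedelta(seconds=_draw_duration_s(dmodel, rng))
                        if cfg.locations:
                            loc = locations[
                                int(rng.choice(len(locations), p=loc_weights[pair]))
                            ]
                        else:
                            loc = None
                        raw_episodes.setdefault(dyad, []).append((t0, t1, loc))

    # merge per-dyad bouts with gap ≤ ping_interval_s: at the scan cadence
    # they are indistinguishable from one continuous episode
    gap = dt.timedelta(seconds=cfg.ping_interval_s)
    truth_eps: list[TrueEpisode] = []
    for dyad in sorted(raw_episodes):
        bouts = sorted(raw_episodes[dyad])
        merged = [list(bouts[0])]
        for t0, t1, loc in bouts[1:]:
            if t0 - merged[-1][1] <= gap:
                merged[-1][1] = max(merged[-1][1], t1)
            else:
                merged.append([t0, t1, loc])
        for t0, t1, loc in merged:
            truth_eps.append(TrueEpisode(dyad, t0, t1, loc or "unknown"))

    sightings: list[SightingRecord] = []
    for ep in sorted(truth_eps, key=lambda e: (e.start, e.dyad)):
        loc = ep.location if ep.location != "unknown" else None
        sightings.extend(
            emit_episode_pings(ep.dyad, ep.start, ep.end, loc, cfg, rng)
        )

    # optional decoy far-distance pings (ambient radio clutter)
    if cfg.decoy_rate_per_dyad_hour > 0:
        for (pair, _), dyads in sorted(groups.items()):
            spans = _pair_activity_spans(cfg, pair)
            hours = sum(hi - lo for lo, hi in spans) / 3600.0 * cfg.sim_days
            for a, b in dyads:
                for _ in range(int(rng.poisson(cfg.decoy_rate_per_dyad_hour * hours))):
                    day = int(rng.integers(cfg.sim_days))
                    lo, hi = spans[int(rng.integers(len(spans)))]
                    t = dt.datetime.combine(
                        cfg.start_date + dt.timedelta(days=day), dt.time(0, 0),
                        tzinfo=tz,
                    ) + dt.timedelta(seconds=float(rng.uniform(lo, hi)))
                    d_far = rng.uniform(3.0, 10.0)
                    noise = rng.normal(0.0, cfg.rssi_model.noise_sd) if cfg.rssi_model.noise_sd else 0.0
                    sightings.append(
                        SightingRecord(a, b, t, rssi_from_distance(d_far, cfg.rssi_model, noise), "dyad")
                    )

    sightings.sort(key=lambda r: (r.timestamp, r.device_a, r.device_b, r.kind))

    n_by_pair: dict[str, int] = {}
    for ep in truth_eps:
        pair = pair_key_str(roles[ep.dyad[0]], roles[ep.dyad[1]])
        n_by_pair[pair] = n_by_pair.get(pair, 0) + 1
    realized = {
        pair: n_by_pair.get(pair, 0) / exposure[pair]
        for pair in exposure
        if exposure[pair] > 0
    }

    truth = GroundTruth(
        episodes=sorted(truth_eps, key=lambda e: (e.start, e.dyad)),
        communities={node: units[node] for node in units},
        realized_rates=realized,
        exposure_dyad_hours=exposure,
    )
    return sightings, truth


def write_truth(truth: GroundTruth, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ground truth as two CSVs (episodes, community labels)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ep_path = out / "truth_episodes.csv"
    com_path = out / "truth_communities.csv"
    with open(ep_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRUTH_EPISODE_HEADER)
        for e in truth.episodes:
            writer.writerow(
                [e.dyad[0], e.dyad[1], e.start.isoformat(), e.end.isoformat(), e.location]
            )
    with open(com_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRUTH_COMMUNITY_HEADER)
        for node in sorted(truth.communities):
            writer.writerow([node, truth.communities[node]])
    return ep_path, com_path


def read_truth(out_dir: str | Path) -> GroundTruth:
    """Read back ground truth written by :func:`write_truth`.

    Realized rates are derived quantities and are not stored; the reader
    returns them empty.
    """
    out = Path(out_dir)
    episodes: list[TrueEpisode] = []
    with open(out / "truth_episodes.csv", "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            episodes.append(
                TrueEpisode(
                    (row["dyad_a"], row["dyad_b"]),
                    dt.datetime.fromisoformat(row["start"]),
                    dt.datetime.fromisoformat(row["end"]),
                    row["location"],
                )
            )
    communities: dict[str, int] = {}
    with open(out / "truth_communities.csv", "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            communities[row["device_id"]] = int(row["unit"])
    return GroundTruth(episodes=episodes, communities=communities)
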