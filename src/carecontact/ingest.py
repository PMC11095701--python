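"""Reading, validating and proximity-filtering raw sighting streams.

A *sighting* is one BLE scan event: ``device_a`` saw ``device_b`` (another
wearable, or a static location marker) at an instant with a received signal
strength in dBm.  The CSV dialect is fixed: UTF-8, comma-separated, header
exactly ``device_a,device_b,timestamp,rssi``, ISO-8601 timestamps.

Malformed rows are never silently dropped: :func:`read_sightings` returns
both the validated records and a rejects report with row numbers and
reasons, and ``len(kept) + len(rejected)`` always equals the row count.
"""

from __future__ import annotations

import csv
import datetime as dt
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .config import AnalysisConfig, Role

SIGHTING_HEADER = ["device_a", "device_b", "timestamp", "rssi"]
ROSTER_HEADER = ["device_id", "role", "home", "unit"]
VALID_ROLES = ("resident", "staff", "agency")


@dataclass(frozen=True)
class SightingRecord:
    """One raw scan observation (dyad or device-location)."""

    device_a: str
    device_b: str
    timestamp: dt.datetime  # timezone-aware; normalized to UTC on read
    rssi: float
    kind: Literal["dyad", "location"] = "dyad"


@dataclass(frozen=True)
class RosterEntry:
    role: Role
    home: str
    unit: str | None = None


@dataclass
class Roster:
    """Device ID → (role, home, optional unit)."""

    entries: dict[str, RosterEntry] = field(default_factory=dict)

    def __contains__(self, device_id: str) -> bool:
        return device_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def role(self, device_id: str) -> Role:
        return self.entries[device_id].role

    def home(self, device_id: str) -> str:
        return self.entries[device_id].home

    def unit(self, device_id: str) -> str | None:
        return self.entries[device_id].unit

    def devices(self) -> list[str]:
        return sorted(self.entries)


@dataclass(frozen=True)
class Reject:
    row: int  # 1-based data-row number (header not counted)
    reason: str


class IngestError(ValueError):
    """Hard ingest failure (bad header, bad roster)."""


def canonical_dyad(a: str, b: str) -> tuple[str, str]:
    """Order a device pair lexicographically; symmetric and idempotent.

    The wearables record undirected co-presence, so ``(a, b)`` and
    ``(b, a)`` name the same tie.
    """
    if a == b:
        raise ValueError(f"self-pair is not a dyad: {a!r}")
    return (a, b) if a < b else (b, a)


def _parse_timestamp(text: str) -> dt.datetime:
    ts = dt.datetime.fromisoformat(text.strip())
    if ts.tzinfo is None:
        raise ValueError("timestamp lacks a UTC offset")
    return ts.astimezone(dt.timezone.utc)


def read_sightings(
    path: str | Path, roster: Roster | None = None
) -> tuple[list[SightingRecord], list[Reject]]:
    """Read a sightings CSV, validating every row.

    With a roster, each record's ``kind`` is set to ``"dyad"`` when
    ``device_b`` is a rostered wearable and ``"location"`` otherwise.
    Returns ``(kept, rejects)``; a missing or wrong header is a hard
    :class:`IngestError`.
    """
    kept: list[SightingRecord] = []
    rejects: list[Reject] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise IngestError(f"{path}: empty file, expected header "
                              f"{','.join(SIGHTING_HEADER)}") from None
        if [h.strip() for h in header] != SIGHTING_HEADER:
            raise IngestError(
                f"{path}: bad header {header!r}, expected {SIGHTING_HEADER}"
            )
        for row_no, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                rejects.append(Reject(row_no, "blank row"))
                continue
            if len(row) != 4:
                rejects.append(Reject(row_no, f"expected 4 fields, got {len(row)}"))
                continue
            a, b, ts_text, rssi_text = (c.strip() for c in row)
            if not a or not b:
                rejects.append(Reject(row_no, "empty device ID"))
                continue
            if a == b:
                rejects.append(Reject(row_no, f"self-sighting {a!r}"))
                continue
            try:
                ts = _parse_timestamp(ts_text)
            except ValueError as exc:
                rejects.append(Reject(row_no, f"bad timestamp {ts_text!r}: {exc}"))
                continue
            try:
                rssi = float(rssi_text)
            except ValueError:
                rejects.append(Reject(row_no, f"bad rssi {rssi_text!r}"))
                continue
            if not math.isfinite(rssi):
                rejects.append(Reject(row_no, f"non-finite rssi {rssi_text!r}"))
                continue
            if rssi >= 0:
                rejects.append(Reject(row_no, f"rssi must be negative dBm, got {rssi}"))
                continue
            kind: Literal["dyad", "location"] = "dyad"
            if roster is not None:
                kind = "dyad" if b in roster else "location"
            kept.append(SightingRecord(a, b, ts, rssi, kind))
    return kept, rejects


def classify_kind(
    records: Iterable[SightingRecord], roster: Roster
) -> list[SightingRecord]:
    """Re-derive each record's dyad/location kind against a roster."""
    out = []
    for r in records:
        kind: Literal["dyad", "location"] = "dyad" if r.device_b in roster else "location"
        out.append(replace(r, kind=kind) if kind != r.kind else r)
    return out


def write_sightings(records: Sequence[SightingRecord], path: str | Path) -> None:
    """Write sightings in the package CSV dialect (inverse of the reader)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SIGHTING_HEADER)
        for r in records:
            writer.writerow(
                [r.device_a, r.device_b, r.timestamp.isoformat(), f"{r.rssi:.1f}"]
            )


def write_rejects(rejects: Sequence[Reject], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "reason"])
        for rej in rejects:
            writer.writerow([rej.row, rej.reason])


def read_roster(path: str | Path) -> Roster:
    """Read the device roster (``device_id,role,home,unit``).

    Unknown roles and duplicate device IDs are hard errors listing the
    offending IDs — a silently mangled roster would misattribute every
    downstream role-stratified table.
    """
    entries: dict[str, RosterEntry] = {}
    bad_roles: list[str] = []
    dups: list[str] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise IngestError(f"{path}: empty roster") from None
        if [h.strip() for h in header] != ROSTER_HEADER:
            raise IngestError(
                f"{path}: bad roster header {header!r}, expected {ROSTER_HEADER}"
            )
        for row_no, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 4:
                raise IngestError(f"{path}: row {row_no}: expected 4 fields")
            device_id, role, home, unit = (c.strip() for c in row)
            if role not in VALID_ROLES:
                bad_roles.append(f"row {row_no}: {device_id!r} has role {role!r}")
                continue
            if device_id in entries:
                dups.append(device_id)
                continue
            entries[device_id] = RosterEntry(role, home, unit or None)  # type: ignore[arg-type]
    if bad_roles:
        raise IngestError(
            f"{path}: unknown roles (must be one of {VALID_ROLES}): "
            + "; ".join(bad_roles)
        )
    if dups:
        raise IngestError(f"{path}: duplicate device IDs: {sorted(set(dups))}")
    return Roster(entries)


def write_roster(roster: Roster, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ROSTER_HEADER)
        for device_id in roster.devices():
            e = roster.entries[device_id]
            writer.writerow([device_id, e.role, e.home, e.unit or ""])


def filter_proximate(
    records: Sequence[SightingRecord], config: AnalysisConfig
) -> list[SightingRecord]:
    """Keep dyad sightings passing the RSSI proximity rule.

    ``stronger_than_threshold`` (default) keeps rssi ≥ threshold: in the
    log-distance path-loss model a stronger (less negative) signal means a
    closer pair.  The mirrored rule is available for hardware whose
    calibration inverts the reading.  Location sightings always pass;
    order is preserved; the operation is idempotent.
    """
    thr = config.rssi_threshold
    if config.rssi_keep_rule == "stronger_than_threshold":
        keep = lambda r: r.rssi >= thr  # noqa: E731
    else:
        keep = lambda r: r.rssi < thr  # noqa: E731
    return [r for r in records if r.kind == "location" or keep(r)]
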