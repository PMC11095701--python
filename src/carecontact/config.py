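"""Configuration objects for simulation and analysis.

Two configs drive the package: :class:`HomeConfig` parameterises the
synthetic care-home simulator, :class:`AnalysisConfig` parameterises the
ingest → episodes → network pipeline.  Both round-trip through YAML with
key names identical to the field names.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

Role = Literal["resident", "staff", "agency"]

#: canonical role-pair keys, alphabetical within the pair
ROLE_PAIRS = (
    ("agency", "agency"),
    ("agency", "resident"),
    ("agency", "staff"),
    ("resident", "resident"),
    ("resident", "staff"),
    ("staff", "staff"),
)


def role_pair_key(role_a: str, role_b: str) -> tuple[str, str]:
    """Unordered role pair as a canonical (alphabetically sorted) tuple."""
    return (role_a, role_b) if role_a <= role_b else (role_b, role_a)


class RssiModel(BaseModel):
    """Log-distance path-loss model for received signal strength.

    rssi(d) = rssi_at_1m - 10 * exponent * log10(d) + N(0, noise_sd)

    The default anchor is calibrated so that the conventional -75 dBm
    proximity cut falls at ~1.6 m: pairs inside the 1.5 m contact radius
    read stronger than -75 dBm, markers or decoys at 3 m and beyond read
    weaker.
    """

    rssi_at_1m: float = -71.0
    exponent: float = 2.0
    noise_sd: float = Field(default=4.0, ge=0.0)


class DurationModel(BaseModel):
    """Log-normal episode duration: median minutes and log-scale dispersion."""

    median_min: float = Field(gt=0.0)
    sigma: float = Field(ge=0.0)


def _default_rate_matrix() -> dict[str, float]:
    # episodes per dyad-hour of joint activity; staff pairs busiest,
    # resident pairs sparse (day-room mingling), agency treated like staff
    # but presence-limited elsewhere
    return {
        "agency-agency": 0.02,
        "agency-resident": 0.02,
        "agency-staff": 0.04,
        "resident-resident": 0.02,
        "resident-staff": 0.05,
        "staff-staff": 0.08,
    }


def _default_duration_models() -> dict[str, DurationModel]:
    # short-contact regime: most bouts well under a minute, a small tail
    # beyond two minutes (passing contacts dominate care-home proximity data)
    return {
        "agency-agency": DurationModel(median_min=0.5, sigma=0.7),
        "agency-resident": DurationModel(median_min=0.6, sigma=0.7),
        "agency-staff": DurationModel(median_min=0.5, sigma=0.7),
        "resident-resident": DurationModel(median_min=0.8, sigma=0.7),
        "resident-staff": DurationModel(median_min=0.6, sigma=0.7),
        "staff-staff": DurationModel(median_min=0.5, sigma=0.7),
    }


def pair_key_str(role_a: str, role_b: str) -> str:
    a, b = role_pair_key(role_a, role_b)
    return f"{a}-{b}"


class HomeConfig(BaseModel):
    """Parameters of the synthetic care home.

    Defaults describe a mid-sized home (population ~50, one 08:00-20:00
    staff shift, handover spikes at shift start/middle/end, a busier
    10:00-15:00 midday window) so that simulated streams carry the
    temporal signatures observed in real care-home proximity data.
    """

    n_residents: int = Field(default=20, ge=0)
    n_staff: int = Field(default=30, ge=0)
    n_agency: int = Field(default=2, ge=0)
    home: str = "synthome"
    locations: list[str] = Field(
        default_factory=lambda: [
            "lounge",
            "dining",
            "corridor",
            "staff-room",
            "smoking-shelter",
        ]
    )
    n_units: int = Field(default=2, ge=1)
    unit_assignment: dict[str, int] | None = None
    shift_windows: list[tuple[str, str]] = Field(
        default_factory=lambda: [("08:00", "20:00")]
    )
    resident_day: tuple[str, str] = ("07:00", "22:00")
    rate_matrix: dict[str, float] = Field(default_factory=_default_rate_matrix)
    handover_boost: float = Field(default=3.0, ge=0.0)
    handover_min: float = Field(default=30.0, gt=0.0)
    midday_boost: float = Field(default=1.8, ge=0.0)
    duration_model: dict[str, DurationModel] = Field(
        default_factory=_default_duration_models
    )
    within_unit_bias: float = Field(default=3.0, ge=1.0)
    agency_presence_prob: float = Field(default=0.3, ge=0.0, le=1.0)
    ping_interval_s: float = Field(default=60.0, gt=0.0)
    ping_miss_prob: float = Field(default=0.05, ge=0.0, lt=1.0)
    rssi_model: RssiModel = Field(default_factory=RssiModel)
    decoy_rate_per_dyad_hour: float = Field(default=0.0, ge=0.0)
    sim_days: int = Field(default=7, ge=1)
    start_date: dt.date = dt.date(2021, 11, 29)
    utc_offset_min: int = 0
    seed: int = 0

    @field_validator("rate_matrix")
    @classmethod
    def _rates_nonneg(cls, v: dict[str, float]) -> dict[str, float]:
        bad = {k: r for k, r in v.items() if r < 0}
        if bad:
            raise ValueError(f"negative rate_matrix entries: {bad}")
        return v

    @model_validator(mode="after")
    def _check_population(self) -> "HomeConfig":
        if self.unit_assignment is not None:
            wearers = set(self.resident_ids()) | set(self.staff_ids())
            assigned = set(self.unit_assignment)
            if assigned != wearers:
                missing = sorted(wearers - assigned)
                extra = sorted(assigned - wearers)
                raise ValueError(
                    "unit_assignment must cover every resident and staff "
                    f"exactly once (missing={missing}, unexpected={extra})"
                )
        return self

    # -- population naming ------------------------------------------------
    def resident_ids(self) -> list[str]:
        return [f"R{i:03d}" for i in range(1, self.n_residents + 1)]

    def staff_ids(self) -> list[str]:
        return [f"S{i:03d}" for i in range(1, self.n_staff + 1)]

    def agency_ids(self) -> list[str]:
        return [f"A{i:03d}" for i in range(1, self.n_agency + 1)]

    def all_ids(self) -> list[str]:
        return self.resident_ids() + self.staff_ids() + self.agency_ids()

    def units(self) -> dict[str, int]:
        """Planted unit label per resident/staff node (agency unattached).

        Default assignment interleaves residents and staff round-robin so
        every unit mixes both roles.
        """
        if self.unit_assignment is not None:
            return dict(self.unit_assignment)
        out: dict[str, int] = {}
        for ids in (self.resident_ids(), self.staff_ids()):
            for i, node in enumerate(ids):
                out[node] = i % self.n_units
        return out

    def tzinfo(self) -> dt.timezone:
        return dt.timezone(dt.timedelta(minutes=self.utc_offset_min))


class AnalysisConfig(BaseModel):
    """Pipeline thresholds: proximity filter, sessionization, reporting."""

    rssi_threshold: float = -75.0
    rssi_keep_rule: Literal[
        "stronger_than_threshold", "weaker_than_threshold"
    ] = "stronger_than_threshold"
    max_gap_s: float = Field(default=60.0, gt=0.0)
    long_interaction_min: float = Field(default=2.0, gt=0.0)
    hour_bins: int = Field(default=1, ge=1)  # report bin width, hours
    report_tz_offset_min: int = 0


def load_config(path: str | Path, kind: type[BaseModel]) -> BaseModel:
    """Load a HomeConfig or AnalysisConfig from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return kind.model_validate(data)


def save_config(cfg: BaseModel, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.model_dump(mode="json"), fh, sort_keys=True)
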