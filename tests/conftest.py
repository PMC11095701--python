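"""Shared fixtures: tiny synthetic streams, record factories, graph makers."""

from __future__ import annotations

import datetime as dt

import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

from carecontact import AnalysisConfig, HomeConfig, Roster, SightingRecord

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from carecontact.ingest import RosterEntry

T0 = dt.datetime(2021, 11, 29, 8, 0, tzinfo=dt.timezone.utc)


def ping(a: str, b: str, t_s: float, rssi: float = -60.0, kind: str = "dyad") -> SightingRecord:
    """Sighting at T0 + t_s seconds."""
    return SightingRecord(a, b, T0 + dt.timedelta(seconds=t_s), rssi, kind)


@pytest.fixture
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def tiny_roster() -> Roster:
    return Roster(
        {
            "A": RosterEntry("resident", "home1", "unit-0"),
            "B": RosterEntry("staff", "home1", "unit-0"),
            "C": RosterEntry("resident", "home1", "unit-1"),
            "D": RosterEntry("staff", "home1", "unit-1"),
            "E": RosterEntry("agency", "home1", None),
        }
    )


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free, loss-free 2-day simulation with its config and truth.

    miss_prob=0 and noise_sd=0 make the ground truth an exact oracle for
    filtering, sessionization and network weights.
    """
    from carecontact import simulate_home
    from carecontact.config import RssiModel

    config = HomeConfig(
        n_residents=8,
        n_staff=10,
        n_agency=1,
        sim_days=2,
        seed=11,
        ping_miss_prob=0.0,
        rssi_model=RssiModel(noise_sd=0.0),
    )
    sightings, truth = simulate_home(config)
    return config, sightings, truth


def random_graph(rng: np.random.Generator, n_max: int = 7, weighted: bool = False) -> nx.Graph:
    """Random labelled graph with string node IDs, possibly disconnected."""
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.2, 0.9))
    g = nx.Graph()
    g.add_nodes_from(f"n{i}" for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w = float(rng.integers(1, 9)) if weighted else 1
                g.add_edge(f"n{i}", f"n{j}", weight=w)
    return g
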