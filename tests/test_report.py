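"""QI report tables and the end-to-end pipeline."""

from __future__ import annotations

import datetime as dt
import filecmp
import random

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from carecontact import (
    AnalysisConfig,
    HomeConfig,
    Roster,
    build_network,
    centrality_by_role,
    connectedness_ranking,
    contingency_summary,
    location_frequency,
    make_roster,
    role_contingency,
    run_pipeline,
    simulate_home,
    strength_duration_summary,
    temporal_heatmap,
    temporal_profile,
    unique_interactions,
    write_roster,
    write_sightings,
)
from carecontact.episodes import InteractionEpisode
from carecontact.ingest import RosterEntry

from conftest import T0


def episode(a, b, start_s=0.0, dur_s=60.0, roles=("resident", "staff"),
            location="unknown"):
    dyad = tuple(sorted((a, b)))
    return InteractionEpisode(
        dyad,
        T0 + dt.timedelta(seconds=start_s),
        T0 + dt.timedelta(seconds=start_s + dur_s),
        n_pings=2,
        location=location,
        role_pair=roles,
        mean_rssi=-60.0,
    )


class TestStrengthDuration:
    def test_single_edge_single_episode(self, tiny_roster):
        eps = [episode("A", "B", dur_s=480)]
        net = build_network(eps, tiny_roster)
        df = strength_duration_summary(net, eps, tiny_roster)
        row = df[df.home == "home1"].iloc[0]
        assert row.weight_median == 1 and row.weight_iqr == 0
        assert row.duration_median_min == pytest.approx(8.0)
        assert row.duration_iqr_min == 0

    def test_linear_interpolation_quantiles(self):
        roster = Roster({c: RosterEntry("staff", "h") for c in "ABCDE"})
        # weights 1,2,3,4 on four dyads
        eps = []
        for i, (a, b) in enumerate([("A", "B"), ("A", "C"), ("A", "D"), ("A", "E")]):
            eps.extend(episode(a, b, start_s=200 * j, roles=("staff", "staff"))
                       for j in range(i + 1))
        net = build_network(eps, roster)
        df = strength_duration_summary(net, eps, roster)
        row = df.iloc[0]
        # numpy linear rule on {1,2,3,4}: median 2.5, q1 1.75, q3 3.25
        assert row.weight_median == pytest.approx(2.5)
        assert row.weight_iqr == pytest.approx(1.5)

    def test_home_without_episodes_gets_null_row(self):
        roster = Roster({
            "A": RosterEntry("resident", "busy"),
            "B": RosterEntry("staff", "busy"),
            "C": RosterEntry("resident", "quiet"),
        })
        eps = [episode("A", "B")]
        df = strength_duration_summary(build_network(eps, roster), eps, roster)
        quiet = df[df.home == "quiet"].iloc[0]
        assert pd.isna(quiet.weight_median) and pd.isna(quiet.duration_median_min)
        assert set(df.home) == {"busy", "quiet"}


class TestCentralityByRole:
    def test_uniform_degree_collapses_percentiles(self, tiny_roster):
        # square A-B-C-D-A: every wearer degree 2
        eps = [episode(*d) for d in [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")]]
        df = centrality_by_role(build_network(eps, tiny_roster), tiny_roster)
        res = df[(df.role == "resident")].iloc[0]
        assert res.mean_degree == res.degree_p5 == res.degree_p95 == 2

    def test_absent_role_has_zero_row(self):
        roster = Roster({"A": RosterEntry("resident", "h"),
                         "B": RosterEntry("resident", "h")})
        df = centrality_by_role(build_network([], roster), roster)
        staff = df[df.role == "staff"].iloc[0]
        assert staff.n == 0 and pd.isna(staff.mean_degree)

    def test_matches_direct_recomputation(self, cfg, clean_sim):
        config, sightings, _ = clean_sim
        from carecontact import filter_proximate, sessionize

        roster = make_roster(config)
        eps = sessionize(filter_proximate(sightings, cfg), cfg, roster)
        net = build_network(eps, roster)
        df = centrality_by_role(net, roster)
        staff_ids = [d for d in roster.devices() if roster.role(d) == "staff"]
        ks = [net.degree(d) for d in staff_ids]
        row = df[df.role == "staff"].iloc[0]
        assert row.n == len(staff_ids)
        assert row.mean_degree == pytest.approx(np.mean(ks))
        assert row.degree_p95 == pytest.approx(np.quantile(ks, 0.95))


class TestRoleContingency:
    def test_margin_arithmetic_from_count_matrix(self):
        counts = pd.DataFrame(
            [[1, 14, 24], [5, 493, 972], [23, 1061, 2300]],
            index=["agency", "resident", "staff"],
            columns=["agency", "resident", "staff"],
        )
        c = contingency_summary(counts)
        assert c.grand_total == 4893
        assert c.col_totals.tolist() == [29, 1568, 3296]
        assert c.row_totals.tolist() == [39, 1470, 3384]
        assert c.col_pct.tolist() == [0.6, 32.0, 67.4]

    def test_single_staff_staff_episode(self):
        c = role_contingency([episode("A", "B", roles=("staff", "staff"))])
        assert c.grand_total == 1
        assert c.col_pct["staff"] == 100.0

    def test_percentages_sum_to_hundred(self):
        rng = random.Random(1)
        roles = ["agency", "resident", "staff"]
        eps = [
            episode(f"A{i}", f"B{i}",
                    roles=(rng.choice(roles), rng.choice(roles)))
            for i in range(500)
        ]
        c = role_contingency(eps)
        assert c.grand_total == 500
        assert c.col_pct.sum() == pytest.approx(100.0, abs=0.1)

    def test_symmetric_collapse_merges_mirror_cells(self):
        eps = [episode("A", "B", roles=("staff", "resident")),
               episode("C", "D", roles=("resident", "staff"))]
        c = role_contingency(eps, symmetric=True)
        assert c.counts.loc["resident", "staff"] == 2
        assert c.counts.loc["staff", "resident"] == 0

    def test_empty_input_zero_matrix(self):
        c = role_contingency([])
        assert c.grand_total == 0
        assert (c.counts.to_numpy() == 0).all()


class TestUniqueInteractions:
    def test_one_partner_three_episodes(self):
        roster = Roster({"A": RosterEntry("resident", "h"),
                         "B": RosterEntry("staff", "h")})
        eps = [episode("A", "B", start_s=200 * i) for i in range(3)]
        df = unique_interactions(eps, roster)
        res = df[df.role == "resident"].iloc[0]
        assert res.n_individuals == 1
        assert res.mean_unique == 1 and res.mean_total == 3
        assert res.unique_pct_of_total == pytest.approx(33.3)

    def test_no_episodes_all_zero(self, tiny_roster):
        df = unique_interactions([], tiny_roster)
        assert (df.n_individuals == 0).all()
        assert (df.mean_total == 0).all()

    def test_matches_brute_force_sets(self, cfg, clean_sim):
        config, sightings, _ = clean_sim
        from carecontact import filter_proximate, sessionize

        roster = make_roster(config)
        eps = sessionize(filter_proximate(sightings, cfg), cfg, roster)
        df = unique_interactions(eps, roster)
        partners: dict[str, set] = {}
        totals: dict[str, int] = {}
        for e in eps:
            a, b = e.dyad
            partners.setdefault(a, set()).add(b)
            partners.setdefault(b, set()).add(a)
            totals[a] = totals.get(a, 0) + 1
            totals[b] = totals.get(b, 0) + 1
        staff = sorted(p for p in partners if roster.role(p) == "staff")
        row = df[df.role == "staff"].iloc[0]
        assert row.n_individuals == len(staff)
        assert row.mean_unique == pytest.approx(
            np.mean([len(partners[p]) for p in staff])
        )
        assert row.mean_total == pytest.approx(np.mean([totals[p] for p in staff]))


class TestTemporal:
    def test_single_episode_single_cell(self):
        eps = [episode("A", "B", start_s=7200, dur_s=1800)]  # 10:00-10:30
        heat = temporal_heatmap(eps)
        assert heat.loc[10, "res-staff"] == 1
        assert heat.to_numpy().sum() == 1

    def test_episode_spanning_midnight_lands_in_two_days(self):
        start = dt.datetime(2021, 11, 29, 23, 50, tzinfo=dt.timezone.utc)
        ep = InteractionEpisode(
            ("A", "B"), start, start + dt.timedelta(minutes=20),
            n_pings=2, role_pair=("resident", "resident"),
        )
        prof = temporal_profile([ep])
        bins = sorted(prof.bin_start)
        assert [b.day for b in bins] == [29, 30]
        assert [b.hour for b in bins] == [23, 0]

    def test_agency_folds_into_staff(self):
        eps = [episode("A", "B", roles=("agency", "resident"))]
        heat = temporal_heatmap(eps)
        assert heat["res-staff"].sum() == 1

    def test_midday_window_busier_than_early_morning(self):
        """Simulated staff-involving interaction concentrates in the
        boosted 10:00-15:00 window relative to the surrounding shift."""
        cfg_home = HomeConfig(n_residents=10, n_staff=10, n_agency=0,
                              sim_days=6, seed=31, midday_boost=2.5,
                              handover_boost=1.0)
        _, truth = simulate_home(cfg_home)
        tz = cfg_home.tzinfo()
        midday = sum(1 for t in truth.episodes
                     if not t.dyad[0].startswith("R") or not t.dyad[1].startswith("R")
                     if 10 <= t.start.astimezone(tz).hour < 15)
        early = sum(1 for t in truth.episodes
                    if not t.dyad[0].startswith("R") or not t.dyad[1].startswith("R")
                    if 8 <= t.start.astimezone(tz).hour < 10)
        assert midday / 5 > early / 2  # per-hour comparison

    def test_nonpositive_bin_rejected(self):
        with pytest.raises(ValueError):
            temporal_profile([episode("A", "B")], bin_hours=0)


class TestLocationsAndRanking:
    def test_location_counts(self):
        eps = [episode("A", "B", location="lounge"),
               episode("C", "D", location="lounge"),
               episode("A", "C", location="staff-room")]
        assert location_frequency(eps) == {"lounge": 2, "staff-room": 1}

    def test_all_unknown_single_bucket(self):
        eps = [episode("A", "B"), episode("C", "D")]
        assert location_frequency(eps) == {"unknown": 2}

    def test_star_centre_ranks_first(self, tiny_roster):
        eps = [episode("A", x) for x in "BCD"]
        df = connectedness_ranking(build_network(eps, tiny_roster))
        assert df.iloc[0].device_id == "A"
        assert not df.iloc[0].least_connected

    def test_all_isolated_all_flagged(self, tiny_roster):
        df = connectedness_ranking(build_network([], tiny_roster))
        assert df.least_connected.all()

    def test_order_matches_sort_oracle(self, cfg, clean_sim):
        config, sightings, _ = clean_sim
        from carecontact import filter_proximate, sessionize

        roster = make_roster(config)
        eps = sessionize(filter_proximate(sightings, cfg), cfg, roster)
        net = build_network(eps, roster)
        df = connectedness_ranking(net)
        s = dict(net.degree(weight="weight"))
        k = dict(net.degree())
        expected = sorted(net.nodes(), key=lambda v: (-s[v], -k[v], v))
        assert df.device_id.tolist() == expected


@pytest.fixture(scope="module")
def sim_inputs(tmp_path_factory):
    d = tmp_path_factory.mktemp("pipe")
    cfg_home = HomeConfig(n_residents=6, n_staff=8, n_agency=1,
                          sim_days=2, seed=13)
    sightings, truth = simulate_home(cfg_home)
    write_sightings(sightings, d / "sightings.csv")
    write_roster(make_roster(cfg_home), d / "roster.csv")
    return d, cfg_home, truth


class TestPipeline:
    def test_two_runs_byte_identical(self, sim_inputs, tmp_path):
        d, _, _ = sim_inputs
        outs = []
        for name in ("run1", "run2"):
            out = tmp_path / name
            run_pipeline(None, d / "sightings.csv", d / "roster.csv", out)
            outs.append(out)
        files = sorted(p.name for p in outs[0].iterdir())
        assert files
        for name in files:
            assert filecmp.cmp(outs[0] / name, outs[1] / name, shallow=False), name

    def test_counts_are_consistent(self, sim_inputs, tmp_path):
        d, _, _ = sim_inputs
        bundle = run_pipeline(None, d / "sightings.csv", d / "roster.csv",
                              tmp_path / "out")
        assert bundle.manifest["rows_read"] == bundle.n_sightings
        assert bundle.n_filtered <= bundle.n_sightings - bundle.n_rejects
        assert bundle.contingency.grand_total == bundle.n_long_episodes
        assert bundle.n_episodes >= bundle.n_long_episodes

    def test_empty_input_yields_valid_bundle(self, tmp_path, tiny_roster):
        s = tmp_path / "s.csv"
        s.write_text("device_a,device_b,timestamp,rssi\n")
        r = tmp_path / "r.csv"
        write_roster(tiny_roster, r)
        bundle = run_pipeline(None, s, r, tmp_path / "out")
        assert bundle.n_episodes == 0
        assert bundle.contingency.grand_total == 0
        assert bundle.network_stats["n_nodes"] == len(tiny_roster)

    def test_round_trip_reproduces_truth_tables(self, tmp_path):
        """Loss-free, noise-free simulation: pipeline edge weights and
        location counts match the ground truth."""
        from carecontact.config import RssiModel

        cfg_home = HomeConfig(n_residents=6, n_staff=6, n_agency=0,
                              sim_days=2, seed=29, ping_miss_prob=0.0,
                              rssi_model=RssiModel(noise_sd=0.0))
        sightings, truth = simulate_home(cfg_home)
        d = tmp_path
        write_sightings(sightings, d / "s.csv")
        write_roster(make_roster(cfg_home), d / "r.csv")
        bundle = run_pipeline(None, d / "s.csv", d / "r.csv", d / "out")
        assert bundle.n_episodes == len(truth.episodes)
        true_locs: dict[str, int] = {}
        for t in truth.episodes:
            true_locs[t.location] = true_locs.get(t.location, 0) + 1
        # modal attribution can flip when episodes of one device overlap,
        # so location counts agree up to a small fraction of episodes
        labels = set(true_locs) | set(bundle.locations)
        mismatch = sum(
            abs(bundle.locations.get(l, 0) - true_locs.get(l, 0)) for l in labels
        )
        assert mismatch <= max(2, 0.05 * bundle.n_episodes)
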