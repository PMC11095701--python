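# carecontact

Social-network analysis of care-home life from Bluetooth wearable
proximity data.

Care homes are dense social worlds in which the frequency, duration,
timing and location of contact between residents and staff drive both
quality of life and infection risk, yet those contacts are almost
impossible to observe reliably by survey or recall.  BLE wearables solve
the observation problem: each device continuously scans for nearby
devices and static location markers and logs *sightings* — `(device_a,
device_b, timestamp, RSSI)` rows, where RSSI (received signal strength,
dBm) proxies physical distance.  `carecontact` turns such streams into
interpretable quality-improvement analytics, and ships a synthetic
care-home simulator with full ground truth so the entire pipeline can be
developed, validated and demonstrated without any real (and inevitably
sensitive) data.

The pipeline:

1. **ingest** — validate the sighting CSV and the device roster
   (role ∈ {resident, staff, agency}, home, unit); keep dyad sightings
   whose RSSI passes the proximity rule (default: stronger than
   −75 dBm ≈ within arm's reach).
2. **episodes** — sessionize each dyad's pings into *interaction
   episodes*: maximal runs with inter-ping gaps ≤ `max_gap_s` (60 s
   default).  Each episode has a duration, ping count and a modal
   location marker.
3. **network** — aggregate episodes into a weighted undirected contact
   graph: edge weight *w* = episode count, node attributes role/home/
   unit.  Metrics: degree *k*, strength *s* = Σ*w*, harmonic and classic
   closeness, Brandes betweenness, eigenvector centrality, density
   2E/N(N−1), local clustering, Freeman degree centralization, Newman
   role assortativity.
4. **community** — subcommunities by Louvain modularity maximization
   (deterministic, seeded multi-restart with fine-level refinement),
   reporting Q, per-community density and membership.
5. **report** — the QI tables: per-home tie strength and duration
   (median/IQR), centrality by home × role (mean, 5th/95th pct), the
   3×3 role-pair contingency of >2-minute interactions with column
   percentages, unique-vs-total interaction counts per role,
   hour-of-day × relationship heat maps, location frequencies and
   most/least-connected rankings.

## Worked example

Simulate a week in a 52-person home (20 residents, 30 staff, 2 agency
workers; one 08:00–20:00 shift with handover spikes and a busier
10:00–15:00 window; two planted units), then analyse it:

```bash
carecontact simulate --out demo --seed 5 --days 7
carecontact analyze --sightings demo/sightings.csv \
    --roster demo/roster.csv --out demo/report
carecontact report --bundle demo/report
```

prints

```
== Pipeline counts ==
  episodes: 14,461
  long episodes: 86
  sightings proximate: 58,397
  sightings read: 61,423
  sightings rejected: 0
== Long interactions by role pair ==
  agency: 0 (0.0%)
  resident: 18 (20.9%)
  staff: 68 (79.1%)
  grand total: 86
== Network ==
  degree centralization: 0.049
  density: 0.953
  mean clustering: 0.964
  modularity q: 0.244
  n communities: 2
  n edges: 1,264
  n nodes: 52
  role assortativity: -0.047
```

Reading: of 61,423 scan rows, 58,397 passed the proximity filter and
merged into 14,461 contact episodes, of which 86 lasted over two
minutes — and 79.1% of those long contacts involved staff on the
canonical side of the pair, the signature of handovers and paired care.
The week's contact graph is near-saturated (density 0.95: almost
everyone met almost everyone at least once), weakly centralized, and
splits into 2 subcommunities at modularity Q = 0.244 — the two planted
units.  `demo/report/` also contains every table as CSV, the graph as
GraphML/GEXF for Gephi, and a JSON bundle plus run manifest.

The same objects are available as a library:

```python
from carecontact import HomeConfig, simulate_home, run_pipeline
sightings, truth = simulate_home(HomeConfig(seed=5))
```

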