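# Methods

## The data and the measurement model

A BLE wearable deployment produces a stream of *sightings*: one row per
scan event in which device A observed device B (another wearable, or a
static location marker) with a received signal strength (RSSI, dBm).
RSSI is a noisy, monotonically decreasing function of distance; the
package models it with the log-distance path-loss form

    rssi(d) = rssi_at_1m − 10·n·log10(d) + ε,  ε ~ N(0, σ²)

with defaults `rssi_at_1m = −71 dBm`, exponent `n = 2`, `σ = 4 dBm`.
The anchor is deliberately calibrated so that the conventional −75 dBm
proximity threshold corresponds to roughly 1.6 m: sightings of pairs
within the 1.5 m "contact" radius read stronger than −75 dBm, while
markers or bystanders at 3 m and beyond read weaker.  Real hardware
calibrations vary, so both the threshold and the comparator direction
are configurable (`AnalysisConfig.rssi_threshold`, `rssi_keep_rule`);
the mirrored rule exists because field reports of BLE systems sometimes
quote the cut with the opposite sign convention, and the choice is an
empirical calibration question, not one the analysis can settle.

## Sessionization

Per unordered device pair (canonical dyad = lexicographically sorted
IDs — co-presence has no direction), time-sorted proximate pings are
greedily merged while the inter-ping gap is ≤ `max_gap_s`; a strictly
larger gap starts a new episode.  `max_gap_s` defaults to 60 s, one
nominal scan interval: a single missed scan does not split a bout, two
do.  A single isolated ping is an episode of duration zero — the data
contain no evidence of contact beyond the instant — so durations are
`end − start` exactly, and detected durations are grid-quantized (an
episode's last ping falls on the scan grid, so a true 2.3-minute bout
is observed as 2.0 minutes at 60 s cadence).  "Long" interactions are
those strictly over `long_interaction_min` (default 2 minutes).
Episode location is the modal marker among both devices' location pings
within the episode ± one gap, ties to the earliest-seen marker,
`unknown` when there are none.  Modal attribution can misassign an
episode when one device is simultaneously engaged elsewhere; the clean
round-trip test bounds this at under 5% of episodes.

## Networks and metrics

The contact network over a window has one node per rostered person
(isolates kept — a resident with no contacts is a finding, not missing
data) and one edge per dyad with ≥1 overlapping episode; weight w is
the episode count, with total minutes (clipped to the window) and mean
RSSI carried as edge attributes.  Degree is reported raw (contact
partners), strength as Σw; observed populations are 30–110 people, so
raw counts are the interpretable scale.  Shortest-path metrics use
unweighted hops: weight encodes tie strength, not traversal cost.
Closeness defaults to the harmonic form normalized by n−1 (finite on
disconnected graphs, which sparsely present agency staff regularly
create), with the classic (n−1)/Σd form available; betweenness is
unnormalized Brandes with even splitting over tied geodesics;
eigenvector centrality is the L2-normalized principal eigenvector of
the weighted adjacency by power iteration on A + I (tolerance 1e-9; the
shift guarantees convergence on bipartite structures).  Degree
centralization is Freeman's Σ(k_max − k_i)/((N−1)(N−2)); role
assortativity is Newman's categorical coefficient from the role-mixing
matrix, with the all-edges-within-one-role limit defined as 1.
Reciprocity is deliberately not computed: proximity data cannot orient
an edge, and the stub raises rather than returning a vacuous 1.0.

## Community detection

Subcommunities maximize weighted Newman–Girvan modularity

    Q = Σ_c [ w_in(c)/W − γ·(s_c/2W)² ]

via the two-phase greedy local-move/aggregate heuristic, made fully
deterministic: nodes are scanned in sorted-ID order (restarts permute
the order with a seeded generator), the best strictly-improving move
wins with ties to the smallest community id, and iteration stops when
no move gains more than 1e-12.  Two robustness measures are built in,
because plain greedy aggregation demonstrably stalls on small dense
weighted graphs: (a) seeded multi-restart (default 8, best-Q partition
kept), and (b) fine-level refinement — after each aggregation cascade,
local moves are re-run at node granularity starting from the current
partition, because aggregation can freeze a node inside a supernode
even when moving it alone would still raise Q.  With both, the
implementation attains the exhaustive-search optimum on every one of
300 random ≤8-node weighted test graphs; the acceptance suite requires
≥0.97× optimum.  Edgeless graphs partition into singletons with Q = 0
by convention.  Per-community density is the induced-subgraph density,
0 for singletons.

## The synthetic care home

The simulator's defaults describe one mid-sized home: 20 residents, 30
staff, 2 agency workers; five communal locations; one 08:00–20:00
shift; residents active 07:00–22:00.  Contact episodes arise, per dyad,
from a Poisson process with piecewise-constant rate

    λ(t) = rate_matrix[role pair] × boosts(t) × within_unit_bias[same unit]

`rate_matrix` entries are expected episodes per dyad-hour of joint
activity (the generative primitive; per-person rates follow from the
dyad counts).  Boosts: staff–staff rates × `handover_boost` (default 3)
in 30-minute windows at shift start, middle and end; staff-involving
rates × `midday_boost` (default 1.8) over 10:00–15:00.  Dyads sharing a
planted unit multiply by `within_unit_bias` (default 3; recovery tests
use 20), planting recoverable subcommunities.  Agency workers attend
each day with probability 0.3, emulating sparse irregular presence.
Default base rates (0.02–0.08 per dyad-hour) were chosen so a ~50
person week yields tens of thousands of scan rows and a dense contact
graph, the regime wearable deployments report.  Episode durations are
log-normal per role pair; the default medians (0.5–0.8 min, σ = 0.7)
encode the short-contact regime in which the large majority of bouts
are passing encounters and only a few percent exceed two minutes —
published deployments are ambiguous about whether "interactions" counts
raw contacts (implying mostly-short bouts) or merged episodes (whose
medians run 8–13 minutes), and the duration model is exposed precisely
so either regime can be emulated.

Emission: during an episode the pair's separation is drawn once from
U(0.3, 1.5) m; pings fall on a `start + k·ping_interval_s` grid
(inclusive of both endpoints when the duration is a whole number of
intervals), each dropped independently with `ping_miss_prob`; RSSI
follows the path-loss model; both devices also ping the episode's
location marker on the same grid.  Optional decoy pings at 3–10 m
(off by default) exercise the proximity filter.  True episodes of one
dyad closer than one ping interval are merged in the ground truth —
at the scan cadence they are observationally one bout — which makes the
`GroundTruth` an exact oracle for episode counts and network weights
when `ping_miss_prob = 0`.

Timestamps are local clock times at a fixed UTC offset (no
daylight-saving transitions), emitted as ISO-8601 with offset and
normalized to UTC on ingest; shift and boost windows are clock-time
semantics.

What the simulator does **not** emulate: visitor churn, multi-way
(k > 2) gatherings as such (two staff with one resident is two dyads),
spatial trajectories, device failure modes beyond i.i.d. ping loss, and
inter-home heterogeneity (one config = one home).  Passing recovery
tests therefore demonstrates the pipeline's correctness on data with
the study's *structure*, not robustness to every artefact of real
deployments.

## Numerical and reporting conventions

Quantiles use linear interpolation between closest ranks (NumPy
default); IQR = Q3 − Q1 under the same rule.  Percentages print to one
decimal.  Contingency cells count episodes by the roles in canonical
dyad order (a symmetric collapse is available, since the ordered
asymmetry is an artefact of ID ordering).  Agency folds into staff only
in the three-category temporal views; everywhere else it is a separate
role.  Table populations (e.g. individuals per role) are computed from
the data, not roster headcounts.  The temporal profile counts an
episode in every bin it overlaps (half-open bins aligned to local
midnight).  The full pipeline is deterministic: identical inputs and
config produce byte-identical artefacts, guarded by a file-compare
test.

## Problem sizes in the test and acceptance suites

Oracle-equivalence checks run brute-force enumeration on ≥200 random
≤7-node graphs (path metrics) and 50 random ≤8-node graphs (exhaustive
modularity over all set partitions); sessionization is checked against
a pairwise gap-scan oracle on 500 random fixtures.  Recovery runs a
40-person, two-unit, 14-day loss-free simulation (bias 20, base rates
0.005/dyad-hour — low enough that truth-merging is negligible and the
Poisson 3-SE calibration check is exact) and requires adjusted Rand
index ≥ 0.9 for the planted units; in practice recovery is exact
(ARI = 1.0).  These sizes make the whole suite run in well under a
minute while every check remains a genuine computation.
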