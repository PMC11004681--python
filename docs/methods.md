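# Methods

This note documents the models, conventions and numerical choices behind
`mantanet`, in the order the pipeline runs.

## Residence events and movements

A residence event for one transmitter opens at a detection at a station and
is extended by each further detection at the *same* station separated by at
most `timeout_min` (default 60) minutes. It closes when the animal is
detected at a different station or when the silence exceeds the timeout;
the event's end is the last included detection. `min_detections` defaults
to 1: a single detection is a valid residence event.

Boundary semantics the upstream tools leave unstated, fixed here and
configurable:

* a gap of **exactly** the timeout continues the event (termination needs a
  strictly greater gap);
* a detection **exactly at** the tag's deployment time survives the
  pre-tagging filter (closed lower bound); an optional handling buffer
  (default 0 min) drops the first minutes after deployment;
* detections of one transmitter with identical timestamps at two stations
  (possible with overlapping detection ranges) are ordered by station id for
  determinism and flagged with a warning.

A movement is the transition between two *consecutive* residence events of
one transmitter at *distinct* stations; re-detection at the same station
after a long silence is not a movement. Movement duration may be zero if
the timestamps collapse; that is allowed. The "direct distance" of a
movement is the great-circle (haversine, R = 6371 km) distance between the
two stations, i.e. a lower bound on the path actually swum.

Both filters are idempotent, only remove rows, and preserve per-transmitter
time order; this is property-tested.

## Networks and metrics

Movement networks are simple directed graphs over the **full** station
table; stations without movements stay in the node set. Edge count is the
number of movements on that ordered pair; edge weight is the count divided
by the network's total movements. Tagging-region networks take the
movements of animals *tagged* in one region over the same full node set, so
edge densities share the denominator n·(n−1) — the convention the published
metrics table is arithmetically consistent with (e.g. 74/(34·33) = 0.066).

Path metrics are hop counts on the unweighted digraph. Average path length
is the mean over **reachable** ordered pairs only, the diameter the maximum
finite distance; unreachable pairs are excluded rather than treated as
infinite (forced by the published table's two-connected-node column having
APL = diameter = 1). On an edgeless network both are undefined and reported
as NaN/null, never 0. Shortest paths are computed by a level-synchronous
matrix BFS and cross-checked in tests against Floyd–Warshall and networkx.

Centralities: in/out/total degree count distinct neighbours (multiplicity
does not inflate degree); betweenness is the unnormalised directed
shortest-path count through a node with even splitting over equal-length
paths (networkx, verified against exhaustive path enumeration); closeness
is the inverse mean hop distance to a node's reachable set, 0 for nodes
that reach nothing; eigenvector centrality is the leading eigenvector of
the symmetrised movement-count matrix, scaled to maximum 1 — the directed
version is ill-defined for nodes without in-edges and is available as an
option. On disconnected graphs the leading eigenvector concentrates on the
dominant component and other components score ≈ 0; that is the documented
behaviour, not an error.

## Permutation null

The non-randomness test asks whether the observed APL is longer than
expected under random networks with exactly the observed in- and out-degree
sequences. The default generator is a Markov chain started at the observed
network with two symmetric move types: directed double-edge swaps
((a,b),(c,d) → (a,d),(c,b)) and reversals of induced directed 3-cycles.
Both rejections (self-loop or duplicate proposals) count as lazy steps and
the chain runs a fixed `attempts_per_edge × n_edges` proposals (default
40). Two details matter and were verified against exhaustive enumeration of
a small degree sequence:

* pairwise swaps alone do **not** connect the space of simple digraphs with
  fixed degrees (a 4-node, 5-edge sequence has 6 realisations of which
  swaps reach 3); the 3-cycle reversals restore ergodicity;
* stopping after a fixed number of *accepted* moves is periodic — the
  accepted-move graph can be bipartite, and an even stop count then never
  lands on half the realisations. Counting attempts (rejections as lazy
  self-steps) makes the chain aperiodic with uniform stationary law; both
  generators pass a chi-square uniformity test against enumeration.

The alternative generator is stub matching (shuffle edge heads, reject
draws with self-loops or duplicates — trivially uniform), with an
`allow_multi` variant that accepts parallel edges and collapses them before
computing APL, mimicking the permissive configuration-model generators
common in R workflows. Degree sequences with no simple realisation raise
after a bounded number of retries.

The p-value is the add-one estimator
`p = (1 + #{null APL ≥ observed}) / (1 + n_iter)` (never exactly 0), upper
tailed because structure implies a longer APL. Default `n_iter` is 10 000;
tests and the acceptance script use 500–2000, which is ample for p-values
down to ~10⁻³. Type-I error is verified by simulation: on observed networks
drawn from the null itself the test rejects at the nominal 5% rate (400
replicates, acceptance band 2–8%).

A genuine limitation, found while validating: when planted clusters are
almost disconnected in the *directed* sense, the reachable-pairs APL
excludes exactly the long cross-cluster paths that signal structure, and
the test loses power (it can even invert). The APL test detects modular
structure reliably only when clusters are at least weakly interconnected;
the synthetic acceptance study therefore uses a between-region movement
probability of 0.01, at which the clusters stay connected.

## Community detection

Subpopulation structure is the maximum-modularity partition of the
symmetrised graph (directed movement counts summed over both directions;
using a single direction is exposed as an option). Weighted Newman–Girvan
modularity is

    Q = Σ_c [ w_c/W − (s_c/2W)² ]

with W the total symmetrised weight, w_c the intra-community weight and
s_c the community strength; Q is invariant under uniform weight scaling
(tested) and is checked against a direct double-sum oracle. Stations with
no movements are removed before clustering and reported by name — they
carry no information about mixing (the original analysis likewise dropped
its two unconnected receivers, leaving 32 of 34 nodes).

Up to `exact_max_nodes` (default 40) nodes the partition is found by
igraph's exact integer-programming modularity maximiser — receiver arrays
of a few dozen stations solve in well under a second, so the fallback to
multi-restart Louvain plus single-node refinement is triggered by size or
solver failure rather than a wall clock. On every graph of ≤ 8 nodes tried,
the exact route attains the brute-force maximum over all set partitions.
Q ≥ 0.3 is flagged as a "good division" following common practice.

## Sex comparisons

Per moving animal the pipeline tabulates total movements and the mean
(optionally sum) of its movements' direct distances. Two sexes are compared
with Shapiro–Wilk per group (skipped for constant samples), a two-sided
variance-ratio F-test (R `var.test` semantics), and an unpaired two-sample
t-test — pooled when the F-test p ≥ 0.05, Welch otherwise; both variants
are always reported. Groups under 3 animals skip testing with an
explanation. Conclusions use graded evidence wording ("no evidence" …
"very strong evidence") instead of a significance label. Because tagging
effort is rarely sex-balanced everywhere, a cohort filter restricts the
comparison (e.g. to one tagging region or station); the analysis driver
picks the region with the most balanced sexes among moving animals.

## Synthetic study generator

The generator emulates the study *design*, not manta ethology. Defaults:
34 stations in 7 regions at approximately the real island-group centroids
(stations jittered ~2 km), 117 animals released in 5 phases, pings at
i.i.d. uniform 60–130 s gaps, per-ping Bernoulli detection (default 0.3 —
per-station detection efficiency is a free parameter, as no field value is
established), 120 simulated days as the desk-scale stand-in for the
multi-year deployment.

Movement is a two-level Markov chain per animal: at the end of each
exponential station visit (mean 120 min, truncated at 1 min) the animal
moves between regions with probability 0.03, within its region with
probability 0.37, or leaves the array and later returns to the same station
(exponential absence, mean 2 days). The 0.03/0.37 split plants ~7.5%
between-region movements, matching the mixing level the field study
observed. Travel time is great-circle distance at 1 m s⁻¹, so a
transmitter is never at two stations at once and timestamps strictly
increase. All randomness flows from one seed via independent per-stage
streams; every output is byte-reproducible from (config, seed).

The first ping of each visit is emitted at arrival. This deliberate choice
guarantees at least one detection per visit at detection probability 1,
which makes the ground-truth recovery invariant *exact*: running the full
pipeline on a perfect-detection log reproduces the simulated movement list
movement-for-movement (tested, and reported by the acceptance script as a
recovery percentage). With gap-delayed first pings, minute-long visits
could silently vanish and the invariant would only hold in expectation.

What the generator does **not** model — and what passing tests therefore do
not show about field data: tag shedding and battery failure, emigration
from the array (so synthetic detection rates exceed the ~80% observed in
the field), detection-range variation with sea state, tides or biofouling,
receiver outages, behavioural heterogeneity between individuals, and any
attraction dynamics at cleaning stations. Tests on synthetic data validate
the *pipeline's correctness*, not the ecological fidelity of its inputs.

## Problem sizes

The test suite and acceptance script run everything at reduced scale chosen
for a laptop-class machine: 3-region (12-station, 30-animal, 8-day)
studies for structure recovery, 500–2000 permutation iterations, 400
type-I replicates on a 10-node null network, exhaustive oracles up to 8–12
nodes. These sizes are the package's own validation design; the library
defaults (full 34-station array, 10 000 iterations) match the study scale.
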