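# mantanet

Movement-network analysis for passive acoustic telemetry, built around the
question that matters for a suspected metapopulation: do tagged animals move
freely across a monitored seascape, or do they form geographically discrete
subpopulations with little mixing between them?

The motivating system is the reef manta ray (*Mobula alfredi*) in the Raja
Ampat archipelago: a 34-receiver array across seven island groups, 117
acoustically tagged animals, and the working hypothesis that the archipelago
hosts several demographically distinct subpopulations rather than one
homogeneous population. The package is general to any VUE-style detection
log plus tag and station metadata.

## What it computes

Starting from a timestamped detection log (transmitter ID heard at a
receiver station), the pipeline:

1. **filters** false positives — only deployed transmitters, no detections
   earlier than a tag's deployment;
2. **extracts residence events** — maximal runs of detections of one animal
   at one station, terminated by detection at another station or by more
   than 60 min of silence — and keeps the transitions between *distinct*
   stations as **movements**;
3. **builds directed weighted movement networks** (stations are nodes, a
   movement u→v is an edge instance; edge weight is the proportion of all
   movements) — one archipelago-wide network and one per tagging region —
   and computes eight network-level metrics (node counts, edge count,
   movement count, edge density m/(n(n−1)), average path length, diameter)
   plus six node centralities (in-, out-, total degree, betweenness,
   closeness, eigenvector);
4. **tests for non-random structure**: the observed average path length
   (APL) is compared with APLs of degree-preserving random rewirings; a
   structured network concentrates movement locally and has a longer APL,
   so the one-tailed permutation p-value is
   `p = (1 + #{null APL ≥ observed}) / (1 + n_iter)`;
5. **detects subpopulations** as the maximum-modularity partition of the
   symmetrised, movement-count-weighted network (exact integer-programming
   solver up to 40 nodes; Q ≥ 0.3 is read as a good division), after
   removing unconnected stations;
6. **compares the sexes** on per-animal movement totals and mean direct
   (great-circle) distances: Shapiro–Wilk per group, variance-ratio F-test,
   then a pooled or Welch two-sample t-test, reported with graded evidence
   language rather than a significance dichotomy.

A synthetic study generator (`mantanet.simulate`) emulates the full design —
34 stations in 7 regions, 117 tags in 5 release phases, pings every 60–130 s,
per-ping Bernoulli detection, two-level Markov movement with planted
subpopulation structure — and exposes the ground truth (every true movement,
the planted station→region membership), so every pipeline stage is testable
against a known answer.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write their tables under `results/`:

```bash
python analysis/01_simulate_study.py
python analysis/02_extract_events.py
python analysis/03_build_networks.py
python analysis/04_permutation_null.py
python analysis/05_detect_communities.py
python analysis/06_sex_comparison.py
```

Output of the first runs (seed 1):

```
array          : 34 stations, 7 regions
tags deployed  : 117 in 5 phases over 120 days
detections     : 166218 (117/117 tags detected, 100%)
true movements : 2777
...
movements      : 2736 between distinct stations
moving animals : 117 (mean 23.4 movements, sd 9.9; mean leg 14.0 km)
...
global network : 34/34 connected nodes, 384 edges, 2736 movements
               : density 0.342, APL 1.68, diameter 3
...
observed APL   : 1.679
null APL       : 1.667 (sd 0.003, 2000 rewirings)
one-tailed p   : 0.0004998 (observed APL longer than the degree-preserving null)
...
modularity     : Q = 0.736 (exact; good division (Q >= 0.3))
communities    : 6; agreement with planted regions ARI = 0.94
```

Reading this: the simulated animals move overwhelmingly within their home
region, so the movement network is far from its degree-preserving null
(p ≈ 5·10⁻⁴) and the exact modularity maximiser recovers region-like
clusters (Q = 0.74; adjusted Rand index 0.94 against the planted
membership — two small adjacent regions merge, which is exactly the kind
of outcome the field study reported when central regions fused into one
cluster). The sex comparison on this synthetic cohort finds, correctly, no
evidence of a difference (the generator plants none).

The same pipeline is exposed as a CLI (`mantanet simulate`, `mantanet
events`, `mantanet analyze --config cfg.yaml`, `mantanet permute`,
`mantanet communities`) and as a library (`mantanet.pipeline.run_pipeline`);
identical configuration and seed reproduce byte-identical outputs.

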