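"""End-to-end orchestration: data (simulated or read) → events → networks →
permutation null → communities → sex comparison, with a reproducible report.

Every stage writes its machine-readable outputs under the configured output
directory; the consolidated ``report.json`` embeds the package version, the
full configuration, the seed and SHA-256 hashes of the outputs, so two runs
with the same configuration and seed produce byte-identical trees.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import community as community_mod
from . import events as events_mod
from . import groupstats, ingest, netbuild, randomnull
from .simulate import SimConfig, simulate_study

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Everything one analysis run depends on."""

    outdir: str = "mantanet_out"
    # either simulate ...
    simulate: Optional[SimConfig] = None
    # ... or read input files
    detections_path: Optional[str] = None
    deployments_path: Optional[str] = None
    stations_path: Optional[str] = None
    input_tz: str = "UTC"
    # event extraction
    timeout_min: float = 60.0
    min_detections: int = 1
    handling_buffer_min: float = 0.0
    # permutation null
    n_iter: int = 10000
    null_method: str = "edge_swap"
    allow_multi: bool = False
    # community detection
    community_method: str = "exact_if_small"
    # sex comparison
    distance_stat: str = "mean"
    sex_cohort_filter: Optional[dict] = None
    # regions for per-tagging-region networks (None = all observed)
    regions: Optional[Sequence[str]] = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        return d


def load_config(path) -> PipelineConfig:
    """Load a pipeline configuration from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulate", None)
    cfg = PipelineConfig(**raw)
    if sim is not None:
        for key in ("region_coords", "deployment_phases", "ping_interval_range"):
            if key in sim and sim[key] is not None:
                sim[key] = [tuple(x) for x in sim[key]] \
                    if key != "ping_interval_range" else tuple(sim[key])
        cfg.simulate = SimConfig(**sim)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, meta: dict) -> None:
    header = "# mantanet " + json.dumps(meta, sort_keys=True, default=str)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return None if np.isnan(o) else float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               default=_json_default) + "\n")


def _nan_to_none(d: dict) -> dict:
    return {k: (None if isinstance(v, float) and np.isnan(v) else v)
            for k, v in d.items()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and return the consolidated report dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = dict(version=__version__, seed=config.seed)
    report: dict = dict(version=__version__, config=config.to_dict(), stages={})

    # ------------------------------------------------------------------ data
    if config.simulate is not None:
        simcfg = config.simulate
        stations, traj, truth, det_log = simulate_study(simcfg)
        _write_csv(stations, out / "stations.csv", meta)
        _write_csv(traj.deployments, out / "deployments.csv", meta)
        _write_csv(det_log.drop(columns=["station_id"]),
                   out / "detections.csv", meta)
        _write_csv(truth.true_movements, out / "true_movements.csv", meta)
        _write_csv(pd.DataFrame(
            sorted(truth.planted_membership.items()),
            columns=["station_id", "region"]),
            out / "planted_membership.csv", meta)
        detections = det_log.rename(columns={"datetime_utc": "timestamp"})[
            ["transmitter_id", "station_id", "timestamp"]]
        deployments = traj.deployments
        report["stages"]["simulate"] = dict(
            n_stations=len(stations), n_animals=len(deployments),
            n_detections=len(detections),
            n_true_movements=len(truth.true_movements))
    else:
        if not (config.detections_path and config.deployments_path
                and config.stations_path):
            raise ValueError("either a simulate block or all three input "
                             "paths (detections, deployments, stations) "
                             "must be configured")
        stations = ingest.read_stations(config.stations_path)
        deployments = ingest.read_deployments(config.deployments_path,
                                              tz=config.input_tz)
        detections = ingest.read_detections(config.detections_path,
                                            stations=stations,
                                            tz=config.input_tz)
        report["stages"]["read"] = dict(
            n_stations=len(stations), n_deployments=len(deployments),
            n_detections=len(detections),
            n_malformed=detections.attrs.get("n_malformed", 0))

    # ---------------------------------------------------------------- filter
    n0 = len(detections)
    detections = ingest.filter_active(detections, deployments)
    n_inactive = detections.attrs.get("n_removed_inactive", 0)
    detections = ingest.filter_pre_tagging(detections, deployments,
                                           buffer_min=config.handling_buffer_min)
    n_pre = detections.attrs.get("n_removed_pre_tagging", 0)
    filter_report = dict(n_input=n0, n_removed_inactive=n_inactive,
                         n_removed_pre_tagging=n_pre, n_kept=len(detections))
    _write_json(filter_report, out / "filter_report.json")
    report["stages"]["filter"] = filter_report

    # ---------------------------------------------------------------- events
    events = events_mod.extract_residence_events(
        detections, timeout_min=config.timeout_min,
        min_detections=config.min_detections)
    movements = events_mod.extract_movements(events)
    movements = events_mod.movement_distances(movements, stations)
    _write_csv(events, out / "residence_events.csv",
               {**meta, "timeout_min": config.timeout_min,
                "min_detections": config.min_detections})
    _write_csv(movements, out / "movements.csv", meta)
    per_ind = events_mod.per_individual_summary(
        movements, deployments, distance_stat=config.distance_stat)
    _write_csv(per_ind, out / "per_individual.csv", meta)
    report["stages"]["events"] = dict(
        n_events=len(events), n_movements=len(movements),
        n_moving_animals=len(per_ind))

    # -------------------------------------------------------------- networks
    net = netbuild.build_network(movements, stations)
    _write_csv(net.edge_counts(), out / "edges.csv", meta)
    try:
        import networkx as nx
        nx.write_graphml(net.graph, out / "network.graphml")
    except Exception as exc:  # pragma: no cover - export is best-effort
        logger.warning("GraphML export failed: %s", exc)

    regions = (list(config.regions) if config.regions
               else sorted(deployments["tagging_region"].unique()))
    region_nodes = stations.groupby("region")["station_id"].size().to_dict()
    metric_rows = []
    gm = netbuild.network_metrics(net, tagging_region_nodes=None)
    metric_rows.append(dict(network="all", **gm.to_dict()))
    for region in regions:
        sub = netbuild.subnetwork_by_tagging_region(
            movements, deployments, region, stations)
        sm = netbuild.network_metrics(
            sub, tagging_region_nodes=region_nodes.get(region))
        metric_rows.append(dict(network=region, **sm.to_dict()))
    metrics_df = pd.DataFrame(metric_rows)
    _write_csv(metrics_df, out / "network_metrics.csv", meta)
    cent = netbuild.node_centralities(net)
    _write_csv(cent, out / "centralities.csv", meta)
    report["stages"]["network"] = dict(
        global_metrics=_nan_to_none(gm.to_dict()),
        per_region={r["network"]: _nan_to_none(
            {k: v for k, v in r.items() if k != "network"})
            for r in metric_rows[1:]})

    # ------------------------------------------------------ permutation null
    if net.n_edges > 0 and np.isfinite(gm.apl):
        perm = randomnull.apl_permutation_test(
            net, n_iter=config.n_iter, seed=config.seed,
            method=config.null_method, allow_multi=config.allow_multi)
        _write_json(perm.to_dict(), out / "permutation_result.json")
        _write_csv(pd.DataFrame({"null_apl": perm.null_apls}),
                   out / "null_apls.csv", meta)
        _plot_null(perm, out / "null_apl_histogram.png")
        report["stages"]["permutation"] = perm.to_dict()
    else:
        report["stages"]["permutation"] = dict(skipped="network has no paths")

    # ------------------------------------------------------------ community
    if net.n_edges > 0:
        part = community_mod.detect_communities(
            net, method=config.community_method, seed=config.seed)
        _write_csv(pd.DataFrame(
            sorted(part.membership.items()),
            columns=["station_id", "community"]),
            out / "communities.csv", meta)
        _write_json(part.to_dict(), out / "community_summary.json")
        report["stages"]["community"] = part.to_dict()
    else:
        report["stages"]["community"] = dict(skipped="edgeless network")

    # ------------------------------------------------------- sex comparison
    sex_results = {}
    for metric in ("total_movements", "mean_distance_km"):
        cmp = groupstats.compare_sexes(
            per_ind, metric=metric, cohort_filter=config.sex_cohort_filter)
        sex_results[metric] = cmp.to_dict()
    _write_json(sex_results, out / "sex_comparison.json")
    report["stages"]["sexbias"] = {m: r["conclusion"]
                                   for m, r in sex_results.items()}

    # ----------------------------------------------------------- provenance
    hashes = {p.name: _sha256(p) for p in sorted(out.iterdir())
              if p.suffix in (".csv", ".json", ".graphml")
              and p.name != "report.json"}
    report["output_hashes"] = hashes
    cfg_for_hash = config.to_dict()
    cfg_for_hash.pop("outdir", None)  # identical analyses hash equal
    report["config_hash"] = hashlib.sha256(
        json.dumps(cfg_for_hash, sort_keys=True, default=str).encode()
    ).hexdigest()
    _write_json(report, out / "report.json")
    return report


def _plot_null(perm, path: Path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # pragma: no cover
        return
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(perm.null_apls, bins=40, color="steelblue", alpha=0.8,
            label="null APL")
    ax.axvline(perm.observed_apl, color="crimson", lw=2,
               label=f"observed = {perm.observed_apl:.3f}")
    ax.set_xlabel("average path length")
    ax.set_ylabel("permutations")
    ax.legend(frameon=False, fontsize=8)
    ax.set_title(f"one-tailed p = {perm.p_value:.4f}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
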