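"""End-to-end paired-condition analysis and study-level aggregation.

``run_pipeline`` executes, per slice and condition, the activity statistics,
cross-correlogram connectivity, graph/centrality metrics, small-world indices
and Estrada-index classification, then compares every paired endpoint across
slices (slice = statistical unit for network endpoints).  Reports are plain
nested dicts, deterministic given the seed, serializable to JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import activity, connectivity, estrada, graph_metrics, smallworld
from .spike_io import SpikeTrainSet, bin_raster, read_spike_trains
from .synthetic import ConditionEffect, PopulationConfig, simulate_slice

#: endpoints compared pairwise across slices (dotted paths into the
#: per-condition summaries)
PAIRED_ENDPOINTS = [
    "mean_rate_hz",
    "burst.count_per_minute",
    "burst.mean_height",
    "links.n_pos", "links.n_neg", "links.sum_pos", "links.sum_neg",
    "graph.average_degree", "graph.density", "graph.components",
    "graph.path_length", "graph.clustering",
    "graph.mean_betweenness", "graph.mean_closeness",
    "graph.mean_eigenvector", "graph.mean_eccentricity",
    "graph.mean_freq_1_6", "graph.mean_freq_ge7",
    "smallworld.sigma", "smallworld.omega",
    "estrada.pct_I", "estrada.pct_II", "estrada.pct_III",
]


@dataclass
class PipelineParams:
    bin_ms: float = 1.0
    burst_bin_ms: float = 500.0
    burst_k_sd: float = 5.0
    k_sd: float = 5.0
    rel_tol: float = 0.01
    n_nulls: int = 100
    threshold_mode: str = "sd"
    min_fraction: float = 0.05
    seed: int = 0


def _condition_summary(sts: SpikeTrainSet, params: PipelineParams,
                       seed: int) -> dict[str, Any]:
    """Full single-condition analysis of one slice."""
    rates = activity.unit_rates(sts)
    raster = bin_raster(sts, bin_ms=params.bin_ms)
    burst = activity.detect_bursts(raster, bin_ms=params.burst_bin_ms,
                                   k_sd=params.burst_k_sd)
    conn = connectivity.connectivity_from_spikes(sts, k_sd=params.k_sd)
    G = graph_metrics.Graph.from_connectivity(conn, sign="pos")
    nodes = graph_metrics.node_metrics(G)
    net = graph_metrics.network_metrics(G)
    if G.m >= 1:
        sw = smallworld.small_world_indices(G, n_nulls=params.n_nulls, seed=seed)
        sw_out = {"sigma": sw.sigma, "omega": sw.omega, "C": sw.C, "L": sw.L,
                  "C_rand": sw.C_rand, "L_rand": sw.L_rand, "C_latt": sw.C_latt}
    else:
        sw_out = {"sigma": None, "omega": None, "C": 0.0, "L": None,
                  "C_rand": None, "L_rand": None, "C_latt": None}
    try:
        spec = estrada.classify(conn.W_pos, threshold_mode=params.threshold_mode,
                                node_ids=conn.unit_ids,
                                min_fraction=params.min_fraction)
        est_out = {"estrada_index": spec.estrada_index,
                   "pct_I": spec.percentages.get("I", 0.0),
                   "pct_II": spec.percentages.get("II", 0.0),
                   "pct_III": spec.percentages.get("III", 0.0),
                   "network_class": spec.network_class,
                   "ratio_II_III": spec.ratio_II_III,
                   "tau": spec.tau}
    except ValueError as exc:
        est_out = {"estrada_index": None, "pct_I": None, "pct_II": None,
                   "pct_III": None, "network_class": None,
                   "ratio_II_III": None, "tau": None, "error": str(exc)}
    dd = net["degree_distribution"]
    return {
        "n_units": sts.n_units,
        "mean_rate_hz": float(rates.mean()),
        "rates": {k: float(v) for k, v in rates.items()},
        "burst": {"count": burst.count,
                  "count_per_minute": burst.count_per_minute(sts.duration_ms),
                  "mean_height": burst.mean_height,
                  "noise_rms": burst.noise_rms},
        "links": {"n_pos": conn.n_pos_links, "n_neg": conn.n_neg_links,
                  "sum_pos": conn.sum_pos_weights,
                  "sum_neg": conn.sum_neg_weights},
        "graph": {"average_degree": net["average_degree"],
                  "density": net["density"],
                  "components": net["components"],
                  "path_length": net["path_length"],
                  "clustering": net["clustering"],
                  "mean_betweenness": float(nodes["betweenness"].mean()) if len(nodes) else 0.0,
                  "mean_closeness": float(nodes["closeness"].mean()) if len(nodes) else 0.0,
                  "mean_eigenvector": float(nodes["eigenvector"].mean()) if len(nodes) else 0.0,
                  "mean_eccentricity": float(nodes["eccentricity"].mean()) if len(nodes) else 0.0,
                  "mean_freq_1_6": dd["mean_freq_1_6"],
                  "mean_freq_ge7": dd["mean_freq_ge7"],
                  "max_degree": dd["max_degree"],
                  "degrees": nodes["degree"].tolist() if len(nodes) else []},
        "smallworld": sw_out,
        "estrada": est_out,
        "_conn": conn,  # stripped before serialization
    }


def analyze_slice(base: SpikeTrainSet, treated: SpikeTrainSet,
                  params: PipelineParams, seed: int) -> dict[str, Any]:
    """Analyze one slice in both conditions plus the paired deltas."""
    out: dict[str, Any] = {"slice_id": base.slice_id}
    out["baseline"] = _condition_summary(base, params, seed=seed)
    out["treated"] = _condition_summary(treated, params, seed=seed + 1)
    directions, props = activity.classify_rate_change(
        activity.unit_rates(base), activity.unit_rates(treated),
        rel_tol=params.rel_tol)
    out["rate_change"] = {"proportions": {k: float(v) for k, v in props.items()},
                          "directions": {k: str(v) for k, v in directions.items()}}
    out["delta_correlation"] = connectivity.compare_connectivity(
        out["baseline"].pop("_conn"), out["treated"].pop("_conn"))
    return out


def _lookup(d: dict, dotted: str):
    cur: Any = d
    for part in dotted.split("."):
        if cur is None:
            return None
        cur = cur.get(part)
    return cur


def paired_endpoint_tests(slice_reports: list[dict]) -> dict[str, Any]:
    """Paired comparison of every endpoint across slices (slice = unit)."""
    out: dict[str, Any] = {}
    for ep in PAIRED_ENDPOINTS:
        a = [_lookup(r["baseline"], ep) for r in slice_reports]
        b = [_lookup(r["treated"], ep) for r in slice_reports]
        pairs = [(x, y) for x, y in zip(a, b) if x is not None and y is not None]
        if len(pairs) < 3:
            out[ep] = {"test": "insufficient_n", "p": None, "n": len(pairs)}
            continue
        va = np.array([p[0] for p in pairs], float)
        vb = np.array([p[1] for p in pairs], float)
        cmp = activity.paired_compare(va, vb)
        out[ep] = {"test": cmp.test, "statistic": cmp.statistic, "p": cmp.p,
                   "n": cmp.n, "mean_baseline": cmp.mean_a,
                   "mean_treated": cmp.mean_b}
    # Fisher's exact test on class-IV network counts per condition
    iv_base = sum(r["baseline"]["estrada"].get("network_class") == "IV"
                  for r in slice_reports)
    iv_treat = sum(r["treated"]["estrada"].get("network_class") == "IV"
                   for r in slice_reports)
    n = len(slice_reports)
    table = [[iv_base, n - iv_base], [iv_treat, n - iv_treat]]
    odds, p = sstats.fisher_exact(table)
    out["network_class_IV"] = {"test": "fisher_exact", "table": table,
                               "statistic": float(odds), "p": float(p)}
    # KS on pooled degree distributions
    deg_a = np.concatenate([r["baseline"]["graph"]["degrees"]
                            for r in slice_reports]) if n else np.array([])
    deg_b = np.concatenate([r["treated"]["graph"]["degrees"]
                            for r in slice_reports]) if n else np.array([])
    if deg_a.size and deg_b.size:
        out["degree_distribution"] = activity.ks_compare(deg_a, deg_b)
    return out


def run_pipeline(config: dict, seed: int = 0) -> dict[str, Any]:
    """Run the full paired-condition study described by ``config``.

    ``config`` either simulates (``{"simulate": {"n_slices": 5, ...}}``) or
    names per-slice spike tables
    (``{"slices": [{"slice_id", "baseline", "treated"}, ...]}``).
    Deterministic given ``seed`` — two runs produce byte-identical reports.
    """
    params = PipelineParams(**config.get("params", {}), seed=seed) \
        if "params" in config else PipelineParams(seed=seed)
    slice_reports: list[dict] = []
    errors: list[dict] = []
    if "simulate" in config:
        sim = dict(config["simulate"])
        n_slices = int(sim.pop("n_slices", 5))
        pop_kwargs = sim.pop("population", {})
        eff_kwargs = sim.pop("effect", None)
        ss = np.random.SeedSequence(seed)
        child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                       for s in ss.spawn(n_slices)]
        for k in range(n_slices):
            cfg = PopulationConfig(**pop_kwargs) if pop_kwargs else None
            eff = ConditionEffect(**eff_kwargs) if eff_kwargs is not None else None
            base, treated, _gb, _gt = simulate_slice(
                child_seeds[k], slice_id=f"slice{k:02d}", config=cfg, effect=eff)
            slice_reports.append(analyze_slice(base, treated, params,
                                               seed=child_seeds[k]))
    else:
        for entry in config.get("slices", []):
            try:
                base = read_spike_trains(entry["baseline"])
                treated = read_spike_trains(entry["treated"])
            except (KeyError, FileNotFoundError, ValueError) as exc:
                errors.append({"slice_id": entry.get("slice_id", "?"),
                               "error": str(exc)})
                continue
            slice_reports.append(analyze_slice(base, treated, params,
                                               seed=seed))
    report = {
        "provenance": {
            "seed": seed,
            "config_hash": hashlib.sha256(
                json.dumps(config, sort_keys=True, default=str).encode()
            ).hexdigest()[:16],
            "params": asdict(params),
        },
        "n_slices": len(slice_reports),
        "slices": slice_reports,
        "errors": errors,
    }
    if len(slice_reports) >= 3:
        report["paired_tests"] = paired_endpoint_tests(slice_reports)
    return report


def summarize(report: dict) -> pd.DataFrame:
    """Study-level endpoint table: mean +/- SEM (parametric endpoints) or
    median +/- IQR (non-parametric, i.e. when the paired test fell back to
    Wilcoxon), per condition."""
    rows = []
    slices = report["slices"]
    tests = report.get("paired_tests", {})
    if not slices:
        raise ValueError("report contains no slices")
    for ep in PAIRED_ENDPOINTS:
        a = np.array([x for x in (_lookup(r["baseline"], ep) for r in slices)
                      if x is not None], float)
        b = np.array([x for x in (_lookup(r["treated"], ep) for r in slices)
                      if x is not None], float)
        if not a.size or not b.size:
            continue
        chosen = tests.get(ep, {}).get("test", "paired_t")
        if chosen == "wilcoxon":
            rows.append({"endpoint": ep, "summary": "median±IQR",
                         "baseline": float(np.median(a)),
                         "baseline_spread": float(np.subtract(*np.percentile(a, [75, 25]))),
                         "treated": float(np.median(b)),
                         "treated_spread": float(np.subtract(*np.percentile(b, [75, 25]))),
                         "test": chosen, "p": tests.get(ep, {}).get("p")})
        else:
            sem_a = float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else 0.0
            sem_b = float(b.std(ddof=1) / np.sqrt(b.size)) if b.size > 1 else 0.0
            rows.append({"endpoint": ep, "summary": "mean±SEM",
                         "baseline": float(a.mean()), "baseline_spread": sem_a,
                         "treated": float(b.mean()), "treated_spread": sem_b,
                         "test": chosen, "p": tests.get(ep, {}).get("p")})
    return pd.DataFrame(rows).set_index("endpoint")


def report_to_json(report: dict, path=None, **kwargs) -> str:
    """Serialize a report deterministically (drops bulky raster fields)."""
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")
    text = json.dumps(report, indent=2, default=default, **kwargs)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
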