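"""End-to-end orchestration: config, staging, structured outputs.

Two pipelines mirror the two analysis arms:

* :func:`run_network_pipeline` — trajectory in, residue communication
  network out: feature extraction, contact map, normalized mutual
  information, -log weights with block-wise uncertainties, minimal
  region-to-region paths and betweenness centrality, all written as
  CSV/JSON/GraphML plus a run manifest.
* :func:`run_energetics_pipeline` — Boltzmann fit table in, gating
  free-energy and perturbation tables out, optionally correlated
  against network metrics.

Outputs are deterministic functions of config + inputs; the manifest
records the config snapshot, package version, input checksums, stage
timings and warnings, and every file written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gating import DEFAULT_TEMPERATURE_K, energy_table, fit_gv, fit_inactivation
from .network import (
    DEFAULT_CONTACT_CUTOFF,
    DEFAULT_FLOOR_EPS,
    DEFAULT_KERNEL_DCUT,
    DEFAULT_KERNEL_TARGET,
    DEFAULT_N_BINS,
    block_weight_std,
    build_weight_matrix,
    compute_contact_map,
    estimate_mutual_information,
    solve_kernel_width,
)
from .paths import betweenness, build_graph, minimal_path_length
from .trajectory import (
    ResidueRegion,
    TrajectoryEnsemble,
    compute_ca_distances,
    compute_displacements,
    load_trajectory,
    superpose_frames,
)

__all__ = [
    "RunConfig",
    "RunManifest",
    "parse_regions",
    "network_results_from_trajectory",
    "run_network_pipeline",
    "run_energetics_pipeline",
    "load_edges_csv",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def parse_regions(spec: dict) -> dict[str, ResidueRegion]:
    """Region definitions from config.

    Each region is either ``{chains: [...], span: [first, last]}``
    (inclusive residue-number range on every listed chain) or
    ``{members: [[chain, resid], ...]}``.
    """
    regions = {}
    for name, body in spec.items():
        if "members" in body:
            members = {(str(c), int(r)) for c, r in body["members"]}
        elif "span" in body:
            first, last = body["span"]
            chains = body.get("chains", ["A"])
            members = {
                (str(c), r) for c in chains for r in range(int(first), int(last) + 1)
            }
        else:
            raise ValueError(f"region {name!r} needs 'members' or 'span'")
        regions[name] = ResidueRegion(name=name, members=frozenset(members))
    return regions


@dataclass
class RunConfig:
    """Validated parameters of a network run."""

    topology: str | None = None
    trajectory: str | None = None
    selection: str = "protein"
    stride: int = 1
    start: int = 0
    stop: int | None = None
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
    kernel_dcut: float = DEFAULT_KERNEL_DCUT
    kernel_target: float = DEFAULT_KERNEL_TARGET
    n_bins: int = DEFAULT_N_BINS
    log_base: float = math.e
    floor_eps: float = DEFAULT_FLOOR_EPS
    frame_time_ns: float | None = None
    block_length_ns: float = 25.0
    block_length_frames: int | None = None
    regions: dict = field(default_factory=dict)
    region_pairs: list = field(default_factory=list)  # [[source, target], ...]
    per_subunit: bool = True
    temperature: float = DEFAULT_TEMPERATURE_K
    seed: int = 0
    out_dir: str = "hergnet_run"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.stride < 1:
            raise ValueError("stride must be >= 1")
        for pair in cfg.region_pairs:
            if len(pair) != 2:
                raise ValueError("region_pairs entries must be [source, target]")
            for name in pair:
                if name not in cfg.regions:
                    raise ValueError(f"region pair references unknown region {name!r}")
        parse_regions(cfg.regions)  # validates structure early
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def resolve_block_length(self, n_frames: int) -> int:
        if self.block_length_frames is not None:
            return int(self.block_length_frames)
        if self.frame_time_ns:
            return max(int(round(self.block_length_ns / self.frame_time_ns)), 2)
        # fall back to five equal blocks
        return max(n_frames // 5, 2)


@dataclass
class RunManifest:
    """Record of one pipeline run, written atomically at the end."""

    config: dict
    version: str = __version__
    input_checksums: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    outputs: list = field(default_factory=list)

    def write(self, path) -> Path:
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))
        tmp.replace(path)
        return path


def _node_label(node) -> tuple[str, str]:
    if isinstance(node, tuple):
        return str(node[0]), str(node[1])
    return "A", str(node)


def network_results_from_trajectory(
    traj: TrajectoryEnsemble, config: RunConfig
) -> dict:
    """Run the full network stack in memory; returns intermediate objects."""
    sigma = solve_kernel_width(
        config.contact_cutoff, config.kernel_dcut, config.kernel_target
    )
    aligned = superpose_frames(traj)
    distances = compute_ca_distances(aligned)
    displacements = compute_displacements(aligned)
    contacts = compute_contact_map(distances, c=config.contact_cutoff, sigma=sigma)
    mi = estimate_mutual_information(
        displacements, n_bins=config.n_bins, log_base=config.log_base
    )
    W = build_weight_matrix(
        contacts, mi, floor_eps=config.floor_eps, log_base=config.log_base
    )
    block_len = config.resolve_block_length(traj.n_frames)
    blocks = None
    if traj.n_frames // block_len >= 2:
        blocks = block_weight_std(
            distances,
            displacements,
            block_len,
            c=config.contact_cutoff,
            sigma=sigma,
            n_bins=config.n_bins,
            log_base=config.log_base,
            floor_eps=config.floor_eps,
        )
    regions = parse_regions(config.regions)
    for region in regions.values():
        region.validate_against(traj)
    graph = build_graph(W, nodes=traj.residue_keys, regions=regions)
    path_results = {}
    for source, target in config.region_pairs:
        path_results[f"{source}->{target}"] = minimal_path_length(
            graph, source, target, per_subunit=config.per_subunit
        )
    centrality = betweenness(graph, normalized=True, weighted=True)
    return {
        "sigma": sigma,
        "trajectory": aligned,
        "contacts": contacts,
        "mi": mi,
        "weights": W,
        "blocks": blocks,
        "graph": graph,
        "paths": path_results,
        "centrality": centrality,
    }


def _write_edges_csv(results, traj, path: Path) -> None:
    W = results["weights"]
    C = results["contacts"].C
    Mn = results["mi"].M_norm
    sigma_w = results["blocks"].sigma_w if results["blocks"] is not None else None
    keys = traj.residue_keys
    ii, jj = np.nonzero(np.triu(W.edge_mask, k=1))
    rows = []
    for i, j in zip(ii, jj):
        rows.append(
            {
                "chain_i": keys[i][0],
                "resid_i": keys[i][1],
                "chain_j": keys[j][0],
                "resid_j": keys[j][1],
                "C": C[i, j],
                "M_norm": Mn[i, j],
                "w": W.W[i, j],
                "sigma_w": sigma_w[i, j] if sigma_w is not None else np.nan,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_edges_csv(path, regions: dict[str, ResidueRegion] | None = None):
    """Rebuild a CouplingGraph from a weighted edge-list CSV."""
    import networkx as nx

    from .paths import CouplingGraph

    df = pd.read_csv(path)
    G = nx.Graph()
    for row in df.itertuples(index=False):
        u = (str(row.chain_i), int(row.resid_i))
        v = (str(row.chain_j), int(row.resid_j))
        G.add_edge(u, v, weight=float(row.w))
    return CouplingGraph(graph=G, region_map=dict(regions or {}))


def _paths_payload(path_results) -> dict:
    payload = {}
    for pair, res in path_results.items():
        if isinstance(res, dict):
            payload[pair] = {
                chain: (
                    {
                        "nodes": [list(_node_label(n)) for n in p.nodes],
                        "length": p.length,
                    }
                    if p.reachable
                    else {"unreachable": True, "reason": p.reason}
                )
                for chain, p in res.items()
            }
        else:
            p = res
            payload[pair] = (
                {
                    "nodes": [list(_node_label(n)) for n in p.nodes],
                    "length": p.length,
                }
                if p.reachable
                else {"unreachable": True, "reason": p.reason}
            )
    return payload


def run_network_pipeline(config: RunConfig, traj: TrajectoryEnsemble | None = None):
    """Trajectory to network outputs on disk; returns (results, manifest).

    ``traj`` may be passed directly (e.g. from the synthetic generator);
    otherwise it is loaded from ``config.topology``/``config.trajectory``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config))
    timings = manifest.timings_s

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        t0 = time.perf_counter()
        if traj is None:
            if config.topology is None:
                raise ValueError("config.topology required when no trajectory given")
            traj = load_trajectory(
                config.topology,
                config.trajectory,
                selection=config.selection,
                stride=config.stride,
                start=config.start,
                stop=config.stop,
            )
            for key in ("topology", "trajectory"):
                p = getattr(config, key)
                if p:
                    manifest.input_checksums[key] = _sha256(Path(p))
        timings["load"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        results = network_results_from_trajectory(traj, config)
        timings["network"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        _write_edges_csv(results, traj, out / "edges.csv")
        manifest.outputs.append("edges.csv")

        (out / "paths.json").write_text(
            json.dumps(_paths_payload(results["paths"]), indent=2)
        )
        manifest.outputs.append("paths.json")

        bc = results["centrality"].bc
        pd.DataFrame(
            [
                {"chain": _node_label(n)[0], "resid": _node_label(n)[1], "bc": v}
                for n, v in sorted(bc.items(), key=lambda kv: str(kv[0]))
            ]
        ).to_csv(out / "centrality.csv", index=False)
        manifest.outputs.append("centrality.csv")

        import networkx as nx

        G = results["graph"].graph
        H = nx.relabel_nodes(G, {n: ":".join(_node_label(n)) for n in G.nodes})
        nx.write_graphml(H, out / "network.graphml")
        manifest.outputs.append("network.graphml")
        timings["write"] = time.perf_counter() - t0

    manifest.warnings = [str(w.message) for w in caught]
    manifest.write(out / "manifest.json")
    manifest.outputs.append("manifest.json")
    return results, manifest


def run_energetics_pipeline(
    fits_csv,
    out_dir,
    reference: str = "WT",
    metrics_csv=None,
    temperature: float = DEFAULT_TEMPERATURE_K,
):
    """Fit table to gating energetics (and optional metric correlations).

    ``fits_csv`` columns: construct, kind, z, z_se, v_half, v_half_se.
    ``metrics_csv`` (optional) columns: construct plus one column per
    network metric (e.g. bc, delta_d_min); each metric is correlated
    against ddG and \\|ddG\\| for each process kind.
    """
    from .paths import correlate_metric_vs_energy

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config={"fits_csv": str(fits_csv),
                                   "reference": reference,
                                   "temperature": temperature})
    manifest.input_checksums["fits_csv"] = _sha256(Path(fits_csv))
    fits = pd.read_csv(fits_csv)
    if fits.empty:
        manifest.warnings.append("empty construct table: nothing to do")
        manifest.write(out / "manifest.json")
        return None, manifest
    table = energy_table(fits, reference=reference)
    table.to_csv(out / "energy_table.csv", index=False)
    manifest.outputs.append("energy_table.csv")

    if metrics_csv is not None:
        manifest.input_checksums["metrics_csv"] = _sha256(Path(metrics_csv))
        metrics = pd.read_csv(metrics_csv)
        report = {}
        merged = table.merge(metrics, on="construct", how="inner")
        metric_cols = [
            c for c in metrics.columns if c != "construct"
            and pd.api.types.is_numeric_dtype(metrics[c])
        ]
        for kind, grp in merged.groupby("kind", sort=False):
            grp = grp[grp["construct"] != reference]
            for col in metric_cols:
                sub = grp.dropna(subset=[col, "ddG"])
                for target, ys in (
                    ("ddG", sub["ddG"]),
                    ("abs_ddG", sub["ddG"].abs()),
                ):
                    key = f"{col}_vs_{target}_{kind}"
                    try:
                        rep = correlate_metric_vs_energy(sub[col], ys)
                        report[key] = rep._asdict()
                    except ValueError as exc:
                        report[key] = {"error": str(exc)}
        (out / "correlation.json").write_text(json.dumps(report, indent=2))
        manifest.outputs.append("correlation.json")

    manifest.write(out / "manifest.json")
    manifest.outputs.append("manifest.json")
    return table, manifest


def fit_table_from_points(
    gv_points: dict[str, pd.DataFrame] | None = None,
    availability_points: dict[str, pd.DataFrame] | None = None,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> pd.DataFrame:
    """Boltzmann-fit every construct's point set into a fit table."""
    rows = []
    for kind, mapping, fitter in (
        ("activation", gv_points or {}, fit_gv),
        ("inactivation", availability_points or {}, fit_inactivation),
    ):
        for construct, points in mapping.items():
            fit = fitter(points, temperature=temperature)
            rows.append(
                {
                    "construct": construct,
                    "kind": kind,
                    "z": fit.z,
                    "z_se": fit.z_se,
                    "v_half": fit.v_half,
                    "v_half_se": fit.v_half_se,
                }
            )
    return pd.DataFrame(rows)
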