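"""Graph analysis of the residue communication network.

The protein is a weighted undirected graph: nodes are residues, edges
carry the -log coupling weights.  Minimal allosteric paths between key
regions (voltage sensor S4, pore S6, selectivity filter) come from
Dijkstra's algorithm, hub residues from Brandes betweenness centrality,
and mutant effects from the change in minimal path length
``delta_d_min = d_min(mut) - d_min(wt)`` aggregated over subunits.
Among equal-length shortest paths, the one with fewer hops and then the
lexicographically smallest node sequence is returned, so results are
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable, NamedTuple

import networkx as nx
import numpy as np
from scipy import stats

from .network import WeightMatrix
from .trajectory import ResidueRegion

logger = logging.getLogger(__name__)

__all__ = [
    "CouplingGraph",
    "AllostericPath",
    "NoPath",
    "CentralityProfile",
    "PathComparison",
    "CorrelationReport",
    "build_graph",
    "shortest_path",
    "minimal_path_length",
    "betweenness",
    "compare_paths",
    "correlate_metric_vs_energy",
]

_TIE_TOL = 1e-9


@dataclass
class CouplingGraph:
    """Residue graph with named key regions."""

    graph: nx.Graph
    region_map: dict[str, ResidueRegion] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for _, _, w in self.graph.edges(data="weight"):
            if w is None or w < 0:
                raise ValueError("all edges must carry non-negative weights")
        nodes = set(self.graph.nodes)
        for region in self.region_map.values():
            missing = set(region.members) - nodes
            if missing:
                raise ValueError(
                    f"region {region.name!r} references missing residues: "
                    f"{sorted(missing)}"
                )

    def region(self, name: str) -> ResidueRegion:
        try:
            return self.region_map[name]
        except KeyError:
            raise KeyError(f"unknown region {name!r}") from None

    def subunits(self) -> list[str]:
        """Chain identifiers present among the nodes (tuple-keyed graphs)."""
        chains = {n[0] for n in self.graph.nodes if isinstance(n, tuple)}
        return sorted(chains)


@dataclass
class AllostericPath:
    """Ordered residue chain realizing a minimal region-to-region path."""

    nodes: list[Hashable]
    length: float
    source_region: str = ""
    target_region: str = ""
    subunit: str | None = None

    @property
    def reachable(self) -> bool:
        return True


@dataclass
class NoPath:
    """Typed record for an unreachable region pair."""

    source_region: str = ""
    target_region: str = ""
    subunit: str | None = None
    reason: str = "no path exists"

    @property
    def reachable(self) -> bool:
        return False

    @property
    def length(self):
        return None


@dataclass
class CentralityProfile:
    """Betweenness centrality per residue."""

    bc: dict[Hashable, float]
    normalized: bool
    endpoints_included: bool = False

    def __post_init__(self) -> None:
        vals = np.array(list(self.bc.values()), dtype=float)
        if vals.size and vals.min() < 0:
            raise ValueError("betweenness must be non-negative")
        if self.normalized and vals.size and vals.max() > 1 + 1e-9:
            raise ValueError("normalized betweenness must not exceed 1")


@dataclass
class PathComparison:
    """Per-subunit minimal path lengths of two graphs and their difference."""

    d_min_wt: dict
    d_min_mut: dict
    delta_mean: float
    delta_sd: float
    n_subunits: int


class CorrelationReport(NamedTuple):
    r: float
    slope: float
    intercept: float
    n: int


def build_graph(
    W: WeightMatrix,
    nodes: list[Hashable] | None = None,
    regions: Iterable[ResidueRegion] | dict[str, ResidueRegion] | None = None,
) -> CouplingGraph:
    """Graph over all residues with finite-weight edges only."""
    n = W.n_nodes
    if nodes is None:
        nodes = list(range(n))
    if len(nodes) != n:
        raise ValueError("node list length must match the weight matrix")
    G = nx.Graph()
    G.add_nodes_from(nodes)
    ii, jj = np.nonzero(np.triu(W.edge_mask, k=1))
    for i, j in zip(ii, jj):
        G.add_edge(nodes[i], nodes[j], weight=float(W.W[i, j]))
    if regions is None:
        region_map = {}
    elif isinstance(regions, dict):
        region_map = dict(regions)
    else:
        region_map = {r.name: r for r in regions}
    return CouplingGraph(graph=G, region_map=region_map)


def _path_key(path):
    return (len(path), [str(n) for n in path])


def shortest_path(
    cg: CouplingGraph | nx.Graph,
    source_set: Iterable[Hashable],
    target_set: Iterable[Hashable],
    source_region: str = "",
    target_region: str = "",
    subunit: str | None = None,
) -> AllostericPath | NoPath:
    """Minimum-total-weight path over all (source, target) member pairs.

    A shared member makes the answer the zero-length path at that node.
    Unreachable pairs yield a :class:`NoPath` record, not an exception.
    """
    G = cg.graph if isinstance(cg, CouplingGraph) else cg
    source_set = set(source_set)
    target_set = set(target_set)
    if not source_set or not target_set:
        raise ValueError("source and target sets must be non-empty")
    shared = source_set & target_set
    if shared:
        node = sorted(shared, key=str)[0]
        return AllostericPath(
            [node], 0.0, source_region, target_region, subunit
        )

    best_len = np.inf
    pairs: list[tuple[Hashable, Hashable, float]] = []
    for s in source_set:
        if s not in G:
            continue
        lengths = nx.single_source_dijkstra_path_length(G, s, weight="weight")
        for t in target_set:
            if t in lengths:
                pairs.append((s, t, lengths[t]))
                best_len = min(best_len, lengths[t])
    if not np.isfinite(best_len):
        logger.warning(
            "no path between regions %r and %r", source_region, target_region
        )
        return NoPath(source_region, target_region, subunit)

    candidates = []
    for s, t, ln in pairs:
        if ln <= best_len + _TIE_TOL:
            for p in nx.all_shortest_paths(G, s, t, weight="weight"):
                candidates.append(p)
    best_path = min(candidates, key=_path_key)
    length = float(
        sum(G[u][v]["weight"] for u, v in zip(best_path, best_path[1:]))
    )
    return AllostericPath(best_path, length, source_region, target_region, subunit)


def _region_members_by_subunit(region: ResidueRegion):
    by_chain: dict[str, set] = {}
    for member in region.members:
        by_chain.setdefault(member[0], set()).add(member)
    return by_chain


def minimal_path_length(
    cg: CouplingGraph,
    source_region: str,
    target_region: str,
    per_subunit: bool = True,
) -> dict[str, AllostericPath | NoPath] | AllostericPath | NoPath:
    """d_min between two named regions, per subunit or tetramer-global.

    Per subunit, source and target members are restricted to the same
    chain (the graph itself stays shared, so paths may detour through
    other subunits); unreachable subunits are returned as
    :class:`NoPath` records and must be excluded from averages.
    """
    src = cg.region(source_region)
    tgt = cg.region(target_region)
    if not per_subunit:
        return shortest_path(
            cg, src.members, tgt.members, source_region, target_region
        )
    src_by = _region_members_by_subunit(src)
    tgt_by = _region_members_by_subunit(tgt)
    out = {}
    for chain in sorted(set(src_by) & set(tgt_by)):
        out[chain] = shortest_path(
            cg, src_by[chain], tgt_by[chain], source_region, target_region, chain
        )
    if not out:
        raise ValueError("regions share no subunit")
    return out


def betweenness(
    cg: CouplingGraph | nx.Graph,
    normalized: bool = True,
    weighted: bool = True,
) -> CentralityProfile:
    """Shortest-path betweenness centrality (Brandes), endpoints excluded."""
    G = cg.graph if isinstance(cg, CouplingGraph) else cg
    bc = nx.betweenness_centrality(
        G, normalized=normalized, weight="weight" if weighted else None
    )
    return CentralityProfile(bc=bc, normalized=normalized)


def compare_paths(
    wt: CouplingGraph,
    mut: CouplingGraph,
    source_region: str,
    target_region: str,
) -> PathComparison:
    """delta_d_min = d_min(mut) - d_min(wt), mean +- SD over subunits.

    Subunits where either graph is unreachable are excluded (with a
    warning) rather than contributing infinities.
    """
    for name in (source_region, target_region):
        if name not in wt.region_map or name not in mut.region_map:
            raise ValueError(f"region {name!r} missing from one of the graphs")
    d_wt = minimal_path_length(wt, source_region, target_region)
    d_mut = minimal_path_length(mut, source_region, target_region)
    if set(d_wt) != set(d_mut):
        raise ValueError("graphs disagree on subunits")
    deltas = []
    for chain in sorted(d_wt):
        a, b = d_wt[chain], d_mut[chain]
        if not (a.reachable and b.reachable):
            logger.warning("subunit %s unreachable; excluded from delta", chain)
            continue
        deltas.append(b.length - a.length)
    if not deltas:
        raise ValueError("no subunit is reachable in both graphs")
    deltas = np.array(deltas)
    sd = float(deltas.std(ddof=1)) if deltas.size > 1 else 0.0
    return PathComparison(
        d_min_wt={c: p.length for c, p in d_wt.items()},
        d_min_mut={c: p.length for c, p in d_mut.items()},
        delta_mean=float(deltas.mean()),
        delta_sd=sd,
        n_subunits=deltas.size,
    )


def correlate_metric_vs_energy(xs, ys) -> CorrelationReport:
    """Pearson r and ordinary least-squares line for metric vs energy."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("xs and ys must be equal-length 1-D sequences")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.linregress(x, y)
    return CorrelationReport(
        r=float(res.rvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=int(x.size),
    )
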