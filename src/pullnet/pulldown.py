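"""Virtual pulldown: seed-based first-order PPI network extraction.

A "virtual pulldown" expands a seed protein into its first-order interaction
neighborhood on a confidence-weighted interactome, mimicking a physical
pulldown experiment in silico. The collection builder chains: edge
confidence filtering, per-seed neighborhood induction, removal of
over-connected (promiscuous) nodes, size capping with enrichment-based
exemptions, merging of highly overlapping networks, and annotation of each
module with the metabolites whose seed proteins it contains.

All stages are deterministic: ties are broken lexicographically on protein
or network identifiers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .assoc_map import SeedMap

logger = logging.getLogger(__name__)

__all__ = [
    "Interactome",
    "NetworkModule",
    "PulldownParams",
    "filter_interactome",
    "first_order_network",
    "prune_overconnected",
    "cap_network",
    "merge_overlapping",
    "annotate_metabolites",
    "run_pulldown",
]


@dataclass
class Interactome:
    """Simple undirected protein graph with per-edge confidence in [0, 1]."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("interactome must not contain self-loops")
        for u, v, c in self.graph.edges(data="confidence"):
            if c is None or not (0.0 <= c <= 1.0):
                raise ValueError(f"edge ({u}, {v}) confidence {c!r} outside [0, 1]")

    @classmethod
    def from_edges(cls, edges: list[tuple[str, str, float]]) -> "Interactome":
        g = nx.Graph()
        for u, v, c in edges:
            g.add_edge(u, v, confidence=float(c))
        return cls(g)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    def degree_quantile(self, q: float) -> float:
        degs = np.array([d for _, d in self.graph.degree()], dtype=float)
        return float(np.quantile(degs, q))


@dataclass
class NetworkModule:
    """One pulldown network: an induced subgraph around one or more seeds."""

    network_id: str
    nodes: frozenset[str]
    edges: frozenset[frozenset[str]]
    seed_proteins: frozenset[str]
    linked_metabolites: frozenset[str] = frozenset()
    merged_from: list[str] = field(default_factory=list)
    cap_exempt: bool = False

    def __post_init__(self) -> None:
        if not self.seed_proteins <= self.nodes and self.nodes:
            raise ValueError("seed proteins must be a subset of module nodes")

    @property
    def size(self) -> int:
        return len(self.nodes)


@dataclass
class PulldownParams:
    """Tunables of the network-collection builder with study defaults."""

    min_confidence: float = 0.1
    degree_percentile: float = 0.99
    inside_fraction_min: float = 0.10
    max_nodes: int = 200
    exemption_q: float = 1e-4
    overlap_min: float = 0.75
    overlap_metric: str = "containment"  # or "jaccard"
    neighborhood: str = "induced"  # or "star"
    whitelist: frozenset[frozenset[str]] = frozenset()


def _induce(g: nx.Graph, nodes: frozenset[str]) -> frozenset[frozenset[str]]:
    sub = g.subgraph(nodes)
    return frozenset(frozenset((u, v)) for u, v in sub.edges)


def filter_interactome(g: Interactome, min_confidence: float = 0.1) -> Interactome:
    """Drop edges below the confidence threshold, then isolated nodes."""
    if not (0.0 <= min_confidence <= 1.0):
        raise ValueError("min_confidence must lie in [0, 1]")
    kept = nx.Graph()
    for u, v, c in g.graph.edges(data="confidence"):
        if c >= min_confidence:
            kept.add_edge(u, v, confidence=c)
    n_edges_removed = g.n_edges - kept.number_of_edges()
    n_nodes_removed = g.n_nodes - kept.number_of_nodes()
    logger.info(
        "filter_interactome: removed %d edges (< %.3g) and %d isolated nodes",
        n_edges_removed, min_confidence, n_nodes_removed,
    )
    return Interactome(kept)


def first_order_network(
    g: Interactome, seed: str, neighborhood: str = "induced"
) -> NetworkModule:
    """Extract the first-order network around one seed protein.

    Nodes are the seed plus its direct neighbors. With the default
    ``induced`` convention the module keeps every interactome edge among
    those nodes (including neighbor-neighbor edges); ``star`` keeps only
    seed-incident edges. A seed absent from the interactome yields an empty
    module with a warning rather than an error.
    """
    if seed not in g.graph:
        warnings.warn(f"seed protein {seed!r} not in interactome", stacklevel=2)
        return NetworkModule(
            network_id=f"net_{seed}", nodes=frozenset(), edges=frozenset(),
            seed_proteins=frozenset(),
        )
    nodes = frozenset({seed}) | frozenset(g.graph.neighbors(seed))
    if neighborhood == "induced":
        edges = _induce(g.graph, nodes)
    elif neighborhood == "star":
        edges = frozenset(frozenset((seed, v)) for v in g.graph.neighbors(seed))
    else:
        raise ValueError(f"unknown neighborhood convention {neighborhood!r}")
    return NetworkModule(
        network_id=f"net_{seed}", nodes=nodes, edges=edges,
        seed_proteins=frozenset({seed}),
    )


def prune_overconnected(
    m: NetworkModule,
    g: Interactome,
    degree_percentile: float = 0.99,
    inside_fraction_min: float = 0.10,
) -> NetworkModule:
    """Remove promiscuous non-seed nodes from a module.

    A node is over-connected when its global interactome degree exceeds the
    ``degree_percentile`` quantile of the degree distribution AND the
    fraction of its interactions falling inside the module is below
    ``inside_fraction_min`` — i.e. it interacts mostly elsewhere and is
    likely an experimental artifact in this context. Seeds are never
    removed; edges are re-induced after removal.
    """
    if not m.nodes:
        return m
    cutoff = g.degree_quantile(degree_percentile)
    module_graph = g.graph.subgraph(m.nodes)
    drop = set()
    for v in m.nodes - m.seed_proteins:
        global_deg = g.degree(v)
        if global_deg <= cutoff:
            continue
        inside = module_graph.degree(v)
        if inside / global_deg < inside_fraction_min:
            drop.add(v)
    if not drop:
        return m
    nodes = m.nodes - drop
    return replace(m, nodes=nodes, edges=_induce(g.graph, nodes))


def cap_network(
    m: NetworkModule,
    g: Interactome,
    max_nodes: int = 200,
    exemption_q: float = 1e-4,
    seed_enrichment_q: float | None = None,
) -> NetworkModule:
    """Cap a module at ``max_nodes`` unless its seed enrichment exempts it.

    A module whose pre-cap seed-protein over-representation q-value is at or
    below ``exemption_q`` is retained whole (``cap_exempt`` set). Otherwise
    the seeds are kept and neighbors are ranked by descending maximum edge
    confidence to any seed, ties broken by ascending protein id, until
    ``max_nodes`` nodes remain; edges are re-induced.
    """
    if m.size <= max_nodes:
        return m
    if seed_enrichment_q is not None and seed_enrichment_q <= exemption_q:
        return replace(m, cap_exempt=True)

    def seed_affinity(v: str) -> float:
        best = 0.0
        for s in m.seed_proteins:
            if g.graph.has_edge(v, s):
                best = max(best, g.graph.edges[v, s]["confidence"])
        return best

    others = sorted(m.nodes - m.seed_proteins, key=lambda v: (-seed_affinity(v), v))
    budget = max_nodes - len(m.seed_proteins)
    nodes = frozenset(m.seed_proteins) | frozenset(others[:budget])
    return replace(m, nodes=nodes, edges=_induce(g.graph, nodes))


def _overlap(a: frozenset[str], b: frozenset[str], metric: str) -> float:
    if not a or not b:
        return 0.0
    inter = len(a & b)
    if metric == "containment":
        return inter / min(len(a), len(b))
    if metric == "jaccard":
        return inter / len(a | b)
    raise ValueError(f"unknown overlap metric {metric!r}")


def merge_overlapping(
    collection: list[NetworkModule],
    g: Interactome,
    overlap_min: float = 0.75,
    metric: str = "containment",
    whitelist: frozenset[frozenset[str]] = frozenset(),
) -> list[NetworkModule]:
    """Merge highly overlapping networks until a fixpoint.

    Overlap defaults to containment, |A ∩ B| / min(|A|, |B|), so a small
    network engulfed by a larger one merges. Each round the currently
    highest-overlap pair strictly above ``overlap_min`` is merged (union of
    nodes/seeds/metabolites, edges re-induced); ties are broken
    lexicographically on the id pair. Pairs in ``whitelist`` (original or
    ancestor ids) are never merged, mirroring networks kept separate because
    they originate from distinct experimental groups. At return, every
    non-whitelisted pair has overlap <= ``overlap_min``.
    """
    modules = {m.network_id: m for m in collection}
    if len(modules) != len(collection):
        raise ValueError("network ids must be unique")

    def ancestors(m: NetworkModule) -> set[str]:
        return {m.network_id, *m.merged_from}

    def whitelisted(m1: NetworkModule, m2: NetworkModule) -> bool:
        return any(
            frozenset((a, b)) in whitelist
            for a in ancestors(m1)
            for b in ancestors(m2)
        )

    while True:
        best: tuple[float, str, str] | None = None
        ids = sorted(modules)
        for i, id1 in enumerate(ids):
            for id2 in ids[i + 1:]:
                m1, m2 = modules[id1], modules[id2]
                ov = _overlap(m1.nodes, m2.nodes, metric)
                if ov <= overlap_min or whitelisted(m1, m2):
                    continue
                cand = (ov, id1, id2)
                if best is None or ov > best[0] or (ov == best[0] and (id1, id2) < best[1:]):
                    best = cand
        if best is None:
            return [modules[i] for i in sorted(modules)]
        _, id1, id2 = best
        m1, m2 = modules.pop(id1), modules.pop(id2)
        nodes = m1.nodes | m2.nodes
        merged = NetworkModule(
            network_id=min(id1, id2),
            nodes=nodes,
            edges=_induce(g.graph, nodes),
            seed_proteins=m1.seed_proteins | m2.seed_proteins,
            linked_metabolites=m1.linked_metabolites | m2.linked_metabolites,
            merged_from=sorted({id1, id2, *m1.merged_from, *m2.merged_from}),
            cap_exempt=m1.cap_exempt or m2.cap_exempt,
        )
        modules[merged.network_id] = merged


def annotate_metabolites(m: NetworkModule, seeds: SeedMap) -> NetworkModule:
    """Record the metabolites whose seed proteins intersect the module."""
    linked = frozenset(
        met
        for met, prots in seeds.metabolite_to_proteins.items()
        if prots & m.nodes
    )
    return replace(m, linked_metabolites=linked)


def run_pulldown(
    g: Interactome,
    seed_map: SeedMap,
    params: PulldownParams | None = None,
) -> tuple[list[NetworkModule], dict]:
    """Build the full network collection from an interactome and a seed map.

    Stages: confidence filter -> per-seed first-order extraction -> hub
    pruning -> size capping (with seed-enrichment exemption) -> overlap
    merging -> metabolite annotation. Returns the ordered collection and a
    run log of per-stage counts. The whole pipeline is deterministic.
    """
    from .enrich import bh_adjust, fisher_ora  # late import avoids a cycle

    params = params or PulldownParams()
    log: dict = {"input_nodes": g.n_nodes, "input_edges": g.n_edges}

    filtered = filter_interactome(g, params.min_confidence)
    log["filtered_nodes"] = filtered.n_nodes
    log["filtered_edges"] = filtered.n_edges

    seeds = seed_map.union_seed_list
    if not seeds:
        warnings.warn("no mapped seed proteins; empty collection", stacklevel=2)
        return [], {**log, "n_seeds": 0, "n_networks": 0}
    log["n_seeds"] = len(seeds)
    log["seeds_outside_interactome"] = sum(1 for s in seeds if s not in filtered.graph)

    modules = []
    for i, s in enumerate(seeds):
        m = first_order_network(filtered, s, neighborhood=params.neighborhood)
        if m.nodes:
            modules.append(replace(m, network_id=f"n{i:04d}_{s}"))
    log["n_first_order"] = len(modules)

    modules = [
        prune_overconnected(
            m, filtered, params.degree_percentile, params.inside_fraction_min
        )
        for m in modules
    ]

    # pre-cap seed-protein enrichment, BH-adjusted across oversized modules,
    # drives the cap exemption
    background = frozenset(filtered.graph.nodes)
    seed_set = frozenset(s for s in seeds if s in background)
    oversized = [m for m in modules if m.size > params.max_nodes]
    exempt_q: dict[str, float] = {}
    if oversized and seed_set:
        pvals = [
            fisher_ora(m.nodes, seed_set, background, network_id=m.network_id).p_value
            for m in oversized
        ]
        for m, q in zip(oversized, bh_adjust(pvals)):
            exempt_q[m.network_id] = q
    modules = [
        cap_network(
            m, filtered, params.max_nodes, params.exemption_q,
            seed_enrichment_q=exempt_q.get(m.network_id),
        )
        for m in modules
    ]
    log["n_cap_exempt"] = sum(m.cap_exempt for m in modules)

    modules = merge_overlapping(
        modules, filtered, params.overlap_min, params.overlap_metric, params.whitelist
    )
    log["n_after_merge"] = len(modules)

    modules = [annotate_metabolites(m, seed_map) for m in modules]
    modules.sort(key=lambda m: m.network_id)
    log["n_networks"] = len(modules)
    return modules, log
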