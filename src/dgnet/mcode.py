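"""Detection of densely interconnected topological modules (MCODE-style).

Vertices are weighted by the local density of the highest k-core of their
closed neighborhood: weight(v) = k_max * density(highest k-core of N[v]).
Members of an isolated m-clique therefore weigh exactly m - 1.  Modules are
grown greedily from the highest-weight unvisited vertex, admitting the seed's
neighbors whose weight exceeds (1 - vwp) times the seed weight; an optional
haircut iteratively prunes singly-connected members, and an optional fluff
step adds dense-neighborhood boundary vertices.

By default module growth is confined to the seed's closed neighborhood, which
keeps a module from leaking across a single bridge edge between two dense
regions (two bridged cliques yield two modules, not one).  The classical
recursive expansion that follows admitted vertices outward is available via
``expand="recursive"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .enrichment_profiles import EnrichmentResult, hypergeom_ora
from .io_formats import GeneSetCollection, PPIEdge

logger = logging.getLogger(__name__)

__all__ = ["TopoModule", "graph_from_edges", "vertex_weighting", "find_modules", "annotate_modules"]


@dataclass
class TopoModule:
    """A detected module: >= 2 genes inducing a connected dense subgraph."""

    module_id: str
    genes: set[str]
    score: float  # density x size of the induced subgraph
    seed: str | None = None
    annotations: list[EnrichmentResult] = field(default_factory=list)


def graph_from_edges(edges: Sequence[PPIEdge]) -> nx.Graph:
    """Simple undirected graph from an edge list (self-loops dropped)."""
    G = nx.Graph()
    for e in edges:
        if e.gene_a != e.gene_b:
            G.add_edge(e.gene_a, e.gene_b)
    return G


def vertex_weighting(graph: nx.Graph) -> nx.Graph:
    """Attach MCODE vertex weights as a ``weight`` node attribute.

    weight(v) = k_max * density(S) where k_max is the highest core number in
    the subgraph induced by the closed neighborhood N[v], and S the subgraph
    of vertices attaining that core number.  Isolated vertices weigh 0.
    """
    if any(u == v for u, v in nx.selfloop_edges(graph)):
        raise ValueError("graph must be simple (no self-loops)")
    G = graph.copy()
    for v in G.nodes:
        neigh = set(G[v]) | {v}
        if len(neigh) < 2:
            G.nodes[v]["weight"] = 0.0
            continue
        H = G.subgraph(neigh)
        core = nx.core_number(H)
        k_max = max(core.values())
        S = H.subgraph([u for u, c in core.items() if c >= k_max])
        G.nodes[v]["weight"] = float(k_max) * nx.density(S)
    return G


def _haircut(G: nx.Graph, members: set[str]) -> set[str]:
    """Iteratively remove members with fewer than 2 neighbors in the module."""
    members = set(members)
    while True:
        sub = G.subgraph(members)
        trim = {v for v in members if sub.degree(v) < 2}
        if not trim or trim == members:
            return members - trim if trim != members else set()
        members -= trim


def find_modules(
    graph: nx.Graph,
    vwp: float = 0.2,
    haircut: bool = True,
    fluff: bool = False,
    fluff_density: float = 0.5,
    expand: str = "neighborhood",
) -> list[TopoModule]:
    """Greedy seed-expansion module detection.

    Seeds are processed in descending vertex weight (ties by node label); a
    neighbor v joins the module iff weight(v) > (1 - vwp) * weight(seed).
    ``expand="neighborhood"`` (default) restricts candidates to the seed's own
    neighbors; ``expand="recursive"`` also examines neighbors of admitted
    vertices.  Every vertex belongs to at most one module (fluffed boundary
    vertices excepted); modules are returned in descending score.
    """
    if not 0.0 <= vwp <= 1.0:
        raise ValueError(f"vwp must be in [0, 1], got {vwp}")
    if expand not in ("neighborhood", "recursive"):
        raise ValueError(f"expand must be 'neighborhood' or 'recursive', got {expand!r}")
    G = vertex_weighting(graph)
    w = {v: G.nodes[v]["weight"] for v in G.nodes}
    order = sorted(G.nodes, key=lambda v: (-w[v], str(v)))
    visited: set[str] = set()
    modules: list[TopoModule] = []
    for seed in order:
        if seed in visited:
            continue
        threshold = (1.0 - vwp) * w[seed]
        members = {seed}
        frontier = [seed]
        while frontier:
            nxt: list[str] = []
            for u in frontier:
                for v in sorted(G[u], key=str):
                    if v in visited or v in members:
                        continue
                    if w[v] > threshold:
                        members.add(v)
                        nxt.append(v)
            frontier = nxt if expand == "recursive" else []
        if haircut:
            members = _haircut(G, members)
        # only final members are consumed; haircut-trimmed vertices stay
        # available to seed or join later modules
        visited.add(seed)
        visited |= members
        if fluff:
            boundary = set()
            for u in members:
                for v in G[u]:
                    if v in members or v in boundary:
                        continue
                    neigh = set(G[v]) | {v}
                    if len(neigh) >= 2 and nx.density(G.subgraph(neigh)) > fluff_density:
                        boundary.add(v)
            members = members | boundary
        if len(members) < 2:
            continue
        sub = G.subgraph(members)
        if not nx.is_connected(sub):
            # keep the seed's component; growth is seed-anchored
            comp = nx.node_connected_component(sub, seed) if seed in members else max(
                nx.connected_components(sub), key=len
            )
            members = set(comp)
            sub = G.subgraph(members)
            if len(members) < 2:
                continue
        modules.append(
            TopoModule("", set(members), nx.density(sub) * len(members), seed=seed)
        )
    modules.sort(key=lambda m: (-m.score, str(sorted(m.genes)[0])))
    for i, m in enumerate(modules, start=1):
        m.module_id = f"M{i}"
    logger.info("find_modules: %d modules detected (vwp=%.2f)", len(modules), vwp)
    return modules


def annotate_modules(
    modules: Sequence[TopoModule],
    sets: GeneSetCollection,
    universe: "set[str] | Sequence[str]",
) -> list[TopoModule]:
    """Attach gene-set over-representation results to each module.

    Each module is one query; BH correction is applied within the module's
    own family of set tests.
    """
    if not modules:
        raise ValueError("no modules to annotate")
    for m in modules:
        m.annotations = hypergeom_ora(m.genes, sets, universe, query_id=m.module_id)
    return list(modules)
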