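"""Merged pathway-process network and focus-pathway extraction.

The GOBP term graph (process-process edges from the ontology) and the
bipartite network (pathway-process edges from kappa selection) are merged
into one functional pathway-process network.  Pathways never connect
directly: they communicate through shared biological processes.

Given a focus pathway, the extraction keeps, for every other reachable
pathway, ALL unweighted shortest paths to the focus, and prunes the rest.
A vertex v lies on a shortest path between p and the focus f iff
d(p, v) + d(v, f) = d(p, f); an edge (u, v) lies on one iff it advances a
shortest path in either direction.  Mandatory waypoints (processes shared
by every shortest path from a pathway to the focus) are found by exact
shortest-path counting: v is mandatory iff sigma_p(v) * sigma_f(v) equals
the total number of shortest paths sigma_p(f).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .bipartite_network import BipartiteNetwork

logger = logging.getLogger(__name__)


class ExtractionError(ValueError):
    pass


def merge(gobp_graph: nx.Graph, net: BipartiteNetwork) -> nx.Graph:
    """Union of process-process and pathway-process edges.

    Vertices carry a ``side`` attribute ("pathway" or "gobp").  An id
    appearing on both sides is an error; GOBP vertices present in only one
    input are retained.
    """
    collision = set(gobp_graph.nodes) & net.pathway_vertices
    if collision:
        raise ExtractionError(f"ids used as both pathway and process: {sorted(collision)[:5]}")
    merged = nx.Graph()
    for node in gobp_graph.nodes:
        merged.add_node(node, side="gobp")
    for node in net.gobp_vertices:
        merged.add_node(node, side="gobp")
    for node in net.pathway_vertices:
        merged.add_node(node, side="pathway")
    merged.add_edges_from(gobp_graph.edges())
    for p, g, w in net.edges:
        merged.add_edge(p, g, kappa=w)
    return merged


def _bfs_counts(graph: nx.Graph, source: str) -> tuple[dict[str, int], dict[str, int]]:
    """BFS distances and exact shortest-path counts from *source*."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = [source]
    while queue:
        next_queue = []
        for u in queue:
            for v in graph.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    sigma[v] = sigma[u]
                    next_queue.append(v)
                elif dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
        queue = next_queue
    return dist, sigma


@dataclass
class ExtractedNetwork:
    """Backbone of shortest paths from every pathway to the focus pathway."""

    focus: str
    graph: nx.Graph
    distances: dict[str, int]  # reachable non-focus pathways -> BFS distance
    unreachable: set[str]
    waypoint_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    _merged: nx.Graph | None = None

    @property
    def retained_vertices(self) -> set[str]:
        return set(self.graph.nodes)


def extract_focus(merged: nx.Graph, focus: str, backbone: bool = True) -> ExtractedNetwork:
    """Extract the focus-pathway subnetwork.

    Retains the focus, every reachable pathway, and every process vertex on
    at least one shortest path between some pathway and the focus.  With
    ``backbone=True`` (default) only edges on such paths are kept; otherwise
    the full induced subgraph on retained vertices.  Unreachable pathways
    are dropped from the graph but reported.  An isolated focus yields a
    single-vertex network with a warning.
    """
    if focus not in merged:
        raise ExtractionError(f"focus pathway {focus!r} not in the merged network")
    if merged.nodes[focus].get("side") != "pathway":
        raise ExtractionError(f"focus {focus!r} is not a pathway vertex")

    pathways = {n for n, d in merged.nodes(data=True) if d.get("side") == "pathway"} - {focus}
    dist_f, _sigma_f = _bfs_counts(merged, focus)
    reachable = {p for p in pathways if p in dist_f}
    unreachable = pathways - reachable
    if unreachable:
        logger.info("%d pathways unreachable from focus %s", len(unreachable), focus)
    if not reachable:
        logger.warning("focus %s is isolated from every other pathway", focus)
        solo = nx.Graph()
        solo.add_node(focus, **merged.nodes[focus])
        return ExtractedNetwork(focus, solo, {}, unreachable, {}, merged)

    retained: set[str] = {focus} | reachable
    kept_edges: set[tuple[str, str]] = set()
    for p in sorted(reachable):
        dist_p, _ = _bfs_counts(merged, p)
        d_total = dist_f[p]
        on_path = {
            v
            for v in dist_p
            if v in dist_f and dist_p[v] + dist_f[v] == d_total
        }
        retained |= on_path
        for u in on_path:
            for v in merged.neighbors(u):
                if v in on_path and abs(dist_p[u] - dist_p[v]) == 1:
                    # edge advances a shortest path between p and focus
                    kept_edges.add((u, v) if u <= v else (v, u))

    sub = nx.Graph()
    for node in retained:
        sub.add_node(node, **merged.nodes[node])
    if backbone:
        for u, v in kept_edges:
            sub.add_edge(u, v, **merged.get_edge_data(u, v, default={}))
    else:
        for u, v, data in merged.subgraph(retained).edges(data=True):
            sub.add_edge(u, v, **data)

    distances = {p: dist_f[p] for p in reachable}
    for node in sub.nodes:
        if node == focus:
            sub.nodes[node]["role"] = "focus"
        elif node in reachable:
            sub.nodes[node]["role"] = "pathway"
        else:
            sub.nodes[node]["role"] = "waypoint"
            if dist_f.get(node) == 1:
                sub.nodes[node]["direct_impact"] = True
    return ExtractedNetwork(focus, sub, distances, unreachable, {}, merged)


def mandatory_waypoints(merged: nx.Graph, pathway: str, focus: str) -> set[str]:
    """Process vertices on EVERY shortest path between *pathway* and *focus*."""
    dist_f, sigma_f = _bfs_counts(merged, focus)
    dist_p, sigma_p = _bfs_counts(merged, pathway)
    if pathway not in dist_f:
        raise ExtractionError(f"{pathway!r} unreachable from {focus!r}")
    d_total = dist_f[pathway]
    total = sigma_f[pathway]
    result = set()
    for v in dist_p:
        if v in (pathway, focus) or v not in dist_f:
            continue
        if dist_p[v] + dist_f[v] == d_total and sigma_p[v] * sigma_f[v] == total:
            result.add(v)
    return result


def route_report(extracted: ExtractedNetwork) -> list[dict]:
    """Per-pathway distance to focus and mandatory process waypoints.

    Waypoints are computed on the merged network when available (so they
    reflect all original routes), else on the extracted backbone, which
    preserves all shortest paths by construction.
    """
    graph = extracted._merged if extracted._merged is not None else extracted.graph
    rows = []
    for pathway in sorted(extracted.distances):
        rows.append(
            {
                "pathway_id": pathway,
                "distance": extracted.distances[pathway],
                "mandatory_waypoints": sorted(
                    mandatory_waypoints(graph, pathway, extracted.focus)
                ),
            }
        )
    return rows


def write_route_tsv(rows: list[dict], path) -> None:
    with open(path, "w") as handle:
        handle.write("pathway_id\tdistance\tmandatory_waypoints\n")
        for row in rows:
            handle.write(
                f"{row['pathway_id']}\t{row['distance']}\t"
                + ",".join(row["mandatory_waypoints"])
                + "\n"
            )
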