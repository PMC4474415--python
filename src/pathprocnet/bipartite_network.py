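"""Bipartite pathway-process network from top-fraction kappa selection.

The kappa similarity matrix (GOBP rows x pathway columns) is thresholded
by rank: the top ``fraction`` of all cells (default 1%) become edges of an
undirected bipartite graph whose vertices are exactly the endpoints of
selected edges.  Ties at the cutoff value are all included, so the result
is deterministic and independent of matrix ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

from .annotation_io import IncidenceFixture
from .kappa import KappaMatrix


class BipartiteError(ValueError):
    pass


@dataclass
class BipartiteNetwork:
    """Pathway-GOBP edges with kappa weights; no isolated vertices."""

    edges: list[tuple[str, str, float]]  # (pathway_id, gobp_id, kappa)
    selection_cutoff: float
    pathway_vertices: set[str] = field(init=False)
    gobp_vertices: set[str] = field(init=False)

    def __post_init__(self) -> None:
        self.edges = sorted(self.edges, key=lambda e: (e[0], e[1]))
        self.pathway_vertices = {p for p, _g, _w in self.edges}
        self.gobp_vertices = {g for _p, g, _w in self.edges}
        overlap = self.pathway_vertices & self.gobp_vertices
        if overlap:
            raise BipartiteError(f"ids on both sides of the bipartition: {sorted(overlap)[:5]}")

    def to_graph(self) -> nx.Graph:
        graph = nx.Graph()
        for p in self.pathway_vertices:
            graph.add_node(p, side="pathway")
        for g in self.gobp_vertices:
            graph.add_node(g, side="gobp")
        for p, g, w in self.edges:
            graph.add_edge(p, g, kappa=w)
        return graph

    def write_edge_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as handle:
            handle.write("pathway_id\tgobp_id\tkappa\n")
            for p, g, w in self.edges:
                handle.write(f"{p}\t{g}\t{w:.6g}\n")


def select_top_edges(matrix: KappaMatrix, fraction: float = 0.01) -> BipartiteNetwork:
    """Select the top ``fraction`` of pathway-GOBP pairs by kappa.

    With M total cells, k = ceil(fraction * M) cells are taken by value;
    every cell tying the k-th value is also included.  Non-finite cells
    are never selected; a matrix without any finite cell is an error.
    """
    if not (0.0 < fraction <= 1.0):
        raise BipartiteError("fraction must be in (0, 1]")
    scores = matrix.scores
    finite = np.isfinite(scores)
    if not finite.any():
        raise BipartiteError("kappa matrix has no finite entries")
    m_total = scores.size
    k = math.ceil(fraction * m_total)
    flat = scores[finite]
    if k >= flat.size:
        cutoff = float(flat.min())
    else:
        cutoff = float(np.sort(flat)[::-1][k - 1])
    rows, cols = np.where(finite & (scores >= cutoff))
    edges = [
        (matrix.pathway_ids[j], matrix.gobp_ids[i], float(scores[i, j]))
        for i, j in zip(rows.tolist(), cols.tolist())
    ]
    return BipartiteNetwork(edges=edges, selection_cutoff=cutoff)


def from_incidence(fixture: IncidenceFixture) -> BipartiteNetwork:
    """Interpret a binary incidence matrix as a bipartite network (weight 1)."""
    edges = [
        (p, g, 1.0)
        for gi, g in enumerate(fixture.gobp_names)
        for pj, p in enumerate(fixture.pathway_ids)
        if fixture.marks[gi, pj]
    ]
    return BipartiteNetwork(edges=edges, selection_cutoff=1.0)


def network_summary(net: BipartiteNetwork) -> dict[str, int]:
    graph = net.to_graph()
    comps = sorted((len(c) for c in nx.connected_components(graph)), reverse=True)
    return {
        "n_pathways": len(net.pathway_vertices),
        "n_gobps": len(net.gobp_vertices),
        "n_vertices": len(net.pathway_vertices) + len(net.gobp_vertices),
        "n_edges": len(net.edges),
        "n_components": len(comps),
        "largest_component_size": comps[0] if comps else 0,
    }


def neighbor_set(net: BipartiteNetwork, vertex: str) -> set[str]:
    """Opposite-side vertices sharing an edge with *vertex*."""
    if vertex in net.pathway_vertices:
        return {g for p, g, _w in net.edges if p == vertex}
    if vertex in net.gobp_vertices:
        return {p for p, g, _w in net.edges if g == vertex}
    raise BipartiteError(f"vertex {vertex!r} not in the network")


def write_graphml(net: BipartiteNetwork, path: str | Path) -> None:
    nx.write_graphml(net.to_graph(), str(path))


def write_dot(graph: nx.Graph, path: str | Path) -> None:
    """Minimal DOT export (no pydot dependency)."""
    with Path(path).open("w") as handle:
        handle.write("graph pathprocnet {\n")
        for node, data in graph.nodes(data=True):
            attrs = ",".join(f'{k}="{v}"' for k, v in data.items())
            handle.write(f'  "{node}" [{attrs}];\n' if attrs else f'  "{node}";\n')
        for u, v in graph.edges():
            handle.write(f'  "{u}" -- "{v}";\n')
        handle.write("}\n")
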