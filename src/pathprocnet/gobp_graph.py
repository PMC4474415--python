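"""Undirected graph over enriched GO Biological Process terms.

Enriched terms are mapped onto the complete GO DAG and connected when the
DAG links them.  Two edge modes are supported:

* ``direct`` (default): an edge joins two enriched terms when one is a
  direct parent/child of the other in the DAG.  This reproduces the
  sparse hierarchical adjacency of the ontology.
* ``closure``: an edge joins any ancestor/offspring pair, however many
  intermediate (non-enriched) terms lie between them.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import networkx as nx

from .annotation_io import OntologyDAG

logger = logging.getLogger(__name__)


class GraphError(ValueError):
    pass


def build_gobp_graph(
    enriched_ids: Iterable[str], dag: OntologyDAG, mode: str = "direct"
) -> nx.Graph:
    """Undirected term graph on the enriched GOBP ids.

    Ids absent from the DAG are dropped with a warning; an empty retained
    vertex set is an error.  The result is simple (no self-loops or
    parallel edges).
    """
    wanted = set(enriched_ids)
    retained = wanted & dag.nodes
    missing = wanted - retained
    if missing:
        logger.warning("%d enriched ids not in the ontology were dropped", len(missing))
    if not retained:
        raise GraphError("no enriched term maps onto the ontology")

    graph = nx.Graph()
    graph.add_nodes_from(retained)
    if mode == "direct":
        for child, parent, _rel in dag.edges():
            if child in retained and parent in retained and child != parent:
                graph.add_edge(child, parent)
    elif mode == "closure":
        for term in retained:
            for anc in dag.ancestors(term) & retained:
                if anc != term:
                    graph.add_edge(term, anc)
    else:
        raise GraphError(f"unknown edge mode {mode!r}")
    return graph


def components(graph: nx.Graph) -> list[set[str]]:
    """Connected components, largest first (ties by smallest member id)."""
    comps = [set(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def component_summary(graph: nx.Graph) -> dict[str, int]:
    """Counts of multi-vertex components and isolated vertices."""
    comps = components(graph)
    multi = [c for c in comps if len(c) > 1]
    return {
        "n_vertices": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "n_components": len(comps),
        "n_multi_vertex_components": len(multi),
        "n_isolated_vertices": sum(1 for c in comps if len(c) == 1),
        "largest_component_size": len(comps[0]) if comps else 0,
    }


def degree_table(
    graph: nx.Graph, names: Mapping[str, str] | None = None, top_k: int = 20
) -> list[tuple[str, str, int]]:
    """Top-k vertices by degree: (id, name, degree) tuples.

    Sorted by degree descending, ties broken by term id ascending.
    """
    if top_k < 1:
        raise GraphError("top_k must be >= 1")
    names = names or {}
    ranked = sorted(graph.degree, key=lambda item: (-item[1], item[0]))
    return [(tid, names.get(tid, tid), deg) for tid, deg in ranked[:top_k]]


def write_degree_tsv(rows: list[tuple[str, str, int]], path) -> None:
    with open(path, "w") as handle:
        handle.write("term_id\tname\tdegree\n")
        for tid, name, deg in rows:
            handle.write(f"{tid}\t{name}\t{deg}\n")
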