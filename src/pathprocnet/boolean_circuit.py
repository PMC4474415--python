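"""Boolean circuit representation of pathways over biological processes.

Each pathway in the bipartite network is expressed as an AND-of-ORs
function of its connected GO Biological Process terms: processes that are
connected to each other in the GOBP term graph form an OR group (any one
active suffices), and distinct groups combine with AND (every group must
contribute an active process).  "Connected" means path-connected within
the subgraph of the term graph induced on the pathway's neighbours —
i.e. the OR groups are that subgraph's connected components — which keeps
the function well defined on chains of adjacency.

Example: neighbours {B1, B2, B3} with one term-graph edge B1-B2 give the
circuit (B1 OR B2) AND (B3).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx

from .bipartite_network import BipartiteNetwork, neighbor_set

logger = logging.getLogger(__name__)


class CircuitError(ValueError):
    pass


def _canonical_groups(groups) -> tuple[frozenset[str], ...]:
    frozen = tuple(frozenset(g) for g in groups)
    return tuple(sorted(frozen, key=lambda g: sorted(g)))


@dataclass(frozen=True)
class BooleanCircuit:
    """AND-of-ORs pathway function; or_groups partition the neighbour set."""

    pathway_id: str
    or_groups: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        groups = _canonical_groups(self.or_groups)
        if not groups or any(len(g) == 0 for g in groups):
            raise CircuitError("or_groups must be non-empty sets")
        seen: set[str] = set()
        for group in groups:
            if seen & group:
                raise CircuitError("or_groups must be pairwise disjoint")
            seen |= group
        object.__setattr__(self, "or_groups", groups)

    @property
    def inputs(self) -> frozenset[str]:
        return frozenset().union(*self.or_groups)


def derive_circuit(
    pathway_id: str, net: BipartiteNetwork, gobp_graph: nx.Graph
) -> BooleanCircuit:
    """Derive the pathway's circuit from its bipartite neighbours.

    OR groups are the connected components of ``gobp_graph`` restricted to
    the pathway's neighbour set.  Neighbours missing from the term graph
    are treated as isolated vertices (logged).
    """
    neighbors = neighbor_set(net, pathway_id)
    if not neighbors:
        raise CircuitError(f"pathway {pathway_id!r} has no connected processes")
    missing = neighbors - set(gobp_graph.nodes)
    if missing:
        logger.info(
            "pathway %s: %d neighbours absent from the term graph, treated as isolated",
            pathway_id,
            len(missing),
        )
    induced = gobp_graph.subgraph(neighbors - missing)
    groups = [set(c) for c in nx.connected_components(induced)]
    groups.extend({m} for m in missing)
    return BooleanCircuit(pathway_id=pathway_id, or_groups=_canonical_groups(groups))


def evaluate(circuit: BooleanCircuit, states: Mapping[str, int]) -> int:
    """Pathway state: 1 iff every OR group has at least one active process."""
    missing = circuit.inputs - set(states)
    if missing:
        raise CircuitError(f"missing states for: {sorted(missing)}")
    for value in states.values():
        if value not in (0, 1):
            raise CircuitError("states must be binary (0/1)")
    return int(all(any(states[g] for g in group) for group in circuit.or_groups))


def format_expression(circuit: BooleanCircuit, names: Mapping[str, str] | None = None) -> str:
    """Canonical parenthesized AND-of-ORs text, deterministic ordering."""
    names = names or {}
    parts = []
    for group in circuit.or_groups:
        labels = [names.get(g, g) for g in sorted(group)]
        parts.append("(" + " OR ".join(labels) + ")")
    return " AND ".join(parts)


def circuit_to_dict(circuit: BooleanCircuit, names: Mapping[str, str] | None = None) -> dict:
    return {
        "pathway_id": circuit.pathway_id,
        "or_groups": [sorted(g) for g in circuit.or_groups],
        "expression": format_expression(circuit, names),
    }


def circuit_from_dict(payload: Mapping) -> BooleanCircuit:
    return BooleanCircuit(
        pathway_id=payload["pathway_id"],
        or_groups=tuple(frozenset(g) for g in payload["or_groups"]),
    )


def write_circuits_json(circuits, path: str | Path, names=None) -> None:
    payload = [circuit_to_dict(c, names) for c in circuits]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
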