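"""Input readers and writers for annotation data.

Handles the four input formats of the pipeline: plain-text gene lists,
GMT gene sets, OBO ontologies (Gene Ontology Biological Process), and
two-column term/gene annotation tables.  Also ships a small packaged
incidence matrix linking 7 coagulation-related pathways to 34 GO
Biological Process terms, used as a worked example and regression anchor
for the bipartite-network code.

Gene identifiers are normalized by uppercasing and trimming whitespace;
no cross-namespace mapping (symbol to accession etc.) is attempted, since
silent identifier translation risks wrong merges when inputs mix UniProt
entry names with gene symbols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet

logger = logging.getLogger(__name__)

#: Annotation sources recognized from term-id prefixes.
SOURCES = ("GOBP", "KEGG", "REACTOME", "BIOCARTA")

#: OBO relations that contribute DAG edges by default.  ``regulates`` and
#: friends are excluded: the ancestor/offspring structure used downstream
#: is the is_a / part_of hierarchy.
DEFAULT_RELATIONS = ("is_a", "part_of")


class AnnotationError(ValueError):
    """Raised for malformed or unusable annotation input."""


def normalize_gene_id(raw: str) -> str:
    """Normalize a gene/protein identifier: trim whitespace, uppercase.

    Idempotent; raises :class:`AnnotationError` on empty input.
    """
    gene = raw.strip().upper()
    if not gene:
        raise AnnotationError("empty gene identifier")
    return gene


def infer_source(term_id: str, default: str = "GOBP") -> str:
    """Infer the annotation source from a term-id prefix.

    ``GO:`` -> GOBP, ``hsa`` -> KEGG, ``REACT_`` -> REACTOME,
    ``h_`` -> BIOCARTA; anything else falls back to *default*.
    """
    if term_id.startswith("GO:"):
        return "GOBP"
    if term_id.startswith("hsa"):
        return "KEGG"
    if term_id.startswith("REACT_"):
        return "REACTOME"
    if term_id.startswith("h_"):
        return "BIOCARTA"
    return default


@dataclass(frozen=True)
class TermRecord:
    """One annotation term (pathway or GO biological process) with its gene set."""

    term_id: str
    name: str
    source: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.term_id:
            raise AnnotationError("term_id must be non-empty")
        if self.source not in SOURCES:
            raise AnnotationError(f"unknown source {self.source!r}")
        object.__setattr__(self, "genes", frozenset(self.genes))

    @property
    def size(self) -> int:
        return len(self.genes)


def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain-text gene list (one identifier per line).

    Lines starting with ``#`` and blank lines are ignored; identifiers are
    normalized and deduplicated.  Raises :class:`AnnotationError` if no
    usable identifier remains.
    """
    path = Path(path)
    n_read = 0
    genes: set[str] = set()
    with path.open() as handle:
        for line in handle:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            n_read += 1
            genes.add(normalize_gene_id(stripped))
    if not genes:
        raise AnnotationError(f"{path}: no usable gene identifiers after filtering")
    logger.info("read %d lines, retained %d unique genes from %s", n_read, len(genes), path)
    return genes


def read_gmt(path: str | Path, default_source: str = "GOBP") -> list[TermRecord]:
    """Read a GMT file (term id, description, then member genes, tab-separated).

    The source of each term is inferred from its id prefix, falling back to
    *default_source*.  Duplicate term ids and lines with fewer than three
    fields are errors.
    """
    path = Path(path)
    records: list[TermRecord] = []
    seen: set[str] = set()
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise AnnotationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            term_id, name = fields[0].strip(), fields[1].strip()
            if term_id in seen:
                raise AnnotationError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            seen.add(term_id)
            genes = frozenset(normalize_gene_id(g) for g in fields[2:] if g.strip())
            records.append(
                TermRecord(term_id, name or term_id, infer_source(term_id, default_source), genes)
            )
    return records


def write_gmt(records: Iterable[TermRecord], path: str | Path) -> None:
    """Write TermRecords to GMT; genes sorted so output is deterministic."""
    path = Path(path)
    with path.open("w") as handle:
        for rec in records:
            handle.write("\t".join([rec.term_id, rec.name, *sorted(rec.genes)]) + "\n")


def read_annotation_table(
    path: str | Path, default_source: str = "GOBP", names: Mapping[str, str] | None = None
) -> list[TermRecord]:
    """Read a two-column TSV (term_id <TAB> gene_id) into TermRecords.

    Rows are grouped by term id; *names* optionally supplies display names.
    """
    path = Path(path)
    by_term: dict[str, set[str]] = {}
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) < 2:
                raise AnnotationError(f"{path}:{lineno}: expected term_id<TAB>gene_id")
            by_term.setdefault(fields[0].strip(), set()).add(normalize_gene_id(fields[1]))
    names = names or {}
    return [
        TermRecord(tid, names.get(tid, tid), infer_source(tid, default_source), frozenset(genes))
        for tid, genes in sorted(by_term.items())
    ]


@dataclass
class OntologyDAG:
    """Directed acyclic graph of GO Biological Process terms.

    Edges run child -> parent and carry a ``relation`` attribute
    (``is_a`` or ``part_of`` by default).  Obsolete terms are dropped at
    load time; they have no placement in the hierarchy.
    """

    graph: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def names(self) -> dict[str, str]:
        return {n: data.get("name", n) for n, data in self.graph.nodes(data=True)}

    def edges(self) -> list[tuple[str, str, str]]:
        """(child, parent, relation) triples."""
        return [(u, v, k) for u, v, k in self.graph.edges(keys=True)]

    def undirected_view(self) -> nx.Graph:
        """Simple undirected projection of the DAG (parent/child adjacency)."""
        return nx.Graph(self.graph)

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable by following child->parent edges from *term*."""
        return nx.descendants(self.graph, term)

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise AnnotationError(f"ontology graph contains a cycle: {cycle}")


def read_obo(
    path: str | Path,
    relations: Sequence[str] = DEFAULT_RELATIONS,
    namespace: str | None = "biological_process",
) -> OntologyDAG:
    """Load an OBO 1.2/1.4 ontology into an :class:`OntologyDAG`.

    Only ``[Term]`` stanzas are consumed; when the file declares namespaces,
    terms outside *namespace* are dropped (pass ``namespace=None`` to keep
    all).  Edges for relations outside *relations* are skipped with a
    warning.  Obsolete terms never enter the graph.  A cycle among the
    retained edges raises :class:`AnnotationError` naming one cycle.
    """
    raw = obonet.read_obo(str(path))  # MultiDiGraph, child->parent, keyed by relation
    dag = nx.MultiDiGraph()
    kept_nodes = []
    for node, data in raw.nodes(data=True):
        ns = data.get("namespace")
        if namespace is not None and ns is not None and ns != namespace:
            continue
        kept_nodes.append(node)
        dag.add_node(node, name=data.get("name", node))
    node_set = set(kept_nodes)
    skipped: set[str] = set()
    for child, parent, rel in raw.edges(keys=True):
        if child not in node_set or parent not in node_set:
            continue
        if rel not in relations:
            skipped.add(rel)
            continue
        dag.add_edge(child, parent, key=rel, relation=rel)
    if skipped:
        logger.warning("skipped OBO relation types: %s", ", ".join(sorted(skipped)))
    out = OntologyDAG(dag)
    out.validate()
    return out


def write_obo(dag: OntologyDAG, path: str | Path, ontology_name: str = "synthetic-go") -> None:
    """Serialize an OntologyDAG back to minimal OBO (round-trip support)."""
    names = dag.names()
    by_child: dict[str, list[tuple[str, str]]] = {}
    for child, parent, rel in dag.edges():
        by_child.setdefault(child, []).append((rel, parent))
    with Path(path).open("w") as handle:
        handle.write(f"format-version: 1.2\nontology: {ontology_name}\n")
        for node in sorted(dag.nodes):
            handle.write(f"\n[Term]\nid: {node}\nname: {names[node]}\n")
            handle.write("namespace: biological_process\n")
            for rel, parent in sorted(by_child.get(node, [])):
                if rel == "is_a":
                    handle.write(f"is_a: {parent}\n")
                else:
                    handle.write(f"relationship: {rel} {parent}\n")


# ---------------------------------------------------------------------------
# Packaged incidence fixture: 7 coagulation-related pathways x 34 GOBP terms
# ---------------------------------------------------------------------------

#: Pathway column labels.  F, C and A are identified in the source material
#: (fibrinolysis pathway, complement-and-coagulation cascades, and the acute
#: myocardial infarction pathway); the remaining columns are kept as letters.
INCIDENCE_PATHWAY_NAMES = {
    "F": "h_fibrinolysisPathway",
    "C": "hsa04610 Complement and coagulation cascades",
    "A": "h_amiPathway",
    "E": "pathway E",
    "P": "pathway P",
    "I": "pathway I",
    "H": "pathway H",
}


@dataclass(frozen=True)
class IncidenceFixture:
    """Binary pathway x GOBP incidence matrix (34 processes, 7 pathways)."""

    pathway_ids: tuple[str, ...]
    pathway_names: Mapping[str, str]
    gobp_names: tuple[str, ...]
    marks: np.ndarray  # shape (len(gobp_names), len(pathway_ids)), dtype int

    def __post_init__(self) -> None:
        marks = np.asarray(self.marks, dtype=int)
        if marks.shape != (len(self.gobp_names), len(self.pathway_ids)):
            raise AnnotationError("incidence matrix shape does not match labels")
        if not np.isin(marks, (0, 1)).all():
            raise AnnotationError("incidence matrix entries must be binary")
        object.__setattr__(self, "marks", marks)

    def column_sums(self) -> dict[str, int]:
        """Connected-GOBP count per pathway."""
        sums = self.marks.sum(axis=0)
        return {p: int(s) for p, s in zip(self.pathway_ids, sums)}

    def gobps_of(self, pathway_id: str) -> set[str]:
        j = self.pathway_ids.index(pathway_id)
        return {name for name, mark in zip(self.gobp_names, self.marks[:, j]) if mark}


def load_incidence_fixture() -> IncidenceFixture:
    """Load the packaged 34 x 7 pathway-process incidence matrix."""
    ref = resources.files("pathprocnet").joinpath("data/mi_incidence.tsv")
    lines = ref.read_text().splitlines()
    header = lines[0].split("\t")
    pathway_ids = tuple(header[1:])
    gobp_names: list[str] = []
    rows: list[list[int]] = []
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.split("\t")
        gobp_names.append(fields[0])
        rows.append([int(x) for x in fields[1:]])
    return IncidenceFixture(
        pathway_ids=pathway_ids,
        pathway_names=dict(INCIDENCE_PATHWAY_NAMES),
        gobp_names=tuple(gobp_names),
        marks=np.array(rows, dtype=int),
    )
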