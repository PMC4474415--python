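"""Synthetic ontologies, annotation corpora, and planted-structure scenarios.

Every stage of the pipeline can be exercised without downloading GO or any
pathway database.  All randomness lives in this module and is driven by an
explicit seed; the analysis modules are deterministic given their inputs.

Overlap model
-------------
Planted pathway-process associations are parameterized by an expected
Jaccard index j between two gene sets of equal size s.  The planted
overlap is o = round(j * 2s / (1 + j)), since Jaccard = o / (2s - o); the
pathway set takes o genes from the process set and s - o fresh genes drawn
from the rest of the universe.  j = 1 yields identical sets.  Background
sets are uniform draws, so their expected Jaccard is roughly
s / (2|U| - s) — near zero for the default sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .annotation_io import OntologyDAG, TermRecord, write_gmt, write_obo


@dataclass
class OverlapProfile:
    """Parameters of the annotation-corpus generator.

    ``planted_pairs`` gives (gobp_index, pathway_index) pairs whose gene
    sets are sampled with expected Jaccard ``planted_jaccard``; all other
    pairs overlap only by chance.
    """

    n_pathways: int = 8
    term_size: int = 20
    planted_pairs: tuple[tuple[int, int], ...] = ()
    planted_jaccard: float = 0.5


@dataclass
class SyntheticScenario:
    seed: int
    universe: set[str]
    dag: OntologyDAG
    gobp_terms: list[TermRecord]
    pathway_terms: list[TermRecord]
    planted: dict = field(default_factory=dict)


def _gene_universe(size: int) -> list[str]:
    return [f"GENE{i:05d}" for i in range(1, size + 1)]


def make_dag(n_terms: int, branching: int = 2, seed: int = 0) -> OntologyDAG:
    """Rooted random DAG of synthetic biological-process terms.

    Node ids are GO-style; edges run child -> parent and only from
    higher-index to lower-index nodes, so the graph is acyclic by
    construction.  Each non-root picks 1..branching parents; most edges
    are ``is_a`` with occasional ``part_of``.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    graph = nx.MultiDiGraph()
    ids = [f"GO:{7000000 + i:07d}" for i in range(n_terms)]
    for i, term in enumerate(ids):
        graph.add_node(term, name=f"synthetic process {i}")
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(branching, i) + 1))
        parents = rng.choice(i, size=k, replace=False)
        for p in parents:
            rel = "part_of" if rng.random() < 0.2 else "is_a"
            graph.add_edge(ids[i], ids[int(p)], key=rel, relation=rel)
    dag = OntologyDAG(graph)
    dag.validate()
    return dag


def _sample_set(rng: np.random.Generator, pool: Sequence[str], size: int) -> frozenset[str]:
    idx = rng.choice(len(pool), size=min(size, len(pool)), replace=False)
    return frozenset(pool[i] for i in idx)


def planted_overlap_size(term_size: int, jaccard: float) -> int:
    """Overlap count giving expected Jaccard j for two sets of equal size."""
    return int(round(jaccard * 2 * term_size / (1.0 + jaccard)))


def make_annotations(
    dag: OntologyDAG,
    universe_size: int,
    overlap_profile: OverlapProfile | None = None,
    seed: int = 0,
) -> tuple[list[TermRecord], list[TermRecord]]:
    """Gene sets for every DAG term plus a batch of synthetic pathways.

    GOBP gene sets are uniform draws from the universe.  Pathways listed
    in ``overlap_profile.planted_pairs`` share genes with their designated
    process at the profile's expected Jaccard; the rest are background.
    """
    if universe_size < 1:
        raise ValueError("universe_size must be >= 1")
    profile = overlap_profile or OverlapProfile()
    rng = np.random.default_rng(seed)
    universe = _gene_universe(universe_size)
    size = profile.term_size

    gobp_ids = sorted(dag.nodes)
    names = dag.names()
    gobp_terms = [
        TermRecord(tid, names[tid], "GOBP", _sample_set(rng, universe, size))
        for tid in gobp_ids
    ]

    planted_by_pathway = {pj: gi for gi, pj in profile.planted_pairs}
    pathway_terms: list[TermRecord] = []
    prefixes = ("hsa", "h_path", "REACT_")
    for j in range(profile.n_pathways):
        prefix = prefixes[j % len(prefixes)]
        pid = f"hsa{j:05d}" if prefix == "hsa" else f"{prefix}{j}"
        if j in planted_by_pathway:
            partner = sorted(gobp_terms[planted_by_pathway[j]].genes)
            o = planted_overlap_size(size, profile.planted_jaccard)
            shared = _sample_set(rng, partner, o)
            rest_pool = [g for g in universe if g not in set(partner)]
            fresh = _sample_set(rng, rest_pool, size - len(shared))
            genes = shared | fresh
        else:
            genes = _sample_set(rng, universe, size)
        pathway_terms.append(TermRecord(pid, f"synthetic pathway {j}", "KEGG" if pid.startswith("hsa") else ("BIOCARTA" if pid.startswith("h_") else "REACTOME"), genes))
    return gobp_terms, pathway_terms


def make_enrichment_scenario(
    n_terms: int = 20,
    universe_size: int = 500,
    term_size: int = 25,
    planted_fraction: float = 0.6,
    query_size: int = 30,
    seed: int = 0,
) -> SyntheticScenario:
    """Corpus with one planted over-represented process.

    The query list takes ``planted_fraction`` of its genes from the
    planted term's gene set and the rest uniformly from outside it, so the
    planted term should dominate the enrichment ranking.
    """
    rng = np.random.default_rng(seed)
    dag = make_dag(n_terms, seed=seed)
    gobp_terms, pathway_terms = make_annotations(
        dag, universe_size, OverlapProfile(n_pathways=5, term_size=term_size), seed=seed + 1
    )
    planted_idx = int(rng.integers(len(gobp_terms)))
    planted = gobp_terms[planted_idx]
    n_from_term = int(round(planted_fraction * query_size))
    universe = _gene_universe(universe_size)
    inside = _sample_set(rng, sorted(planted.genes), n_from_term)
    outside_pool = [g for g in universe if g not in planted.genes]
    outside = _sample_set(rng, outside_pool, query_size - len(inside))
    scenario = SyntheticScenario(
        seed=seed,
        universe=set(universe),
        dag=dag,
        gobp_terms=gobp_terms,
        pathway_terms=pathway_terms,
        planted={"enriched_term": planted.term_id, "query": set(inside | outside)},
    )
    return scenario


def make_kappa_scenario(
    n_gobp: int = 25,
    n_pathways: int = 8,
    universe_size: int = 400,
    term_size: int = 20,
    n_planted: int = 4,
    planted_jaccard: float = 0.5,
    seed: int = 0,
) -> SyntheticScenario:
    """Corpus with planted high-overlap pathway-process pairs.

    Planted pairs link pathway j to process j (j < n_planted); everything
    else is background.  Used to check that planted pairs outrank
    background pairs in kappa.
    """
    dag = make_dag(n_gobp, seed=seed)
    profile = OverlapProfile(
        n_pathways=n_pathways,
        term_size=term_size,
        planted_pairs=tuple((j, j) for j in range(n_planted)),
        planted_jaccard=planted_jaccard,
    )
    gobp_terms, pathway_terms = make_annotations(dag, universe_size, profile, seed=seed)
    planted_pairs = [
        (gobp_terms[j].term_id, pathway_terms[j].term_id) for j in range(n_planted)
    ]
    return SyntheticScenario(
        seed=seed,
        universe=set(_gene_universe(universe_size)),
        dag=dag,
        gobp_terms=gobp_terms,
        pathway_terms=pathway_terms,
        planted={"pairs": planted_pairs, "jaccard": planted_jaccard},
    )


def make_circuit_scenario(groups: Sequence[int], seed: int = 0) -> SyntheticScenario:
    """Scenario whose derived circuit has exactly the requested OR groups.

    ``groups`` lists the sizes of the OR groups.  Process ids B1, B2, ...
    are assigned group by group; within a group consecutive processes are
    chained parent-child in the DAG (path-connected), and no edge joins
    different groups, so the induced components match the partition
    exactly.  One pathway P1 connects to every process.
    """
    if not groups or any(g < 1 for g in groups):
        raise ValueError("all group sizes must be >= 1")
    rng = np.random.default_rng(seed)
    n = sum(groups)
    ids = [f"B{i}" for i in range(1, n + 1)]
    graph = nx.MultiDiGraph()
    for i, term in enumerate(ids):
        graph.add_node(term, name=f"process {i + 1}")
    planted_groups: list[set[str]] = []
    pos = 0
    for size in groups:
        member_ids = ids[pos : pos + size]
        planted_groups.append(set(member_ids))
        for child, parent in zip(member_ids[1:], member_ids[:-1]):
            graph.add_edge(child, parent, key="is_a", relation="is_a")
        pos += size
    dag = OntologyDAG(graph)

    universe = _gene_universe(10 * n)
    gobp_terms = [
        TermRecord(tid, f"process {i + 1}", "GOBP", _sample_set(rng, universe, 8))
        for i, tid in enumerate(ids)
    ]
    pathway_genes = frozenset().union(*(t.genes for t in gobp_terms))
    pathway_terms = [TermRecord("P1", "synthetic pathway", "KEGG", pathway_genes)]
    return SyntheticScenario(
        seed=seed,
        universe=set(universe),
        dag=dag,
        gobp_terms=gobp_terms,
        pathway_terms=pathway_terms,
        planted={"pathway": "P1", "or_groups": planted_groups},
    )


def make_merged_scenario(
    n_pathways: int = 6,
    n_gobp: int = 15,
    pathway_edge_prob: float = 0.3,
    gobp_edge_prob: float = 0.15,
    seed: int = 0,
) -> tuple[nx.Graph, str]:
    """Random merged pathway-process network plus a focus pathway.

    Pathway vertices connect only to process vertices (Bernoulli edges);
    process vertices connect to each other with their own edge
    probability.  Every pathway is guaranteed at least one process
    neighbour so the network is non-trivial.  Returns the merged graph and
    the id of the first pathway as focus.
    """
    rng = np.random.default_rng(seed)
    merged = nx.Graph()
    pathways = [f"PW{i}" for i in range(n_pathways)]
    gobps = [f"GO:{8000000 + i:07d}" for i in range(n_gobp)]
    for p in pathways:
        merged.add_node(p, side="pathway")
    for g in gobps:
        merged.add_node(g, side="gobp")
    for p in pathways:
        hit = False
        for g in gobps:
            if rng.random() < pathway_edge_prob:
                merged.add_edge(p, g, kappa=float(rng.uniform(0.3, 1.0)))
                hit = True
        if not hit:
            g = gobps[int(rng.integers(n_gobp))]
            merged.add_edge(p, g, kappa=float(rng.uniform(0.3, 1.0)))
    for i in range(n_gobp):
        for j in range(i + 1, n_gobp):
            if rng.random() < gobp_edge_prob:
                merged.add_edge(gobps[i], gobps[j])
    return merged, pathways[0]


def write_scenario(scenario: SyntheticScenario, outdir: str | Path) -> dict[str, str]:
    """Serialize a scenario to standard formats consumable by the pipeline.

    Writes genes.txt (query list), gobp.gmt, pathways.gmt and
    ontology.obo; returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    query = scenario.planted.get("query")
    if query is None:
        # default query: union of the first few pathway gene sets, so the
        # corpus terms are genuinely over-represented in it
        query = set()
        for term in scenario.pathway_terms[: max(2, len(scenario.pathway_terms) // 2)]:
            query |= term.genes
    paths = {
        "gene_list": str(outdir / "genes.txt"),
        "gobp_gmt": str(outdir / "gobp.gmt"),
        "pathway_gmt": str(outdir / "pathways.gmt"),
        "obo": str(outdir / "ontology.obo"),
    }
    with open(paths["gene_list"], "w") as handle:
        handle.write("# synthetic query gene list\n")
        for gene in sorted(query):
            handle.write(gene + "\n")
    write_gmt(scenario.gobp_terms, paths["gobp_gmt"])
    write_gmt(scenario.pathway_terms, paths["pathway_gmt"])
    write_obo(scenario.dag, paths["obo"])
    return paths


PRESETS = ("enrichment", "kappa", "circuit", "extraction")


def make_preset(preset: str, seed: int = 0) -> SyntheticScenario:
    """Named scenarios for the ``simulate`` CLI subcommand."""
    if preset == "enrichment":
        return make_enrichment_scenario(seed=seed)
    if preset == "kappa":
        return make_kappa_scenario(seed=seed)
    if preset == "circuit":
        return make_circuit_scenario([2, 1], seed=seed)
    if preset == "extraction":
        # larger corpus with several planted links so the merged network
        # has multi-hop routes between pathways
        return make_kappa_scenario(
            n_gobp=40, n_pathways=10, universe_size=600, n_planted=6, seed=seed
        )
    raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
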