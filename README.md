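# pathprocnet

Pathway databases (KEGG, Reactome, BioCarta) describe overlapping biology in
inconsistent vocabularies: the same signalling pathway can carry different
member lists and different prose in each source. `pathprocnet` standardizes
pathway descriptions for a condition-specific gene/protein list by linking
enriched pathways to Gene Ontology Biological Process (GOBP) terms, producing
a *functional pathway–process network* in which pathways communicate only
through shared biological processes. It is aimed at systems biologists who
want to compare pathways across databases, read a pathway as a logic circuit
of processes, and trace the routes that connect other pathways to a pathway
of interest.

## Method

Given a query list of genes/proteins and annotation corpora (pathway and
GOBP gene sets, plus the GO ontology):

1. **Enrichment.** Each term is screened by the one-tailed Fisher exact test
   and its jackknifed variant, the EASE score, over a background universe
   (defaults: overlap count ≥ 2, EASE ≤ 0.05).
2. **Kappa similarity.** Agreement between a GOBP term *T_i* and a pathway
   *T_j* with gene sets *G_i*, *G_j* over the universe
   *G* = ∪*G_k* is Cohen's κ: with a = |G_i ∩ G_j|, b = |G_i \ G_j|,
   c = |G_j \ G_i|, d = |G \ (G_i ∪ G_j)| and n = a+b+c+d,

       Pr_agree  = (a + d) / n
       Pr_random = ((a+b)(a+c) + (b+d)(c+d)) / n²
       κ         = (Pr_agree − Pr_random) / (1 − Pr_random)

3. **GOBP term graph.** Enriched processes are connected when the GO DAG
   (is_a / part_of) links them parent–child (optional ancestor-closure mode).
4. **Bipartite network.** The top 1% of all (GOBP, pathway) cells by κ —
   ties at the cutoff included — become edges of an undirected bipartite
   pathway–process graph.
5. **Boolean circuits.** Each pathway becomes an AND-of-ORs function of its
   connected processes: processes that are path-connected in the term graph
   form an OR group; distinct groups combine with AND.
6. **Focus extraction.** The term graph and bipartite graph are merged, and
   a focus pathway's subnetwork keeps every vertex and edge on any
   unweighted shortest path from each other pathway to the focus, reporting
   per-pathway distances and mandatory waypoint processes.

## Worked example

The package ships a 34-process × 7-pathway incidence matrix around the
acute myocardial infarction (AMI) pathway:

```python
from pathprocnet import load_incidence_fixture, neighbor_set
from pathprocnet.bipartite_network import from_incidence, network_summary

fixture = load_incidence_fixture()
net = from_incidence(fixture)
print(network_summary(net))
print(fixture.column_sums())
```

prints

```
{'n_pathways': 7, 'n_gobps': 34, 'n_vertices': 41, 'n_edges': 95, 'n_components': 1, 'largest_component_size': 41}
{'F': 22, 'C': 17, 'A': 16, 'E': 14, 'P': 12, 'I': 9, 'H': 5}
```

i.e. one connected pathway–process network in which the fibrinolysis
pathway (F) is characterized by 22 processes, the complement-and-coagulation
cascades (C) by 17, and the AMI pathway (A) by 16. The three
best-connected pathways jointly cover 32 of the 34 processes and share 8
(coagulation, blood coagulation and their regulation, hemostasis,
regulation of body fluid levels), marking those as the underlying processes
of the infarction response:

```python
sets = [neighbor_set(net, p) for p in ("F", "C", "A")]
print(len(set.union(*sets)), len(set.intersection(*sets)))   # 32 8
```

Boolean circuits come from the term-graph structure. With three processes
B1, B2, B3 connected to a pathway P and one term-graph edge B1–B2:

```python
from pathprocnet.boolean_circuit import BooleanCircuit, evaluate, format_expression
circuit = BooleanCircuit("P", (frozenset({"B1", "B2"}), frozenset({"B3"})))
print(format_expression(circuit))                      # (B1 OR B2) AND (B3)
print(evaluate(circuit, {"B1": 1, "B2": 0, "B3": 1}))  # 1
print(evaluate(circuit, {"B1": 1, "B2": 1, "B3": 0}))  # 0
```

P activates only when B3 is active and at least one of B1/B2 is.

## Command line

Each stage is a subcommand (`enrich`, `kappa`, `gobp-graph`, `bipartite`,
`circuits`, `extract`), `simulate` writes synthetic corpora, and `run`
drives the whole chain from a YAML config:

```sh
pathprocnet simulate --preset extraction --seed 3 --out demo/
pathprocnet run --config demo/config.yaml
```

which reports `{"stages": ["load", "enrich", "kappa", "gobp_graph",
"bipartite", "circuits", "merge", "extract"]}` and leaves edge lists,
GraphML exports, circuit JSON, a route report and a manifest under
`demo/results/`.

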