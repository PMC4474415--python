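# Methods

## Model

`pathprocnet` treats two annotation terms as binary raters over a gene
universe and scores their agreement with Cohen's kappa. The pipeline
composes six stages — enrichment screen, kappa matrix, GOBP term graph,
top-fraction bipartite selection, Boolean circuits, focus extraction — each
deterministic given its inputs. All randomness is confined to the
synthetic-data generators.

### Enrichment screen

One-tailed Fisher exact test on the 2×2 table of (query, term) membership
within the universe; `p = P(X ≥ a)` for hypergeometric X with the table's
margins (computed by `scipy.stats.hypergeom.sf`). The EASE score is the
jackknifed variant: the overlap cell a is replaced by max(a−1, 0) before
testing, so an overlap of one gene is never significant. The default
variant decrements a and leaves b, c, d unchanged; a `shift` variant that
moves the removed gene to b (preserving the query margin) is available.
The degenerate jackknifed table arising from a = n = 1 is defined to have
p = 1. Defaults `min_count = 2`, `max_ease = 0.05` are the conventional
screening thresholds for this analysis. No multiple-testing correction is
applied by default (the screen is a filter, not an inference); a
Benjamini–Hochberg q-value can be attached with `bh_correct=True`.

### Kappa

κ = (Pr_agree − Pr_random)/(1 − Pr_random) with
Pr_agree = (a+d)/n and Pr_random = ((a+b)(a+c) + (b+d)(c+d))/n².
The universe defaults to the union of the gene sets of all supplied terms
and is overridable. Degenerate denominator (Pr_random = 1, e.g. two empty
sets): κ is defined as 1 when the intersected sets are equal (b = c = 0),
else 0 — this preserves "identical terms agree perfectly" without a
division by zero. The matrix computation is vectorized over binary
membership matrices; each cell equals the scalar formula exactly (checked
to 1e-12 against rational arithmetic in the tests).

### GOBP term graph

Ontology terms are read with `obonet` (OBO 1.2/1.4); only
`biological_process` terms are retained when namespaces are declared,
obsolete terms are dropped (they have no placement in the DAG), and
`is_a`/`part_of` edges are loaded by default — other relation types
(`regulates`, …) are skipped with a warning since the ancestor/offspring
hierarchy is built on the first two. Acyclicity is verified at load; a
cycle is an error naming one offending cycle.

"Linked in the complete DAG" is interpreted as a **direct** parent–child
edge by default, which reproduces the sparse hierarchical adjacency of the
ontology; `mode="closure"` instead connects every ancestor/offspring pair,
covering the looser reading. The choice matters for enriched sets with
gaps: a grandparent–grandchild pair is connected only in closure mode.

### Bipartite selection

With an N_GOBP × N_pathway matrix, k = ⌈fraction · M⌉ cells (M = matrix
size, default fraction 0.01) are selected by value and **all ties at the
k-th value are included**: selection is then deterministic and independent
of row/column order, at the cost of occasionally exceeding k edges.
Ceiling guarantees a non-empty selection for small matrices. Vertices are
exactly the endpoints of selected edges; the smallest selected κ is
recorded as the cutoff. Edges carry κ as a weight for reporting, but all
downstream graph algorithms are unweighted.

### Boolean circuits

A pathway's circuit inputs are its bipartite neighbours. OR groups are the
connected components of the term graph induced on the neighbour set —
path-connectedness, not direct adjacency, because pairwise OR/AND labels
are inconsistent on chains (B1–B2–B3 with B1, B3 non-adjacent would
receive both labels). Groups combine with AND. The circuit is canonical
(groups and members sorted), so serialized circuits are diffable.
Evaluation is monotone by construction: activating a process can never
deactivate a pathway.

### Focus extraction

The merged network is the exact union of term-graph edges and bipartite
edges; pathway–pathway edges cannot occur (an id on both sides is an
error). For a focus pathway f, a vertex v lies on a shortest path from
pathway p to f iff d(p,v) + d(v,f) = d(p,f); an edge (u,v) lies on one iff
additionally |d(p,u) − d(p,v)| = 1 within that vertex set. All shortest
paths are therefore retained without enumerating them. Mandatory waypoints
use exact shortest-path counts (integer arithmetic): v is on every
shortest path p→f iff σ_p(v)·σ_f(v) = σ_p(f). Unreachable pathways are
excluded from the graph and reported separately. The default output is the
shortest-path backbone; `backbone=False` retains the full induced subgraph.
An isolated focus yields a single-vertex network with a warning rather
than an error.

## Packaged incidence fixture

`data/mi_incidence.tsv` is a 34-process × 7-pathway binary incidence
matrix around the acute myocardial infarction pathway (columns F, C, A, E,
P, I, H; F = fibrinolysis pathway, C = complement-and-coagulation
cascades, A = AMI pathway; the remaining columns are kept as letters).
Its column sums (22, 17, 16, 14, 12, 9, 5), the 32-process union and
8-process intersection of the three best-connected pathways are
regression-pinned in the tests and recomputed by `scripts/acceptance.py`.

## Synthetic data

The generators emulate the *structure* of annotation corpora, not their
content:

- `make_dag` builds a rooted random DAG (edges only from higher to lower
  index, hence acyclic by construction) with mostly `is_a` and occasional
  `part_of` edges.
- `make_annotations` samples uniform gene sets per term. Planted
  pathway–process pairs share genes at a target expected Jaccard j: for
  equal set sizes s, the planted overlap is o = round(j·2s/(1+j)), since
  Jaccard = o/(2s−o). Background pairs overlap only by chance
  (expected Jaccard ≈ s/(2|U|−s)).
- Defaults: universe 400 genes, term size 20, planted Jaccard 0.5 —
  a planted pair then has κ ≈ 0.43 while background pairs centre on 0,
  a separation comparable to a top-percentile kappa cutoff on real
  corpora against its corpus mean.
- `make_circuit_scenario` plants an exact OR-group partition by chaining
  DAG edges within groups and none between them; recovery is structural,
  not statistical, so the expected recovery rate is 100%.
- `make_merged_scenario` draws Bernoulli pathway–process (p = 0.3) and
  process–process (p = 0.15) edges over 6 pathways and 15 processes, with
  every pathway guaranteed one neighbour.

What the generators do **not** emulate: realistic GO term-size
distributions (term sizes are constant per corpus), the correlation
between a term's DAG depth and its gene-set size, gene multi-annotation
biases, and database-specific identifier conventions. Passing tests
therefore demonstrate correctness of the algorithms under controlled
overlap structure, not recovery performance on real GO/KEGG/Reactome
releases, whose enrichment output depends on the annotation snapshot.

## Numerical choices

- Fisher/EASE p-values via `hypergeom.sf` (survival function at a−1);
  agreement with factorial brute force is 1e-12 or better on all tables
  with n ≤ 60.
- Kappa in double precision; selection uses exact value comparison with
  id-based tie-breaks downstream, so results are order-free.
- Enrichment output sorted by (EASE, term id); degree tables by
  (−degree, term id); circuit groups lexicographically — every reported
  artifact is byte-reproducible for a fixed config (manifest records a
  config hash).
- Shortest-path counts use Python integers (no overflow for any graph
  size of interest).

## Problem sizes in the acceptance script

The script checks the kappa oracle on 1000 random tables, the Fisher
oracle exhaustively on all 46 375 tables with n ≤ 30 (the test suite
covers n ≤ 60), extraction on 100 random merged networks, circuit
recovery on 200 instances and kappa ranking on 60 replicates — sizes at
which every check completes in seconds while exercising all code paths.

## Known limitations

- Headline counts of any specific historical corpus (numbers of enriched
  terms, edges, or a particular κ cutoff) depend on the annotation
  databases' release and the enrichment backend used at the time; they are
  not reproducible from gene-set files alone and are not targets of this
  package.
- Gene identifiers are normalized by case/whitespace only; mixed
  identifier namespaces must be mapped by the caller before input.
- The OR rule asserts that connected processes are interchangeable for
  pathway activation; that is a modelling assumption inherited from the
  method, not a biological guarantee, and probabilistic weighting of
  groups is out of scope.
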