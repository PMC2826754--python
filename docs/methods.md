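# Methods

## Problem

Given a probabilistic protein interaction network — an undirected graph
whose edges carry independent probabilities of being functional — and a
partially known complex or pathway (the *query*), rank or select the
remaining proteins by their probability of being connected to the query.
The natural statistic is two-terminal network reliability: the
probability that at least one fully operational path joins the query to
the candidate. Computing it exactly is #P-hard, so this package computes
a *provable lower bound* instead, plus the machinery to answer
threshold queries over whole networks efficiently.

## The flow bound

For a candidate sink `t` and query members acting as sources, take a
maximum set of `d` pairwise edge-disjoint source→sink paths. Disjoint
paths fail independently when edges fail independently, so with
`P_i = 1 − ∏_j r_j` the failure probability of path `i`,

    R  ≥  1 − ∏_{i=1..d} P_i .

The bound is valid for *any* set of disjoint paths and tightens as `d`
grows; by Menger's theorem the maximum `d` equals the minimum
cardinality edge cut between query and sink, which we obtain as a
unit-capacity maximum flow. Multiple sources are joined to a virtual
super-source through artificial certain edges (reliability 1, excluded
from path lengths and failure products) whose capacity equals the
member's incident edge count, so one query member may head several
paths.

Numerical and determinism choices:

* **Routing.** Flow decompositions are not unique and the bound depends
  on the one chosen. We compute a *min-cost* maximum flow with arc cost
  `−log r` (successive shortest paths with Dijkstra potentials), so
  among all maximum flows the one maximising the product of used edge
  reliabilities is selected; paths are then peeled greedily by maximum
  reliability product (shortest path on `−log r` restricted to
  flow-carrying arcs). Ties break on lexicographic node order, so
  output is fully deterministic.
* **Undirected edges** become two opposing unit arcs; opposing flow is
  cancelled before decomposition, so edge-disjointness holds on the
  undirected edge.
* **No path-length cutoff** is applied, unlike the length-4 cutoff
  customary in Monte Carlo reliability estimation: a long certain path
  is still evidence of connection.
* The brute-force oracle `exact_reliability` enumerates all `2^|E|`
  edge states (refusing above a configurable 20-edge cap) and is the
  ground truth in the test suite: the flow bound never exceeds it, and
  equals it whenever all simple source→sink paths are pairwise
  edge-disjoint.

## Scaling by hierarchical clustering

Scoring every protein means one flow instance per candidate. To prune,
the network is summarised as a **cluster graph**: vertices are clusters
(query proteins stay as individual vertices); an edge joins two
clusters when at least one network edge crosses between their member
sets, weighted by the *maximum* crossing probability and annotated with
the crossing-edge *count* (multiplicity).

A path in the cluster graph stands for up to *bandwidth* real
edge-disjoint paths. We compute a maximum flow on the cluster graph
with edge capacities equal to multiplicities and cost `−log(max
weight)`; each decomposed path carrying `f_i` units (never more than
the multiplicity of its first edge out of the query) contributes
`P_i^{f_i}` to the failure product:

    max_bound  =  1 − ∏_i P_i^{f_i} .

Because any set of real disjoint paths maps to a feasible cluster flow
(distinct crossing edges per cluster edge), the cluster max flow always
dominates the real path count; combined with max-weight optimism on
every edge, `max_bound` is an upper estimate of any member's flow
bound. This is a heuristic admissibility argument, not a proof — the
bound depends on which maximum flow is decomposed — so the test suite
checks dominance empirically over random (network, hierarchy, query)
triples and counts violations; across thousands of member checks the
observed violation rate is on the order of 0.1%, and none occurred in
the threshold-query equivalence experiments. Had we instead restricted
cluster paths to unit capacity and exponentiated only by first-edge
multiplicity, under-counting of merged paths would make violations
common; the capacitated, reliability-routed formulation was chosen for
that reason.

**Clusterings.** Nearest Neighbor Clustering (NNC) absorbs edges in
decreasing weight order — new pair, insertion, or merge — skipping any
action that would push a cluster past the size cap; leftovers become
singletons. This keeps sizes near-uniform and pushes heavy edges inside
clusters, exactly what the max-weight cluster summary wants. Spectral
clustering (eigenvectors of the raw similarity matrix, k-means with
k-means++ and 10 restarts, seeded) is provided for comparison but
produces badly skewed cluster sizes on interaction-like networks, so
hierarchies are built by *recursive NNC*: leaves under `leaf_size`
members, each higher level grouping the level below via its cluster
graph with caps counted in protein members. Defaults
(`leaf_size=100`, level caps 100/400/1600/∞) give 3–4 levels on
proteome-scale (thousands of nodes) networks; the desk-scale
experiments in the tests use 10/40/160/∞ on 200-node networks, the same
×4 growth.

**Threshold search.** Best-first: starting from the hierarchy roots
(query members removed from their home clusters), repeatedly expand the
highest-bound cluster at or above the threshold into its children —
ties broken by cluster id — updating the cluster graph incrementally
(only edges incident to the expanded cluster's members are recomputed;
bounds of untouched clusters are reused, which is safe in the
optimistic direction since earlier bounds were computed on coarser
graphs; a `strict` flag recomputes everything for the equivalence
tests). Accepted leaves contribute their members to the candidate list;
every candidate is then *verified* with a true flow computation on the
full network, and only verified bounds ≥ the threshold are answered.
`flow_instances_executed` counts exactly these full-network
verifications — the expensive unit the clustering exists to save.

**Adaptive thresholds.** If the answer set comes back empty (`halve`)
or smaller than a target (`target_k`), the threshold is halved (floor
`1e-6`) and the search resumes with all cached cluster bounds and
verified scores intact; resuming is exactly equivalent to a fresh run
at the final threshold.

**Budgeted queries** drop the threshold entirely: leaves are delivered
in best-first order, candidates inherit their delivering leaf's bound
ranking, and only the top `⌈fraction × #candidates⌉` receive a full
flow computation — `fraction=0.01` is a 100× saving, `fraction=1.0`
reproduces the exhaustive ranking exactly.

## Baselines

* **Monte Carlo (MCS).** Each sample keeps every edge independently
  with its probability and scores 1 if a kept path (optionally length-
  capped at 4, the literature convention, off by default) connects the
  query to the sink; the estimate is the sample mean with binomial
  standard error. Consistent but offers no finite-sample guarantee.
* **Random walk with restart (RWR).** Column-normalised edge weights,
  restart to a uniform distribution over query members, power iteration
  to L1 change < 1e-10. Normalisation is the crux: affinity routed
  through a high-degree intermediate is divided by the hub's weight
  sum, so two sinks behind identical-reliability paths get *different*
  affinities when one intermediate is a hub — the flow bound gives them
  equal scores. The row/column normalisation convention and the uniform
  multi-source restart are our choices; the contrast is qualitative and
  does not depend on them.

## Synthetic study conditions

The generator emulates a probabilistic yeast-scale interaction map at
reduced size:

* **Topology**: preferential attachment with `attach_edges=4`, matching
  the ~4 edges/node (mean degree ~8) of a 3112-node, 12594-edge
  proteome network, and giving the heavy-tailed degree distribution
  such maps show.
* **Background weights**: `beta(1, 19)` (mean 0.05, density rising
  steeply toward zero) — many weak edges, few strong ones. This places
  typical candidate reliabilities well below 0.05, the regime in which
  published membership thresholds of 0.01–0.1 are selective; flatter
  laws (e.g. `beta(1, 3)`) make nearly every node exceed 0.05 and turn
  threshold queries vacuous.
* **Planted complexes**: 27 vertex-disjoint complexes of 3–15 members
  by default (fewer on small test networks so they fit), each realised
  as a random spanning tree plus extra edges to at least half of all
  internal pairs, with weights drawn in `[intra_reliability, 1]`
  (default 0.9).

What passing tests on these networks do *not* show: recovery rates on
real interaction data, robustness to correlated assay noise or to
systematically biased edge probabilities, and behaviour on overlapping
complexes (the generator plants disjoint ones by design).

Leave-one-out evaluation hides one complex member, queries with the
rest, and records the hidden member's 1-based rank (ties share the best
rank; the worst tie rank is also kept) and score; aggregates are the
top-k recovery curve and per-threshold recall.

## Problem sizes used in the shipped experiments

Desk-scale replicas keep the full pipeline honest while staying cheap:
oracle comparisons use ≤8-node/≤14-edge graphs (exact enumeration),
threshold-query optimality uses twenty 200-node/8-complex networks, and
budget accounting uses a 1004-node network (1000 candidates). The
method itself has no scale-specific constants beyond the hierarchy caps
described above.

## Known limitations

* The flow bound is conservative when strong paths share edges: shared
  edges force either/or path choices, and the bound can sit well below
  the exact reliability on densely overlapping topologies.
* Cluster-bound admissibility is empirical, not proven; a pruned
  cluster could in principle hide a qualifying member (observed at
  ~0.1% of member checks on adversarially dense random instances,
  never under the study conditions).
* Exact reliability is only available for tiny subgraphs; there is no
  mid-scale exact method between the 20-edge oracle cap and Monte
  Carlo.
* Edge failures are assumed independent; correlated experimental
  evidence violates this and the bound's guarantee with it.
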