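# Methods

## Problem and model

A signalling pathway is modelled as a simple path of exactly *l* proteins
in an undirected PPI network, starting at a membrane protein and ending at
a nuclear protein, with cellular-location ranks non-decreasing along the
way. Path cost is the sum of edge weights w(u, v) = −log max(|r(u, v)|, ε)
with r the Pearson correlation of the incident genes' expression profiles;
the detection problem is therefore minimum-weight constrained simple-path
search, which is NP-hard in general. The method trades exactness per trial
for speed: color-coding restricts each trial to colorful paths, and a
bounded, admissible branch-and-bound enumerates those.

## Expression preprocessing

* **Filtering.** Genes with a missing-value fraction ≥ `max_missing_frac`
  (default 0.2) are dropped; the threshold is strict, so a gene at exactly
  20% is removed.
* **KNN imputation** (default k = 15 neighbours). Distance between genes is
  the *mean* squared difference over mutually observed samples, so genes
  with different overlaps are comparable; a neighbour must itself be
  observed at the sample being filled. Fewer eligible neighbours than k:
  all are used; none: the gene's own observed median. Ties in distance
  break by gene id, making imputation fully deterministic.
  The neighbour mean is unweighted; distance weighting was considered and
  rejected as the default because it adds a bandwidth choice without
  evidence of benefit at these matrix sizes.
* **Over/under calls** compare the summed magnitude of positive versus
  negative log2 ratios (ties → under). A count-majority rule is the
  obvious alternative; magnitude sums were chosen because many small
  fluctuations of one sign should not outvote a few strong responses of
  the other.
* **Correlation** needs ≥ 3 mutually observed samples and nonzero variance;
  anything else raises an undefined-correlation signal that the network
  builder maps to the cap weight — never to r = 0, which would wrongly
  claim evidence of independence.

## Network weighting

Natural logarithm by default (base only rescales all weights uniformly and
cannot change any argmin path; base 10 is available). The floor
ε = 10⁻⁴ keeps weights finite (cap ≈ 9.21) when |r| is tiny or undefined.
Edges whose endpoints lack expression data keep the cap weight rather than
being deleted, preserving connectivity and hence the articulation
structure; a deletion mode exists behind a flag. Default search length and
color count come from the hop diameter of the largest connected component
(unit-weight Dijkstra ≡ BFS), the small-world bound on how many steps
separate any two proteins.

## Topology-aware coloring

Nodes are colored in descending-degree order (ties by node id); each node
of degree ≥ 2 draws uniformly among colors unused by its already-colored
neighbours (uniform over all k when none is free). Two leaf policies:

* `paper_faithful` (default): a leaf copies its single neighbour's color,
  conserving the palette for the interior — at the cost that a path
  *ending* at that leaf cannot be colorful.
* `strict_leaf`: a leaf draws a color different from its neighbour's.

A final pass recolors articulation points that collide with a neighbour,
choosing a color unused in the neighbourhood when one exists. In
`paper_faithful` mode a deliberate leaf copy is not treated as a collision
(otherwise every star hub would immediately undo the leaf rule); the QA
`constraints_report` counts violations under the same convention. With
k larger than an articulation point's degree, a free color always exists,
so its violations are zero — a property the tests assert.

Repetition math: a uniform coloring makes a fixed k-node path colorful
with probability k!/k^k > e^(−k), so t = ⌈ln α / ln(1 − e^(−k))⌉ colorings
bound the failure probability by α (8929 for k = 8, α = 0.05). The
topology-aware scheme only raises the per-trial success probability, so t
remains a valid (conservative) repetition count.

## Bounded search

Depth-first branch-and-bound over colorful, location-monotone simple
paths with f(x) = g(x) + w_min·(l − d), where d is the node count of the
partial path and w_min the global minimum edge weight. Since every edge
costs at least w_min, h never overestimates the completion cost
(admissible) and f is non-decreasing along expansions (consistent; an
internal debug mode asserts this during search). Pruning uses
min(bound, best-so-far) with a *strict* inequality so equal-weight optima
survive for the lexicographic tie-break (smallest node sequence).

* **Pre-traverse depth** d (default 3): bound pruning is disabled for
  prefixes of ≤ d nodes, forcing short prefixes to be explored before the
  bound bites. Infeasibility pruning (target unreachable in the remaining
  steps, by precomputed hop distances) applies at every depth; it can
  never remove a completable path.
* **Bound calibration.** `sample_path_stats` draws n (default 5000)
  self-avoiding random walks of l nodes, restarting on dead ends, and
  pools their edge weights into w_avg and w_STD;
  Bound_Score = (w_avg + α·w_STD)·l with α default 0.5. The factor l (node
  count) is kept as the default even though an l-node path has l − 1
  edges — looser, never unsound; an edge-count mode exists. Stats are
  sampled once per length per run and reused across restarts.
* **Location constraint.** Ranks membrane = 1, cytoplasm = 2, nucleus = 3;
  `intracellular` and unannotated proteins are wildcards compatible with
  any rank (the four printed compartments admit no total order, so the
  wildcard reading was chosen). The monotone check tracks the last
  non-wildcard rank.
* **Restarts.** `search_with_restarts` redraws the coloring
  (k = l colors) with fresh child seeds of one master seed,
  deduplicates results and, once `max_results` paths are held, tightens
  the bound to the worst kept weight. `n_colorings` defaults to
  `required_repetitions(l, 0.05)`.

An existence-only variant (`colorful_path_exists`) answers "is there any
colorful l-path s→t" by dynamic programming over (node, color-set,
location-rank) states — equivalent to the search with an infinite bound
(property-tested against it) but with predictable cost, which is what the
paired coloring-comparison experiments use.

## Evaluation

Precision = |detected ∩ main chain| / |detected|, recall over the main
chain, F = 2pr/(p+r). Percentages print at one decimal and F at two, with
half-up rounding to match benchmark-table convention (9/16 → 56.3%). Path
assembly keeps paths hitting ≥ ⌈|main chain|/2⌉ reference nodes and unions
their nodes and edges. Enrichment is the plain term-by-term upper-tail
hypergeometric test with optional Bonferroni correction; parent–child
models that require the GO DAG are out of scope, and annotation exports
can be scored by external tooling instead.

## Synthetic benchmark generator

The generator emulates the study conditions end to end: a Barabási–Albert
preferential-attachment network (scale-free degree distribution,
`m_attach` = 2 giving mean degree ≈ 4, the sparsity of curated PPI maps); a
planted l-node path with membrane/cytoplasm/nucleus tags whose missing
consecutive edges are added; and an expression matrix (default 200
samples) in which planted genes load on one latent factor with loading
λ = σ·√(r_on/(1 − r_on)), so every planted pair has expected correlation
r_on (default 0.9), while all other genes are independent noise of
matching variance. Missing values are masked uniformly at random. With
r_on = 0.9 the planted edges cost ≈ −log 0.9 ≈ 0.1 while background edges
cost ≫ 1, making the planted path the unique minimum-weight l-path with
high probability — verified exhaustively on small instances.

What the generator does **not** emulate: dye bias, batch effects,
heavy-tailed microarray noise, correlated off-path modules, false-positive
interactions. Passing the recovery tests therefore demonstrates the
search machinery is correct and calibrated, not that real pathways are
always unique weight minima.

## Problem sizes and numerical choices

The test-suite experiments run at desk scale, chosen so that the whole
suite completes in a couple of minutes while keeping every Monte-Carlo
margin comfortable: oracle-equivalence and articulation checks on 100
random graphs of ≤ 12 nodes; planted-path recovery on n = 60, l = 7 over
20 seeded runs with the full default repetition count (3284 colorings);
the paired coloring comparison on n = 300 scale-free graphs with 500
paired colorings for l ∈ {7, 8}; the colorful-probability law at 10,000
trials (asserted within 3 Monte-Carlo standard errors). Absolute success
percentages on real yeast/human networks depend on those networks and are
not reproduced; only the paired ordering (topology-aware ≥ uniform) is
asserted.

All randomness descends from `numpy` `SeedSequence` spawns of one master
seed per entry point; reruns are bit-identical. Floating-point
comparisons in the search use strict inequalities with no tolerance:
ties are resolved lexicographically, and the admissibility argument is
exact, not approximate.

## Known limitations

* Linear chains only; tree-shaped queries and edge-orientation inference
  are out of scope.
* The leaf-copy default makes paths that terminate at a leaf undetectable
  in that coloring; use `strict_leaf` when endpoints may be leaves.
* The bound calibration assumes sampled path weights are roughly normal;
  on networks where most edges sit at the ε cap the distribution is
  bimodal and α should be raised (or the bound set to ∞) to avoid pruning
  sparse high-evidence paths.
* Imputation cost grows with the number of genes carrying missing values
  times matrix size; it is intended for matrices up to tens of thousands
  of genes, not single-cell scale.
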