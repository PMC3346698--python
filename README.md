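# pathcolor

Detection of candidate signalling pathways — minimum-weight simple paths
from a membrane protein to a nuclear protein — in protein–protein
interaction (PPI) networks weighted by gene-expression correlation.

Signal transduction follows linear protein cascades, but finding the best
simple path of a fixed length in a weighted graph is NP-hard. `pathcolor`
combines three ideas to make it practical on genome-scale networks:

1. **Co-expression weighting.** Each interaction (u, v) gets the weight
   w(u, v) = −log max(|r(u, v)|, ε), where r is the Pearson correlation of
   the two genes' (KNN-imputed) log2 expression profiles. Strongly
   co-expressed interactions become cheap, so biologically supported
   cascades are minimum-weight paths.
2. **Topology-aware color-coding.** Nodes get one of k colors and the
   search is restricted to *colorful* paths (all colors distinct), which
   replaces the factorial bookkeeping of simple-path search. Instead of
   coloring uniformly at random, nodes are colored in descending-degree
   order so that hubs and articulation points — which nearly every path in
   a scale-free network must cross — differ from their neighbours, while
   leaves copy their neighbour's color. This raises the per-trial
   probability that a true pathway is colorful above the uniform baseline
   k!/k^k > e^(−k). With t = ⌈ln α / ln(1 − e^(−k))⌉ independent colorings
   the chance of missing a k-node path is below α (t = 8929 for k = 8,
   α = 0.05).
3. **Bounded A\* search.** Colorful paths are enumerated depth-first with
   the evaluation f(x) = g(x) + w_min·(l − d): accumulated weight plus the
   cheapest network edge charged for every remaining step. The heuristic is
   admissible and consistent, so pruning against the calibrated ceiling
   Bound_Score = (w_avg + α·w_STD)·l — estimated from randomly sampled
   simple l-paths — never discards the optimum once the bound covers it.
   Paths must also respect cellular-location monotonicity
   (membrane → cytoplasm → nucleus).

Detected paths are assembled into a subnetwork (keeping paths that hit at
least half of a reference main chain) and scored by precision, recall and
F-measure, with a term-by-term hypergeometric enrichment test for
annotation sets.

## Worked example

Generate a synthetic benchmark — a 60-node scale-free network with a
planted 7-protein membrane-to-nucleus path whose genes share a latent
expression factor (pairwise |r| ≈ 0.9) — then run the full pipeline:

```sh
pathcolor simulate --n 60 --length 7 --seed 42 --out-dir demo/instance
# synthetic instance in demo/instance
#   (planted path: P0042 -> P0050 -> P0052 -> P0021 -> P0005 -> P0047 -> P0054)

cat > demo/run.yaml <<EOF
network: demo/instance/network.tsv
expression: demo/instance/expression.tsv
locations: demo/instance/locations.tsv
reference: demo/instance/planted_path.txt
start: P0042
end: P0054
length: 7
d: 3
alpha: 0.5
seed: 7
n_colorings: 500
stats_samples: 2000
out_dir: demo/run
EOF
pathcolor run --config demo/run.yaml
```

`demo/run/results.tsv` ranks the colorful location-valid 7-node paths by
weight:

```
rank  weight     path
1     0.672511   P0042|P0050|P0052|P0021|P0005|P0047|P0054
2     4.77674    P0042|P0003|P0052|P0021|P0005|P0047|P0054
3     4.804736   P0042|P0003|P0005|P0021|P0052|P0050|P0054
```

The planted path is ranked first: its six co-expressed edges cost 0.67 in
total, while every alternative must use at least one weakly correlated edge
(sampled per-edge weights on this network: mean 3.03, sd 1.43, minimum
0.089 — giving a bound score of (3.03 + 0.5·1.43)·7 ≈ 26.2). Assembling the
paths that hit at least ⌈7/2⌉ = 4 reference proteins and scoring against
the planted main chain (`demo/run/evaluation.json`):

```
recall 100.0% (7/7)   precision 50.0% (7/14)   F 0.67
```

All 7 reference proteins are recovered; the assembly adds 7 neighbouring
proteins, exactly the behaviour the precision/recall trade-off quantifies.
`demo/run/manifest.json` records every seed, parameter and library version
needed to reproduce the run bit-exactly.

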