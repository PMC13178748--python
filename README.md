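# ppinet

Offline analysis of seed-protein interaction networks: build a
high-confidence protein–protein interaction (PPI) graph around a
literature-curated seed panel, rank hub proteins by centrality, detect
functional modules by modularity optimization, and test gene sets for
over-representation — with a ground-truthed synthetic-data generator so
every stage can be validated without touching a web service.

The shipped example panel is an 18-protein cystoid macular edema (CME)
set spanning angiogenesis (VEGFA, ANGPT2, KDR, FLT1, PDGFB),
inflammation (IL6, TNF, CXCL8, CXCL10, CCL2), vascular permeability
(ICAM1, EDN1), hypoxia/oxidative stress (HIF1A, NOS2), matrix
remodeling (MMP2, MMP9) and TGFB1/PTGS2, but the package is agnostic to
the disease context: any seed list plus a STRING-dialect interaction
table works.

## What it computes

**Network.** Interaction records (gene symbol pairs with a combined
confidence score in [0, 1]) are filtered at an inclusive threshold
(default ≥ 0.700), deduplicated keeping the maximum score per pair, and
assembled into a weighted undirected graph; isolated proteins are
pruned and logged.

**Topology** (all from scratch, on the unweighted graph, normalized to
[0, 1]):

- degree centrality `C_D(v) = deg(v) / (n − 1)`
- betweenness `C_B(v) = Σ_{s≠v≠t} σ_st(v)/σ_st / ((n−1)(n−2)/2)`
  via Brandes' accumulation, endpoints excluded
- closeness `C_C(v) = (r/(n−1)) · (r/Σ d(v,u))` over the r nodes
  reachable from v (component-corrected; `(n−1)/Σd` when connected)
- eigenvector centrality: dominant adjacency eigenvector by power
  iteration, Euclidean norm 1
- local clustering `c_v = 2·Δ(v)/(deg(v)(deg(v)−1))`

plus global density, mean clustering, and diameter / mean shortest path
on the largest connected component.

**Communities.** From-scratch Louvain maximization of modularity

    Q = Σ_c [ W_c/W − γ (S_c/2W)² ]

(weighted by the combined scores by default, resolution γ = 1, seeded
node-visit order for exact reproducibility).

**Enrichment.** Local over-representation analysis against GMT
libraries: one-sided hypergeometric tail `P(X ≥ k)`,
`X ~ Hypergeom(N, K, n)`, summed in log-space, with Benjamini–Hochberg
adjustment across each library and significance at adjusted p < 0.05.

**Synthetic benchmarks.** A stochastic block model with planted
modules, planted hub nodes and spiked gene sets emits the same file
dialects the readers consume, together with a ground-truth manifest, so
module recovery (adjusted Rand index), hub ranking and enrichment
ranking can be scored exactly.

## Worked example

Generate a ground-truthed bundle and run the full pipeline on it:

```
$ ppinet simulate --seed 1 --out demo/bundle
bundle in demo/bundle: 90 nodes, 217 edges, seeds=G002,G017,...,G089

$ ppinet run --seed-list demo/bundle/seeds.txt \
             --interactions demo/bundle/interactions.tsv \
             --gmt demo/bundle/library.gmt --out demo/out
wrote 8 artifacts to demo/out
network: 89 nodes, 217 edges, 8 communities (Q=0.6605)
```

The bundle plants 8 modules over 90 proteins with ~217 high-confidence
edges and an 18-protein seed panel. One planted node had no sampled
edge and is pruned as an isolate, leaving 89 nodes. The run directory
contains, among others:

```
$ head -5 demo/out/global_metrics.txt
n_nodes=89
n_edges=217
density=0.05541368743615935
avg_clustering=0.24425879987677745
diameter_lcc=7

$ head -3 demo/out/hub_summary.txt
Top 5 by Degree Centrality
  G049: 0.1250
  G011: 0.1023
```

`G049` is one of the planted hubs; the Louvain partition recovers the
8 planted modules (adjusted Rand index 0.98 against the manifest), and
the enrichment report flags the module-spiked gene sets as significant
(e.g. `GS000  10/40  p_adj=3.1e-02`) while decoy sets stay at p ≈ 1.

The same `run` subcommand accepts a real seed list and a cached STRING
flat file (`--score-scale per_mille` for 0–999 scores); a live STRING
REST provider is available programmatically when the `requests`
package is installed.

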