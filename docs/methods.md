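# Methods

## Scope and model

`ppinet` analyzes a confidence-weighted, undirected protein–protein
interaction graph built around a seed-gene panel. The unit of input is
an interaction record: an unordered pair of HGNC-style gene symbols
with a combined confidence score in [0, 1]. Symbols are uppercased at
parse time and taken as given (no identifier-mapping service); scores
arriving on the 0–999 flat-file scale are converted only when the
caller explicitly declares `score_scale="per_mille"` — the scale is
never guessed, because a unit/per-mille confusion silently empties a
network after thresholding.

The analysis graph keeps one edge per unordered pair at the maximum
observed score (interaction tables commonly emit each pair once per
direction; the maximum is the lossless reduction for a symmetric
confidence). Records are filtered at an inclusive threshold, default
0.700, the conventional "high confidence" cut. Isolated proteins are
pruned by default and recorded in the run log; a flag retains them for
benchmarks that need isolates.

## Topological metrics

All centralities and path statistics are computed on the **unweighted**
graph. The scores express confidence, not proximity, and the reported
[0, 1]-normalized conventions are the hop-count ones; weights are kept
for community detection and provenance only.

- **Degree centrality**: deg(v)/(n−1).
- **Betweenness**: Brandes' single-source accumulation over unweighted
  shortest paths, endpoints excluded, divided by (n−1)(n−2)/2 (the
  number of unordered pairs a vertex can mediate). Graphs with n ≤ 2
  report zeros.
- **Closeness**: the component-corrected (Wasserman–Faust) form
  (r/(n−1))·(r/S), with r the number of nodes reachable from v and S
  their total hop distance; this reduces to (n−1)/S on connected graphs
  and is 0 for isolates. The correction matters only on disconnected
  inputs, which a pruned high-confidence pull can produce.
- **Eigenvector centrality**: dominant eigenvector of the unweighted
  adjacency, Euclidean norm 1 over all nodes. It is found by power
  iteration on A + I rather than A: the identity shift leaves the
  eigenvectors unchanged while preventing the period-2 oscillation pure
  A-iteration exhibits on bipartite graphs (stars, paths), which
  otherwise never converges. Defaults: uniform start, tolerance 1e-6 on
  the maximum per-node change between iterates, 1000 iterations, then a
  convergence error reporting the residual. The stopping rule measures
  successive change, which on slowly-mixing graphs understates the true
  error by roughly 1/(1−ρ) (ρ the eigenvalue ratio); verification tests
  that compare against closed forms therefore run the solver at 1e-10.
  On disconnected graphs the component with the largest spectral radius
  dominates and other components decay toward zero — documented
  behavior, not an error.
- **Local clustering**: 2·Δ(v)/(deg(v)(deg(v)−1)), 0 for degree < 2.
- **Global metrics**: density 2E/(n(n−1)) and mean clustering over the
  whole graph; diameter and mean shortest path (mean over unordered
  reachable pairs) over the largest connected component only. A
  size-1 largest component reports the path metrics as undefined
  (`None`), never zero. Component ties break to the component holding
  the lexicographically smallest node.

Ranking (`top_k`) sorts descending with lexicographic tie-breaks and
never rounds before ranking; the hub tables render values to 4 decimals
at presentation only.

## Community detection

Modularity at resolution γ is evaluated as
Q = Σ_c [W_c/W − γ(S_c/2W)²] with W the total edge weight, W_c the
intra-community weight and S_c the summed strength — algebraically the
usual double sum Σ_ij (A_ij − γ k_i k_j/2W) δ(c_i,c_j) / 2W, which is
exactly what the test oracle computes.

The Louvain optimizer is written from first principles: phase 1 moves
single nodes to the adjacent community with the largest positive gain
ΔQ = w_{i→c}/W − γ S_c k_i / (2W²) (computed incrementally after
removing i; verified against from-scratch recomputation on every
accepted move in a test harness), sweeping until no move improves Q;
phase 2 aggregates communities into super-nodes whose self-loops carry
the intra-community weight, and the two phases repeat until an
aggregation pass changes nothing. Design choices where the algorithm
is genuinely underdetermined:

- node-visit order is shuffled each sweep from an explicit seed
  (default 42, logged in every report), because Louvain output is
  order-dependent; identical seed + input is bitwise reproducible;
- equal-gain ties go to the lowest community id;
- final labels are contiguous integers ordered by first appearance over
  the lexicographically sorted node list;
- edges are weighted by the combined scores by default (the graph is
  confidence-weighted, and the reference implementations of this
  algorithm consume weights); `weighted=False` reproduces the
  unweighted variant;
- γ defaults to 1.0.

## Over-representation analysis

Each gene set is scored with the one-sided hypergeometric upper tail
P(X ≥ k), X ~ Hypergeom(N, K, n), after intersecting both the query and
the set with the universe. The tail is a direct sum of point masses in
log-space (lgamma-based log-binomials + scaled exponential sum), stable
at interactome-scale universes (N ~ 20,000) and validated against a
rational-arithmetic oracle for all parameter tuples with N ≤ 25.
Depletion is deliberately not tested.

The universe is an explicit input: a gene-list file or the keyword
`union` (union of the library's genes — the default, and the logged
choice). Benjamini–Hochberg runs across **all** sets of one library,
including zero-overlap sets, so the FDR family matches the report;
libraries are adjusted independently. The step-up is computed as a
running minimum over the descending order statistics of p·m/rank (the
rank-m entry taken as p itself, which is the same number but bit-exact
in floats). Results sort by (adjusted p, raw p, term name); the
significance flag is strict adjusted p < α, default α = 0.05. Ranking
is by adjusted p only — no composite ranking statistic.

## Synthetic data generator

The generator plants exactly the structures the pipeline claims to
detect, so every stage can be scored against ground truth offline:

- **Graph**: a stochastic block model — every intra-module pair is an
  edge with probability `p_in`, every inter-module pair with `p_out`
  (< p_in); designated hub nodes then receive `hub_extra_degree`
  uniformly chosen extra partners; scores are uniform on
  [`score_low`, `score_high`], above the 0.700 threshold by default.
- **Library**: one spiked set per module (`planted_set_overlap` module
  members plus out-of-module fillers to `decoy_set_size` — fillers are
  drawn outside the module so the planted overlap is exact) hidden
  among `decoy_set_count` uniform decoy sets. Set names are a uniform
  `GS###` sequence; only the ground-truth manifest knows which are
  planted.
- **Seed panel**: the hub nodes plus one random non-hub member per
  module.

The default specification mirrors a small seed-protein interactome
study: 8 modules of 9–14 proteins (90 nodes), p_in = 0.36,
p_out = 0.005, 10 hubs with 3 extra edges each — about 220 expected
high-confidence edges — and an 18-protein seed panel. A named preset,
`SyntheticSpec.planted_partition_benchmark()` (4 modules × 15 nodes,
p_in = 0.30, p_out = 0.01, no hubs), is the community-recovery
calibration benchmark. All randomness flows from one seeded NumPy
stream with a documented draw order (intra edges, inter edges, hubs,
scores, library, seed panel), so a (spec, seed) pair reproduces
byte-identical bundles.

What the generator does **not** emulate: degree-corrected block
structure, realistic score distributions (real combined scores are
heavily right-skewed, not uniform), overlapping modules, study-bias
hubs, or annotation redundancy between gene sets. Passing tests
demonstrate that the algorithms recover planted structure under their
own statistical assumptions — not that any particular biological
conclusion from a real interactome is correct.

## Pipeline and determinism

The pipeline is a fixed stage order — seeds → interaction source →
score filter → graph build → topology → communities → enrichment →
writers — driven by a flat declarative config (YAML) with CLI
overrides (precedence CLI > file > defaults). Every output table is
sorted (nodes lexicographically, enrichment by adjusted p) and floats
are printed with `repr`, so identical config + inputs give
byte-identical artifacts. The `Network` container canonicalizes edge
and adjacency storage order at construction, which makes every float
accumulation independent of input row order; consequently all analysis
artifacts are invariant under permutations of the interaction table.
The run log records every parameter, the SHA-256 of every input file,
the Louvain seed and a reconstruction of the equivalent CLI command; it
deliberately contains no timestamps. Input checksums are the one thing
that legitimately changes when the input file is reordered, so
permutation-invariance checks compare the log modulo its checksum
lines.

Stage errors propagate wrapped with the stage name. Config validation
runs before any I/O. An empty post-filter network produces a diagnostic
naming the threshold. Seeds absent from the interaction source are kept
in the seed list and reported in the log, not treated as errors.

## Verification strategy and problem sizes

The published statistics this kind of study prints depend on a live
database snapshot that is not deposited, so verification is
property-based, at sizes chosen to keep the full suite under a minute:

- centralities vs brute-force path-enumeration and dense
  eigendecomposition oracles on 30 random connected graphs (n ≤ 8), and
  exact rational closed forms on stars, paths, cycles and complete
  graphs (n = 3–7);
- modularity vs the direct double sum on 40 random weighted
  (graph, partition) pairs; Louvain vs exhaustive search over all 4,140
  partitions of the two-cliques-plus-bridge graph;
- planted-partition recovery on the 4×15 benchmark: adjusted Rand
  index ≥ 0.9 at the reference seed and in the median over 20 seeds;
- hypergeometric tail vs the rational oracle (all tuples, N ≤ 25), BH
  vs the literal step-up definition on 1,000 random vectors, and a null
  calibration: 10,000 uniform (query, decoy-set) draws at
  N = 20,000, K = 5,000, n = 2,000 must give P(p ≤ 0.05) within 3
  binomial standard errors of 0.05. These null parameters are chosen so
  the discrete p-value grid near the 0.05 quantile is finer than the
  acceptance band (pmf step ≈ 0.006), since the calibration identity
  only holds for an approximately continuous test statistic;
- end-to-end: byte-identical reruns, permutation invariance, planted
  module/hub/enrichment recovery on the default bundle.

## Known limitations

- Path-based metrics ignore edge weights by design; there is no
  weighted-shortest-path or harmonic centrality.
- Louvain is greedy: global optimality is only guaranteed (and only
  checked) on small instances; no Leiden refinement, consensus
  clustering, or hierarchical output.
- The ORA universe defaults to the union of library genes, which is the
  common web-service convention but biases p-values when the library
  covers the genome unevenly; supply an explicit background for real
  analyses.
- The live STRING provider is a thin optional client (requires the
  `requests` package) and is intentionally untested offline; cached
  files are the supported reproducible path.
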