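# Methods

This note documents the models, conventions and numerical choices behind
`metacentrality`, in the order the pipeline runs them.

## Network model and I/O

All computation assumes an undirected, connected graph with strictly
positive, finite edge weights and no self-loops; `WeightedNetwork`
enforces this once at construction. Two deliberate I/O policies:

* **Duplicate undirected edges are an error**, not summed. Silent
  aggregation would change the maximum weight w_M and hence every
  transmission probability downstream; failing loudly is safer.
* **Disconnected input is reduced to its largest connected component**
  with a logged warning counting the dropped nodes. The theory requires a
  connected graph, but real edge lists are frequently messy, and dropping
  satellite components is the conventional cleanup.

Node identifiers are opaque strings; every tie-break in the package
(ranking order within tied scores, component selection, cluster merge
order) is lexicographic in these ids, which makes all outputs
byte-reproducible.

## Centrality measures

Degree and k-shell are unweighted by design — they contribute purely
topological opinions to the aggregation. The weighted conventions are:

* **Closeness** uses edge length 1/w (weight read as connection
  strength), score (n−1)/Σ_j d(i,j). This is the standard convention when
  heavier edges mean closer nodes.
* **Eigenvector** is the principal eigenvector of the weight matrix W,
  non-negative, unit Euclidean norm (power iteration, tol 1e−10, max
  1000 iterations).
* **PageRank** uses damping 0.85, tol 1e−10, max 1000 iterations; scores
  sum to 1.
* **Weighted k-shell** prunes on the composite degree
  k′_i = round(√(k_i·s_i)) with k_i the residual degree and s_i the
  residual strength, both recomputed after every removal cascade; a node
  removed while the pruning threshold is k gets shell index k. Rounding is
  half-up (not banker's) so k′ is stable across platforms. On unit-weight
  graphs k′ = k and the result equals the plain k-shell.
* **Expected force** enumerates every ordered sequence of exactly two
  transmission events from the seed; each resulting 3-node cluster is
  weighted by its outgoing force (total edge weight from cluster to
  susceptible nodes), counted once per sequence (so clusters reachable by
  several orders count with multiplicity); the score is the Shannon
  entropy (natural log) of the normalized force distribution. Networks
  with fewer than 4 nodes are rejected: every 2-event cluster would cover
  the graph with zero outgoing force. The 2-event weighted setting is the
  cited method's canonical configuration; the package's enumeration
  oracle in the test suite pins this exact definition.

Rankings use the average-position tie convention (tied scores share the
mean of the spanned positions, positions sum to n(n+1)/2), matching the
tie-aware Spearman correlation used in aggregation.

## Spreading simulation

Discrete-time, synchronous updates against the pre-step infected set. The
per-step infection probability of susceptible node i is

    p_i(t) = 1 − Π_{j ∈ N_i(t)} (1 − (w_ij / w_M)^α)

i.e. independent Bernoulli transmission channels with success probability
equal to the α-th power of the relative edge weight. α defaults to 1,
binding spreading entirely to the weights — larger α only compresses the
dynamic range of per-node outcomes without changing their comparison,
which is why 1 is the ground-truth setting.

Conventions that the hand-checkable deterministic limit pins down (all
weights equal ⇒ every channel fires with probability 1 ⇒ the epidemic is
a BFS wave):

* the t = 0 ratio (always 1/n, seed-independent) is **not** recorded;
  recording starts after the first step, so the 3-path gives exactly 1.0
  (middle seed) and mean(2/3, 1) = 5/6 (end seed);
* the spreading-power index is the mean over runs of the mean per-step
  infection ratio until full coverage (100 runs by default);
* SIR adds recovery: the pre-step infected set transmits, then each of
  those transmitters recovers with probability `recovery_prob`
  (absorbing). The index is the mean final recovered count.
  `recovery_prob = 0` is rejected (it silently degenerates to SI with an
  identically-zero index); the experiments default to 0.8 when SIR is
  requested.

RNG streams are keyed by (master seed, seed-node index, run index), so
the ground-truth table is independent of evaluation order and exactly
reproducible. The update is implemented incrementally — each susceptible
node carries its cumulative log-survival against the infected set,
updated only for newly infected neighbours — so one run costs
O(n · coverage) vectorized work; a 300-node, 100-runs-per-seed ground
truth over all seeds completes in well under a minute on one CPU. A step
cap of 10^6 guards against pathological configurations.

## Aggregation

The correlation matrix is tie-aware Spearman (Pearson on the
average-position vectors); negative entries are clipped to 0 (disagreement
is treated like non-correlation), the diagonal is 1, and a fully tied
ranking (zero rank variance) is treated as uncorrelated with everything.

Slicing anchors every subset at its own row (i ∈ h_i, l_i, hl_i). The
candidate pool spans all rows and all three categories; duplicates by
member set are kept because the entropy depends on the anchor row. The
entropy uses the natural log and the 1/|x| scaling, which biases the
selection toward smaller subsets. Ties in entropy are broken toward
smaller cardinality, then smaller anchor row, then category order
H < HL < L — the first two mirror the "fewer rankings preferred"
rationale, the last is pure determinism. Defaults t_b = 0.8, t_s = 0.3
are the published general-purpose setting; they are parameters of
`AggregationParams`, not constants.

Borda scores are B(z) = Σ_t (|C| − pos_t(z)) with tie-averaged positions;
the descending reorder of B (standard tie policy) is the aggregated
ranking. A1 comes from the highest-entropy subset and is the headline
predictor; A2 (second-highest) is reported alongside. The `meta_centrality`
entry point needs only the network: the aggregation itself never touches
simulation.

## Evaluation

Recognition rate at fraction f uses top-k sets with k = ceil(f·n) — ceil
guarantees non-empty sets at small f (the convention is a package choice;
floor or round would differ only at very small n·f). Boundary ties are
resolved by the rankings' deterministic within-tie order (lexicographic
node id); with many tied scores this makes the reported rate one specific
member of the family of rates a different tie order would produce. The f
grid defaults to {0.05, 0.10, 0.15, 0.20, 0.25, 0.50}; summaries report
mean, population std, min, quartiles, max over the grid, plus the
percentage rise of the aggregate's mean over the best single predictor.

## Spectrum pipeline

The symmetric normalized Laplacian is built from the weight matrix;
eigenvalues come from a dense symmetric solver (capped at n = 3000 —
beyond that an error points to iterative strategies, which are out of
scope), are clamped to [0, 2] within 1e−9 and rejected outside that
tolerance. Histograms use 200 bins of width 0.01, the last bin closed so
an eigenvalue of exactly 2 (bipartite graphs) is counted; mass is
normalized to 1 **before** EMD so collections of different sizes are
comparable — with raw counts the distance would be dominated by network
size. EMD is reported in bin units; pairwise matrices are optionally
normalized by their maximum (the heat-map convention, default on).
Clustering is scipy complete linkage on the condensed matrix with input
rows sorted by name for deterministic merge order.

## Synthetic fixtures

The generators exist so every stage is testable without external data:

* deterministic named graphs (path, star, cycle, complete, complete
  bipartite) with closed-form centralities and spectra; the unit-weight
  path doubles as the deterministic SI fixture (every edge attains w_M);
* `community` — planted-partition (stochastic block model) graphs,
  default 3 blocks; eigenvalue mass near 0;
* `bipartite_like` — random bipartite graphs plus ~3% within-side noise
  edges, keeping ≥95% of edges across the planted bipartition; mass near 2;
* `motif_duplication` — grown from a small clique by repeatedly
  duplicating a random node, copying its edges with weights perturbed
  multiplicatively by uniform [0.9, 1.1] (exact duplication would create
  degenerate eigenvalue multiplicities); mass near 1;
* `er_weighted`, `ba_weighted` — unstructured baselines.

Random weights default to uniform [0.1, 1.0]: wide enough that w/w_M
spreads transmission probabilities over a useful range. Connectivity is
enforced by bounded resampling with a perturbed substream. These fixtures
emulate spectral and community structure, not the degree heterogeneity,
clustering spectra or weight distributions of real co-authorship,
transportation or neural networks — green tests demonstrate correctness
of the machinery and qualitative separation of the planted families, not
performance claims about any real dataset.

## Experiment scales

The bundled experiments run at the scale of a small biological network
(~300 nodes, 100 simulation runs per seed, the full eight-measure set),
which a laptop CPU completes in seconds to minutes; the same code path
handles larger inputs up to the dense-eigensolver cap. The
planted-community experiment reported by `scripts/acceptance.py` uses
3 blocks, p_in = 0.1, p_out = 0.005 — sparse enough that spreading power
varies meaningfully across nodes, dense enough to stay connected.

## Known limitations

* The weighted-centrality conventions (closeness length 1/w, composite
  weighted shell, 2-event weighted expected force) are the standard
  published forms; other weighted variants exist and would change the
  input rankings.
* Recognition rates on rankings with many tied scores depend on the
  deterministic tie order; a different tie-breaking convention can move
  the rate at a tie-crossing boundary.
* Directed graphs, multigraphs, continuous-time (Gillespie) dynamics and
  approximate closeness for very large networks are out of scope.
* Entropy-based subset selection assumes at least two input rankings and
  degenerates gracefully (to a single ranking) when every candidate
  subset is a singleton.
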