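# metacentrality

Super-spreader identification on weighted networks by **meta-centrality**:
an entropy-guided, correlation-aware modification of Borda-count rank
aggregation, validated against ground-truth spreading power from weighted
SI/SIR epidemic simulation, with Laplacian-spectrum characterization of
network collections.

It is written for network epidemiologists and computational social
scientists who need to rank the nodes of an undirected, connected,
positively weighted graph `G(V, E)` by how far an epidemic seeded at each
node would spread — and who know that no single centrality measure is a
reliable predictor across network types.

## The method

**Inputs.** Eight node rankings from standard centrality measures: degree
`C_D`, strength `C_S`, weighted closeness `C_C` (edge length `1/w`),
eigenvector `C_E`, weighted PageRank `C_P`, k-shell `C_K`, weighted
k-shell `C_KW` (composite degree `round(√(k·s))`), and expected force
`C_EX` (entropy of the normalized outgoing force over all 2-event
transmission clusters). Degree and k-shell are kept unweighted on purpose,
as purely topological opinions.

**Aggregation.** Treating each ranking τ_t as an expert, the classic Borda
score of node z is B(z) = Σ_t (|C| − pos_t(z)); nodes are reordered by
descending B. The modification selects *which* experts vote:

1. *Correlate* — M = [m_ij], the Spearman correlation between rankings,
   negatives clipped to 0.
2. *Slice* — per row i: h_i = {i} ∪ {j : m_ij ≥ t_b},
   l_i = {i} ∪ {j : m_ij ≤ t_s}, hl_i = h_i ∪ l_i, with defaults
   t_b = 0.8, t_s = 0.3. Strong agreement and clear disagreement are both
   informative; half-agreed experts are dropped.
3. *Select* — each candidate subset x is scored by
   E(x) = −(1/|x|) Σ_{j∈x} p_j ln p_j with p_j = m_ij / Σ_{k∈x} m_ik;
   the two highest-entropy subsets are kept.
4. *Aggregate* — Borda over each selected subset gives the meta-rankings
   **A1** (headline) and **A2**.

**Ground truth.** Discrete-time weighted SI: a susceptible node i with
infected neighbours N_i(t) is infected with probability
`1 − Π_{j∈N_i(t)} (1 − (w_ij/w_M)^α)` (α = 1 by default, w_M the largest
weight). The spreading power of a seed is the mean over 100 runs of the
mean per-step infection ratio until full coverage; an SIR variant uses the
mean final recovered count. Predictors are scored by the **recognition
rate** |I_f ∩ S_f| / |I_f| — the overlap of the top f fraction of the
ground-truth and predictor rankings — over f ∈ {0.05, 0.10, 0.15, 0.20,
0.25, 0.50}.

**Spectrum characterization.** The normalized Laplacian
`L = I − D^{−1/2} W D^{−1/2}` has eigenvalues in [0, 2]: mass near 0
signals communities, near 1 motif duplication, near 2 bipartiteness. Each
spectrum is binned into 200 unit-mass bins; the Earth Mover's distance
between two spectra is the L1 distance between cumulative histograms, and
complete-linkage clustering of the pairwise EMD matrix groups networks by
spectral shape.

## Worked example

```python
from metacentrality import (FixtureSpec, SimulationConfig, compute_rankings,
                            evaluate, ground_truth_ranking,
                            make_random_network, meta_centrality)

net = make_random_network(FixtureSpec("community", 120, seed=7,
                                      params={"blocks": 3, "p_in": 0.15, "p_out": 0.01}))
truth = ground_truth_ranking(net, SimulationConfig(alpha=1.0, n_runs=100, seed=7))
agg = meta_centrality(net)                       # A1, A2 + provenance
predictors = dict(compute_rankings(net), A1=agg.a1, A2=agg.a2)
print(evaluate(truth.ranking, predictors, aggregated=("A1", "A2")).summary["mean"])
```

which prints (mean recognition rate over the f grid):

```
C_D     0.5171
C_S     0.6083
C_C     0.5921
C_E     0.1662
C_P     0.5898
C_K     0.1565
C_KW    0.1139
C_EX    0.6014
A1      0.6139
A2      0.6139
```

A1 recovers 61.4% of the true top-f super-spreaders on average — above
every single measure and well above the median single-measure mean
(0.554). The `examples/` directory holds four short narrative scripts
(centralities, spreading ground truth, meta-centrality, spectrum
clustering); `metacentrality --help` exposes the same stages as a CLI.

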