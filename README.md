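# spontnet

Network analysis of spontaneous neural activity recorded longitudinally with
two-photon calcium imaging.

When the same population of cortical cells is imaged repeatedly over days to
weeks, three questions arise naturally: how is the cell-to-cell correlation
structure organized within a session, how quickly does that organization
reorganize from day to day, and is there a subset of cells whose coupling
survives the reorganization?  `spontnet` implements an end-to-end pipeline
for all three, aimed at systems neuroscientists working with tracked-ROI
fluorescence traces (and, via its synthetic generator, at methodologists who
want ground truth to validate against).

## The methods

**Network reconstruction.**  For cells *i*, *j* with fluorescence traces
*x<sub>i</sub>(t)*, edges are Pearson correlations of the *differenced*
series (differencing reduces serial autocorrelation, making the stationarity
assumption of the correlation tenable).  Significance comes from a jitter
null: each cell's trace is independently offset by a random start index
*p* ∈ {0, …, 60} (two seconds at 30 Hz) and truncated to length *T* − 2*p*,
destroying fine temporal alignment while preserving marginal statistics.
Over 1000 repetitions this yields an empirical two-sided p-value and a
jitter z-score per pair: the binary adjacency **A** (*p* < 0.05) feeds the
module and core-periphery analyses, the signed z-scored matrix **W** feeds
the similarity analyses.

**Hierarchical modules.**  Partitions maximize the modularity

&nbsp;&nbsp;&nbsp;&nbsp;*Q*(γ) = Σ<sub>ij</sub> [*A<sub>ij</sub>* − γ
*k<sub>i</sub>k<sub>j</sub>*/2*m*] δ(*g<sub>i</sub>*, *g<sub>j</sub>*),

by a generalized Louvain scheme, with multi-scale structure found
recursively: the coarsest resolution γ that splits a (sub)network defines a
level, a split is retained only if its *Q* beats the 95th percentile of
degree-preserving rewired graphs, and detection recurses inside each
module.  Spatial compactness of every module is scored as a z-score of the
mean nearest-same-module-neighbor distance against position permutations.

**Similarity decay.**  For each session pair the shared cells are
identified, the two matrices (correlation **W** or module co-assignment
**C**) are restricted to them, their upper triangles are correlated
(*r<sub>uv</sub>*), and *r<sub>uv</sub>* is standardized against a
Mantel-style null permuting rows and columns of one matrix.  Correlating
the resulting *z<sub>uv</sub>* with the day distance *d<sub>uv</sub>*
quantifies the decay of network organization over time.

**Multilayer dynamics and flexibility.**  Sessions become layers of a
multilayer network coupled by an inter-layer parameter ω; multilayer
modularity *Q*(γ, ω) (per-layer degree null, ordinal coupling) is maximized
over a bounded {γ, ω} region where structure is non-trivial, and each
node's flexibility *f<sub>i</sub>* — the fraction of adjacent-layer
transitions that change its module — is rank-averaged over 10000 sampled
parameter pairs.

**Temporal core-periphery.**  The consistency matrix *G<sub>ij</sub>*
(fraction of sessions in which an edge is present) is fit with a sigmoidal
coreness template *C\*<sub>m</sub>* = 1/(1 + e<sup>−(m−βN)·tan(πα/2)</sup>),
assigned to nodes by simulated annealing (10 restarts) to maximize the core
quality *R* = Σ<sub>ij</sub> *G<sub>ij</sub>C<sub>i</sub>C<sub>j</sub>*; a
31 × 31 grid over (α, β) with an entry-shuffle permutation null locates
parameter regions with genuine persistent cores.

## Worked example

```python
import numpy as np
import spontnet as sn

# a two-week study: 5 sessions, 100 tracked cells, five modules,
# a 20% persistent core, periphery drifting between modules
cfg = sn.SyntheticConfig(
    n_cells=100, n_sessions=5, day_offsets=(0, 3, 7, 10, 14),
    n_frames=1500, hierarchy_branching=(5,), signal_strength_per_level=(1.0,),
    noise_sd=0.8, dropout_prob=0.05, drift_prob_per_day=0.25,
    core_fraction=0.2, seed=0,
)
sessions, truth = sn.generate_study(cfg)

rng = np.random.default_rng(1)
nets = [sn.build_network(s, n_jitter=200, rng=rng) for s in sessions]
print("significant edges, session 1:", int(nets[0].A.sum() // 2))

mats = sn.session_matrices_from_networks(nets)
pairs = sn.pairwise_similarity(mats, n_perm=1000, rng=rng)
r, table = sn.decay_analysis(pairs)
print(f"decay of similarity with day distance: r = {r:.2f}")

ml = sn.build_multilayer(nets)
bounds = sn.estimate_parameter_bounds(ml, rng=rng, gamma_limits=(0.3, 3.0),
                                      omega_limits=(0.0, 2.0))
prof = sn.sample_flexibility(ml, n_samples=200, rng=rng, bounds=bounds)

cm = sn.consistency_matrix(ml)
core = sn.anneal_coreness(cm, alpha=0.5, beta=0.8, rng=rng)
print("cells in the detected core (midpoint rule):",
      int(core.core_mask("midpoint").sum()), "of", ml.n_nodes)
rho, p = sn.flexibility_vs_coreness(prof, core)
print(f"flexibility vs coreness: Spearman rho = {rho:.2f} (p = {p:.1e})")
top = core.core_mask("top20")
planted = truth.core_mask[ml.node_ids]
print("overlap of top-coreness cells with the planted core: "
      f"{(top & planted).sum()}/{min(top.sum(), planted.sum())}")
```

Output (~100 s on one CPU):

```
significant edges, session 1: 787
decay of similarity with day distance: r = -0.81
cells in the detected core (midpoint rule): 16 of 78
flexibility vs coreness: Spearman rho = -0.40 (p = 2.5e-04)
overlap of top-coreness cells with the planted core: 14/14
```

Reading it: pairwise correlation structure becomes less similar the further
apart two sessions are (negative decay correlation); the sigmoid-midpoint
core comprises ~20% of the cells tracked through all five sessions; cells
with high coreness are exactly the planted stable assembly and have low
flexibility — a stable temporal core inside a reorganizing periphery.

A command-line interface mirrors these stages
(`spontnet simulate / reconstruct / modules / similarity / multilayer /
coreperiphery`); see `spontnet --help`.

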