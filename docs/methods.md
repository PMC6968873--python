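# Methods

This note documents the models implemented in `spontnet`, the assumptions
they rest on, the design of the synthetic-data generator used to validate
them, and every numerical choice a careful user might want to audit.

## 1. Network reconstruction

For each session, traces are first differenced
(x₂ − x₁, …, x_T − x_{T−1}); differencing suppresses the strong serial
autocorrelation of calcium indicators and brings the series closer to the
stationarity that Pearson correlation assumes.  The raw edge weight between
two cells is the Pearson correlation of their differenced traces.

**Jitter null.**  Each repetition draws, independently per cell, an offset
p uniform on {0, …, max_offset} (max_offset = 2 s × sampling rate, 60
frames at 30 Hz), keeps the T − 2p samples starting at p, differences, and
recomputes all pairwise correlations.  The per-pair statistics over
n_jitter = 1000 repetitions give

* P_ij = (1 + #{|r_jitter| ≥ |r_obs|}) / (1 + n_jitter) — two-sided on |r|,
  because the signed matrix treats anticorrelations as meaningful, with a
  +1 pseudocount so p is never zero with finite surrogates;
* W_ij = (r_obs − mean r_jitter) / sd r_jitter — the signed z-scored weight;
* A_ij = 1[P_ij < α], α = 0.05 — the sparse binary adjacency.

Numerical choices:

* Within a repetition, all cells' surrogates are truncated to the common
  minimum length before one vectorized correlation pass.  A pair's own
  overlap could be up to ~120 frames longer out of thousands; the common
  subset is still an exact Pearson estimate and keeps the null exchangeable,
  at a ~50× speedup.
* Surrogates are slightly shorter than the original series, so the null
  correlation is marginally more variable than the observed one; the test
  is therefore conservative by a percent or two at the trace lengths used
  here (the calibration checks in the test suite quantify this).
* Because equal offsets for the two cells of a pair reproduce the observed
  alignment exactly, a pair's p-value has an effective floor near
  1/(2·(max_offset+1)) rather than 1/(n_jitter+1); this is a property of
  the jitter design, not a defect, and is far below α.
* Cells whose differenced trace has zero variance are flagged: their
  entries are NaN, their rows of A are zero, and they are excluded from all
  downstream intersections.
* Binary A feeds module/core detection; signed W feeds similarity — the
  pipeline never mixes the two roles.

Pearson correlation of differenced traces is invariant to per-cell affine
rescaling, so arbitrary fluorescence units (raw, ΔF/F, …) give identical
networks; a test pins this exactly.

## 2. Modularity and the multi-scale hierarchy

Modularity is evaluated exactly as

    Q(γ) = Σ_ij [A_ij − γ k_i k_j / 2m] δ(g_i, g_j)

over all ordered pairs **including i = j** (A_ii = 0) and **without** the
conventional 1/2m prefactor.  Positive rescaling never moves the argmax,
and the i = j convention makes the one-module partition score exactly 0 at
γ = 1 — an identity the tests assert.

Maximization is a generalized Louvain on the dense modularity matrix:
greedy local moves (including moves out to a fresh singleton community, 
without which small instances can be trapped) followed by aggregation,
restarted with `n_runs` random node orders (default 100), ties broken
toward the lowest community index.  The returned Q is verified against the
all-singletons and one-module partitions.  On all small instances tested
(≤ 8 nodes single-layer, ≤ 10 supra-nodes multilayer) the engine attains
the exhaustive-search optimum.

**Hierarchy.**  Levels are found recursively.  On each (sub)network the
coarsest γ on an ascending grid (geometric, 0.5 → 8, 13 points) that
produces > 1 module defines a candidate split; the split's Q is compared
with Q on 100 degree-preserving rewired copies (Maslov–Sneppen double-edge
swaps, ~5m accepted swaps) and retained when p < 0.05; recursion continues
inside each module from the same grid index (the grid never moves
backward).  Recursion stops below 4 nodes, at empty subgraphs, or after 12
levels.  Cells whose branch terminates early carry their final module down
the remaining levels, so every finer level refines every coarser one by
construction.  A network with no significant split reports zero levels —
the behavior on Erdős–Rényi graphs ~95% of the time, which the suite
checks.  The number of rewiring nulls is configurable; 100 gives a minimum
attainable p of 1/101.

**Spatial statistics.**  For each module (size ≥ 2) the mean distance from
each member to its nearest co-member is compared with the same statistic
under ≥ 1000 random permutations of all cell positions (module labels
fixed): z = (obs − null mean)/null sd.  Negative z = spatially compact.  A
module spanning all cells is permutation-invariant and scores z = 0;
singletons are skipped with a warning.  The per-study summary is the
Spearman correlation of z with hierarchical level.

**Co-assignment.**  C_ij is the fraction of partitions in which i and j
share a module.  Session-level co-assignment matrices are built from the
retained hierarchy levels (each level is one partition); this keeps the
consensus aligned with the hierarchy analysis and avoids thousands of extra
maximizations whose partitions would be near-duplicates across a γ range.
The generic consensus operation accepts any partition collection (its
reference sample count, 10000, remains the configurable default for
consensus over independent maximizations).

## 3. Session-pair similarity and decay

For sessions u, v the cells present in both (after excluding flagged cells;
minimum 10 shared, configurable — fewer than ~45 edge pairs makes the
upper-triangle correlation unstable) index submatrices of W (or of the
co-assignment C).  Similarity r_uv is the Pearson correlation of the
strictly-upper triangles.  The Mantel-style z applies one random node
permutation to the rows and columns of the *first* matrix and recomputes r
against the second (1000 permutations).  The statistic is not symmetric in
its arguments, so both orderings are computed; pair records carry z_uv,
z_vu and their mean, and decay analyses use the mean.  Day distance d_uv
comes from the session metadata (integer days), never from session indices.

Decay = Pearson correlation of z with d across pairs (≥ 3 pairs; constant
inputs are flagged undefined).  The tercile variant splits each session's
levels 1..L into up to three contiguous groups and repeats the analysis on
co-assignment matrices restricted to each group; with fewer than three
levels the groups collapse, with a warning.

## 4. Multilayer modularity and flexibility

Layers are the binary adjacencies of (by default the first five) sessions,
restricted to the cells present in all of them.  The supra-modularity
matrix holds A_u − γ k_u k_uᵀ/2m_u on the diagonal blocks (per-layer degree
null; an empty layer contributes no null term) and ω·I between **adjacent**
layers (sessions are temporally ordered; all-pairs coupling is available
behind a flag).  Maximization runs the same Louvain engine on the
(cell, layer) supra-graph, so labels share one namespace across layers.
Flexibility is f_i = 1 − (1/(T−1)) Σ_u δ(g_{i,u}, g_{i,u+1}) — adjacent
transitions only.

**{γ, ω} bounding.**  A parameter pair is *feasible* when the partition has
more than one and fewer than N·T communities and flexibility is neither
identically 0 nor identically 1.  Feasibility is probed on a 6 × 6 grid
over (γ ∈ [0.05, 5], ω ∈ [0, 3] by default); the largest axis-aligned
rectangle of feasible grid points is refined by bisection toward the
neighboring infeasible grid lines and finally shrunk (factor 0.9 per step)
until all four corners re-verify.  A pure two-point bisection proved
fragile because feasibility is not monotone along an axis; the grid step
makes the search robust while bisection still sharpens the edges.
Flexibility profiles average within-sample ranks of f_i over n_samples
uniform draws from the box (reference default 10000; 100–200 in the test
suite and acceptance script, which is ample for rank stability at N ≤ 100).

## 5. Temporal core-periphery

The consistency matrix G_ij is the *fraction* of layers containing edge
(i, j) (values are multiples of 1/T, zero diagonal).  The coreness template

    C*_m = 1 / (1 + exp(−(m − βN) · tan(πα/2))),  m = 1..N

is nondecreasing in m; α = 0 gives the all-0.5 maximally fuzzy profile,
α = 1 is handled as the binary step limit (0 below βN, 1 above, 0.5 at
equality), and the exponent is clipped at ±700 to avoid overflow.  Node
coreness is the permutation of the template maximizing
R = Σ_ij G_ij C_i C_j.  R is reported on the unnormalized template; a
normalized variant (template divided by its sum) is available for
cross-(α, β) comparability — at fixed parameters it rescales R by a
positive constant and cannot change the optimal permutation.

**Annealing.**  State = assignment of template values to nodes; proposal =
swap two nodes (ΔR in O(N) via cached row sums); initial temperature set so
a typical downhill move accepts with probability ~0.8; geometric cooling
0.95 per sweep of N² proposals; a restart stops after 50 sweeps without
improvement; best of 10 restarts (all configurable; the suite verifies the
annealer reaches the factorial-search optimum for N ≤ 8).

**Permutation null.**  The default null shuffles the off-diagonal entries
of G uniformly (upper triangle permuted, mirrored), preserving the weight
multiset while destroying which pairs are persistent.  A symmetric
row/column relabeling variant is provided for completeness, but the optimal
R is *exactly invariant* under relabeling (the objective is
permutation-invariant), so that variant can only measure annealing noise —
the entry-shuffle is the meaningful null and is the default everywhere.
The (α, β) surface uses a 31 × 31 linear grid with 100 nulls per point by
default, and reports observed minus null-mean R plus the top decile of
points.

**Core definitions.**  Two thresholds are implemented: the sigmoid midpoint
(coreness > 0.5), used to report core *size*, and the top 10% by coreness
(configurable), used for the core-vs-periphery connection-stability
comparison (decay analysis run separately inside the core set and inside
its complement, with a lowered shared-cell minimum of 4 and a warning when
the core has fewer than 4 cells).  Constant coreness (α = 0) makes top-k
selection an arbitrary tie-break and is flagged.

## 6. The synthetic-data generator

The generator emulates a tracked-ROI longitudinal imaging study.  Each
cell's trace is Σ_l w_l · s^(l)_{g_l(i)}(t) + σ ε(t), passed through a
per-cell affine map (gain 0.5–1.5, offset 0–100) to arbitrary fluorescence
units.  The latent module signals s are Gaussian noise smoothed with a
~0.5 s moving average and standardized — smoothing keeps the *differenced*
latents non-degenerate and temporally structured, which is exactly what the
jitter null destroys — and are redrawn independently per session.

* **Hierarchy**: a branching list (e.g. (2, 2)) defines nested modules;
  cells spread evenly over the finest modules; level-l labels are the
  ancestors of the finest label, so refinement holds by construction.
* **Drift**: non-core cells are reassigned between sessions with
  probability 1 − (1 − rate_i)^gap_days; per-cell rates are
  drift_prob_per_day × Uniform(1−h, 1+h) (h = 0.8 by default) because real
  populations lie on a stability continuum, and a continuum is also what
  makes rank-based flexibility/coreness comparisons informative.  A
  drifting cell keeps its coarse parent with probability 0.8, preserving
  the hierarchy while eroding fine structure.
* **Core**: a fraction (default 20%) of cells whose labels never drift,
  drawn from as few finest modules as possible so they form a coherent,
  persistently co-active assembly.  A scattering of individually stable
  cells would share no edges and would not constitute a temporal core in
  the network sense (the quadratic core quality cannot, even in principle,
  assemble it).  Correspondingly, drifting cells reorganize only among
  modules that host no core cells: the core assembly is closed, so
  transient visitors cannot acquire spurious persistent coupling to it.
* **Space**: finest-module centers are uniform in the central 70% of the
  field of view; positions scatter around them (σ = spatial_module_sd) and
  are fixed across sessions (cells are tracked).
* **Dropout**: independent per session; the whole pattern is redrawn (≤ 100
  attempts) if any session pair would share fewer than 10 cells.

All randomness flows from one seed through fixed substreams, so identical
configurations are bit-identical.

Defaults mirror the emulated study design: 5 sessions over two weeks,
18000 frames at 30 Hz (10 min), 150 cells, 20% core.  What the generator
does **not** emulate: imaging artifacts (no pixels, PSFs, neuropil, or
segmentation errors), spiking or indicator dynamics (latents are smoothed
noise, not calcium transients), graded synaptic rewiring (drift is a
discrete module reassignment), or tracking mistakes (cell identities are
exact).  Passing recovery tests therefore demonstrates the *statistical
machinery* — calibration of the nulls and recoverability of planted
modular, temporal, and core structure — not robustness to the optical and
biophysical confounds of real recordings.

## 7. Problem sizes in the tests and acceptance script

The validation studies are deliberately desk-scale so the whole suite runs
in minutes on one CPU:

* hierarchy recovery: 64 cells, 1 session, 1500 frames, weights (0.9, 0.9),
  noise 0.8 — chosen from a block-density scan so the binarized graph shows
  a density gradient (within-fine ≈ 0.95, within-coarse-only ≈ 0.45,
  between ≈ 0.05) rather than saturating into cliques, which is the regime
  in which a two-level hierarchy is identifiable from binary adjacency;
  150 jitters, 100 rewiring nulls, 20 seeds.
* stable-core studies: 100 cells, 5 sessions over 14 days, five flat
  modules, drift 0.25/day (heterogeneity 0.8), so that ~90% of periphery
  cells reorganize at least once over the study — without that, a planted
  core is not operationally distinct from the periphery; 120 jitters,
  200 {γ, ω} samples, 10 seeds.
* calibration: 50 independent cells × 6000 frames, 1000 jitters (the
  false-positive band is ±3 binomial SDs around α); 200 Mantel and 50
  spatial null repetitions.

The in-study defaults (18000 frames, 1000 jitters, 10000 parameter samples,
31 × 31 grid with 100 nulls) remain the package defaults.

## 8. Known limitations

* The hierarchy procedure is a recursive stand-in for multi-resolution
  consensus methods; its γ grid granularity bounds which scale separations
  it can distinguish, and its significance test inherits the conservatism
  of partially-rewired dense subgraphs.
* The quadratic core quality admits one dominant core; multi-core
  structure is out of scope.
* Mantel z-scores treat edges as exchangeable units; spatial
  autocorrelation of edge weights is not modeled.
* The annealer is stochastic; optimality is verified exhaustively only at
  small N, and large-N results should use several restarts (default 10).
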