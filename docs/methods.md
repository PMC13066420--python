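# Methods

This note documents the models implemented in `cellplacer`, the parameter
defaults and their units, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the underlying method
description left the design open.

## 1. Cell-to-spot mapping

### Costs

Let S (c × g) and G (s × g) be the log-normalized cell and spot expression
matrices restricted to the union of per-type marker genes (top 100 by
one-vs-rest Welch t-statistic). The fused Gromov–Wasserstein problem uses

- **M** (c × s): cosine dissimilarity between cell and spot expression.
- **C1** (c × c): cosine dissimilarity between cells.
- **C2 = A1 ⊙ A2** (s × s): A1 is the Euclidean spot-center distance matrix
  scaled to maximum 1; A2 is the cosine dissimilarity of a spot embedding.
- η = 0.5 weighs the linear against the quadratic term; p, q are uniform.

Zero-norm expression rows receive cosine dissimilarity 1 against everything
(including themselves): a cell or spot with no signal on the marker panel
carries no evidence of similarity.

### Spot embedding provider

The role of the spot embedding is to make A2 *spatially consistent*: spots
that are both near each other and transcriptionally similar should have
small A2 entries. The reference approach uses a graph neural embedding;
`cellplacer` ships a dependency-free default — PCA (50 components) of spot
expression followed by two rounds of averaging each spot's vector with its
k = 6 spatially nearest spots — and accepts any externally computed
embedding as an array or CSV (`spot_embedding(..., provider=...)`). With
`k_smooth=0` the provider degenerates to plain PCA.

### Solver

`fused_gromov_wasserstein` is a conditional-gradient (Frank–Wolfe) loop
with the L2 Gromov loss: the quadratic term is evaluated through the
standard tensor decomposition (constant + `−2 C1 T C2ᵀ`), the linear
minimization oracle is the exact transportation LP solved by HiGHS
(`scipy.optimize.linprog`), and the step size comes from exact line search
on the quadratic restriction. Iterates remain on the transport polytope, so
marginals are conserved to LP accuracy (≤ 1e-6 in all tests) at every
iteration; the objective is non-increasing by construction. Default cap
10,000 iterations with relative tolerance 1e-9; convergence on realistic
inputs takes < 10 iterations. There is no entropic regularization.

### Assignment

`assign_top_k` grants each spot its k = 5 largest-mass cells. Because a
cell can top several spots, candidates are granted in descending coupling
mass (ties: spot index, then cell index), each cell placed at most once.
Cells of user-listed low-abundance types left out of the coupling are
appended to their cosine-argmax spot afterward; cells already placed are
never moved.

## 2. Particle refinement

Assigned cells are initialized isotropic-normal around their spot centers
(σ = r_s/3; the reference description says only "randomly initialized
around the known spot coordinates") and integrated with forward Euler,
simultaneous (Jacobi) updates, step h (default 20), t_f = 10 iterations.

### Forces

- **Morse** `V(r) = V0 exp(−r²/c1²) − U0 exp(−r²/c2²)`, force summed over
  all pairs, amplitude multiplied by a linear annealing factor
  `s(t) = (t_f − t)/t_f` (the reference states annealing without a formula;
  linear decay is the simplest monotone choice and is config-exposed).
- **Spot constraint**: magnitude `min(b (d − r_s)², 1.5)` toward the
  assigned spot center once the cell is outside the spot radius, zero
  inside; b = 0.05.
- **Gene similarity**: attraction of magnitude `a(t) · max(PCC(g_i, g_j), 0)`
  along the connecting unit vector, `a(t) = (t − t_f)²/(20 t_f²)`, restricted
  to cells in the same or adjacent spots (centers within 1.5 × the minimum
  spot spacing, covering square and hexagonal grids; neighborhoods built
  once at initialization). g are 50-dim PCA embeddings, not raw expression.
- **Ligand–receptor** (optional, off by default — it contributes little
  beyond the expression term): same form with weights from the sparsified
  affinity W.

### Morse parameter selection

Parameters are derived from the rule *equilibrium radius = 0.35 × minimum
spot-center distance*. The published per-dataset tuples share fixed ratios
(U0/c1 ≈ 0.0827, V0/c1 ≈ 0.9093, c2/c1 ≈ 1.5706); `choose_morse_params`
keeps that family shape and rescales c1 so the numeric argmin of V lands on
the target within 1%. (The published tuples themselves do not place the
analytic well at the stated equilibrium — e.g. the 600-µm-grid tuple has
its minimum near r ≈ 76 — so the rule, not the tuples, is authoritative
here; the tuples contribute only the family shape.) Homogeneity makes the
equilibrium scale exactly linearly with the spot spacing, so the same rule
serves µm-scale and unit-scale datasets.

### LR affinity and sparsification

W0 = T_L T_Rᵀ + T_R T_Lᵀ over the filtered LR panel (both genes detected in
≥ 1% of cells). Sparsification keeps the spirit of spectral sparsification
without its full machinery: effective resistances are estimated by eight
random ±1 projections through a regularized Laplacian solve, edges are
ranked by weight × resistance, and edges are kept until the retained
fraction of total edge weight reaches the threshold (default 0.4). A plain
weight-quantile fallback (`method="quantile"`) is provided. W stays
symmetric with support inside W0's.

### Tissue boundary

The boundary is the level set {Z = 0.4 max Z} of an equal-weight Gaussian
mixture over the initial positions with covariance 1e4·I. The maximum is
evaluated over the component centers (exact up to kernel overlap). A cell
below the level is moved along the density gradient and the crossing is
located by bracketing plus bisection (80 halvings, i.e. to machine
precision along the ray); if the gradient vanishes the cell walks toward
the densest center. The 1e4 covariance is coordinate-scale dependent: it
suits µm-scale tissues, and `boundary_scale_auto` rescales it by
(tissue diameter / 100)² for other unit systems.

### Time step and coordinate scale

The default h = 20 is matched to µm-scale coordinates (the synthetic
generator's default 2000-unit tissue). For unit-scale data the perturbation
benchmark uses h = 0.5, mirroring the reference protocol for that
evaluation. An additional hyperparameter m = 0.025 appears in that protocol
without a definition in the model equations; it is stored as an inert
config stub (`RefineConfig.m`) and never used.

## 3. Subcellular-element shapes

Each refined centroid is rescaled by `1.25 √n_e r_intra / d_m` (d_m =
median Delaunay edge length of the centroids) and expanded into n_e = 20
elements sampled isotropic-normal (σ = r_intra/2). Elements follow an
overdamped Langevin equation with: intercellular 12-6 potential
(equilibrium r_inter = 2.4) between elements of different cells, weighted
by α_ij = linear map of max(PCC, 0.05) from [0.05, 1] onto [0.04, 1];
intracellular `β[12-6] + γ r³` (r_intra = 2, β = 0.25, γ = 0.001) between
all element pairs of a cell; and Gaussian noise annealed as
σ(t) = √((T_max − t)/T_max), zero at the final step. Noise is discretized
in the Euler–Maruyama sense (per-step std σ(t)·√dt).

Numerical choices:

- **Substepping.** At the nominal dt = 0.04 forward Euler is unstable for
  the stiff 12-6 core once a cell is compact (the cell artificially swells
  ~35% above the steady-state law √n_e·r_intra/2). Each of the T_max = 2000
  outer steps is therefore integrated as 5 inner Euler substeps of dt/5;
  the isolated-cell radius then lands within ~1% of the closed form. The
  outer step remains the unit of the noise/annealing schedule.
- **Force clamp.** Per-element force norms are clamped at 50 so the raw
  initialization (which contains near-singular element overlaps) relaxes
  instead of exploding; the clamp is inactive after the first few steps.
- **Neighbor pruning.** Inter-cell forces act only between cells whose
  centroids are within 3 × √n_e·r_intra, and the 12-6 kernel is evaluated
  on a KD-tree pair list within 4·r_inter (beyond which it is numerically
  negligible); the pair list refreshes every 5 outer steps with that margin.
- **Reported radius** is √2 × the RMS element distance from the cell's
  element centroid (equals the disc radius for uniformly filled discs); the
  reference never defines its measurement.
- A NaN step is rejected and dt halved (logged), failing after 20 halvings.

## 4. Contact-based communication

A k = 8 nearest-neighbor graph over all elements pooled defines contacts:
cells i and j touch if any cross-cell element neighbor relation exists in
either direction. For each contact, directed scores s_ij^LR = g_i^L g_j^R
use log-normalized expression. Cluster-level scores average over **all**
cell pairs of the two clusters (denominator N_I·N_J; non-contacting pairs
contribute zero) — the directed mean matrix a practitioner expects from a
communication tool. Significance comes from n = 100 label permutations with
the add-one estimator p = (1 + #{S_perm ≥ S_obs})/(n + 1), which cannot
return p = 0; under an exchangeable null the realized false-positive rate
at p < 0.05 is 5/101 ≈ 0.0495, and the calibration test confirms
0.05 ± 0.02 over pooled tests. Multi-subunit receptor complexes must be
pre-flattened to gene pairs; complex-level aggregation is out of scope.

## 5. Evaluation metrics

- **KL divergence**: 100 × 100 histogram over the joint bounding box,
  normalized, `Σ p log((p+ε)/(q+ε))` with ε = 1e-10. An optional Gaussian
  smoothing (`smooth_sigma`, in bins) gives the kernel-density variant used
  for the benchmark protocols, where raw 100×100 histograms of ~10³ points
  are too sparse to compare meaningfully.
- **Wasserstein**: exact EMD with uniform weights; equal-size clouds go
  through `linear_sum_assignment`, unequal sizes through the HiGHS LP.
- **Ripley's L**: `K(r) = a/(n(n−1)) ΣΣ I(d_ij ≤ r)`, L = √(K/π), no edge
  correction, 20 radii up to a quarter of the shorter bounding-box side;
  curves compared by MSE. Without edge correction L(r) < r slightly even
  under CSR; tests account for that bias.
- **Neighborhood enrichment**: Delaunay connectivity, observed inter-cluster
  edge counts vs n = 1000 label permutations, reported as z-scores.
- **Same-type NN distance**: per-cell distance to the nearest same-label
  cell; singleton types are skipped.

## 6. Synthetic data: what it does and does not establish

`generate_tissue` emulates the statistical structure of the benchmark
tissues, not any real dataset: uniform cell positions within layered /
ring / blob type regions, per-type mean expression with an equal block of
markers at 8× baseline fold-change, negative-binomial counts with
dispersion 0.5 (mean-variance inflation typical of UMI data), defaults of
1000 cells, 4 types, 200 genes on a 2000-unit tissue (~60-unit cell
spacing, Visium-like in µm). `make_pseudo_visium` implements the benchmark
aggregation: uniform grid, global distance-ordered greedy assignment to the
nearest grid point (a cell competes only at its nearest grid point —
whether it may overflow to the second-nearest is unspecified; not doing so
is the stricter reading), ≤ 5 cells per grid point, half-grid-spacing
reach, empty spots removed, spot expression = sum of members. The default
14 × 14 grid for 1000 cells follows the "each grid point has at least 5
cells" sizing rule.

A green end-to-end test therefore establishes that the pipeline recovers
layered type structure from its own aggregation under NB noise — not
performance on real tissue, where marker separation is weaker, cell density
varies, and boundaries are irregular. The refinement-benefit tests compare
against the random initial placement within assigned spots (the baseline
the reference benchmark uses), with KDE-smoothed densities as in that
protocol.

## 7. Known limitations

- Uniform cells-per-spot capacity; no cavities or variable density.
- The gene-similarity force attracts with distance-independent magnitude
  within a neighborhood, so strongly correlated types compact toward their
  density cores; on tissues whose types are homogeneously spread this can
  over-concentrate (the Morse term bounds, but does not remove, the effect).
- FGW solve time is dominated by the exact LP oracle (~2 s per iteration at
  1000 cells × 200 spots); for much larger instances inject an external
  assignment or subsample.
- 2-D only; no batch correction across datasets; no secreted/diffusive
  signaling.
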