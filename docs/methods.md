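# Methods

## Model and pipeline

A population is N subjects × M views of cortical morphological networks
(CMNs) over a shared set of N_r ROIs. A CMN edge is the absolute difference
of a cortical attribute's ROI means, so every network is symmetric,
non-negative and zero-diagonal, in the attribute's units (mm for thickness).
ROI means come from per-vertex measurements: the mean of mc(v) over the
vertices labelled with each ROI.

### Subject-similarity graphs

Per view, subjects are represented by the strict upper triangle of their
network (row-major order (0,1), (0,2), …; length N_r(N_r−1)/2 — the same
fixed bijection is used by the weight anti-linearization, so rankings and
matrices always agree on edge identity). From the Euclidean distance matrix
D we build the scaled-exponential affinity

    S(i,j) = exp(−D(i,j)² / (2 σ_ij²)),   σ_ij = (μ_i + μ_j + D(i,j)) / 3

with μ_i the mean distance of i to its K_n nearest neighbors — the local
scaling convention of the SNF literature, which adapts the kernel width to
local sampling density. The kernel is evaluated first and then sparsified on
the mutual-OR KNN mask (j in i's K_n nearest or vice versa; ties at the
K_n-th distance are all kept, with lower index ranking first among equals),
symmetrized as (S + Sᵀ)/2 and zeroed on the diagonal. All-identical
subjects (zero scale) degrade gracefully to affinity 1 on the mask. The
per-view Laplacian is the standard unnormalized L = diag(rowsum(S)) − S,
which is positive semidefinite; the trace objective below is minimized by
its smallest eigenvectors, which is what makes spectral clustering work.

### Joint clustering on the Stiefel manifold

The per-view Laplacians are assembled into the (MN) × (MN) block matrix L
with −β·I_N on every off-diagonal block. β (default 1) balances within-view
cluster quality against cross-view label alignment; the coupling term
−β Σ_{m≠t} U_mᵀU_t is what aligns cluster identities across views without
any post-hoc label matching. The relaxed assignment problem

    min_U trace(UᵀLU)   s.t.  UᵀU = I_{N_c}

is solved over the stacked U (one N × N_c block per view) on the Stiefel
manifold St(MN, N_c). The constraint is deliberately on the stacked matrix:
its analytic minimum is the sum of the N_c smallest eigenvalues of L, which
gives the optimizer an exact external check (per-block orthonormality would
change both the feasible set and the optimum). The optimizer iterates:
negative gradient Z = −LU; canonical tangent projection
η = Z − U·sym(UᵀZ); Armijo backtracking (initial step 1, shrink 0.5,
sufficient decrease 1e−4) on the retracted candidate; polar retraction via
thin SVD (the closest orthonormal-column matrix in Frobenius norm).
Convergence is declared when the relative objective change falls below
`tol` (default 1e−8), with `max_iter` 500 and a recorded warning (not an
error) on non-convergence. Initialization is the exact eigenvector warm
start by default (`init="eigen"`), with a seeded random orthonormal start
(`init="random"`) available; from random starts the projected gradient
still reaches the analytic minimum on the tested problem sizes, only
slower.

Labels are read off by one k-means (k-means++ with 20 restarts, seeded)
over all MN rows of the optimized embedding; because the M view blocks
share centroids, label c means the same cluster in every view.

Two behaviors of this formulation are worth stating precisely, and both are
exercised by tests:

* Views generated from one shared partition receive exactly aligned labels,
  and at separation-to-noise ratio ≥ 10 the planted partition is recovered
  with ARI = 1 per view in ≥ 95% of seeds.
* A *differential* view (its own independently shuffled partition) cannot
  place its own indicators in the bottom-N_c eigenspace: any cross-view
  aligned vector earns the full −(M−1)β coupling reward while a
  view-specific vector earns none, so the embedding carries the consensus
  structure and a shrunken copy of it in the differential block. In
  practice the differential view's labels depart from exact agreement with
  the consistent views (which stay perfectly aligned), but they lean toward
  the consensus partition rather than the view's own planted one. Users
  who need a discordant view's own partition should raise N_c beyond the
  consensus cluster count so the extra embedding dimensions can carry it.

### Fusion

Within each aligned cluster, per-view member networks are averaged
elementwise (local templates). Clusters are then fused across views by SNF:

* full kernel P(i,j) = A(i,j) / (2 Σ_{l≠i} A(i,l)) off-diagonal, ½ on the
  diagonal, so every row sums to exactly 1; a row with no off-diagonal mass
  falls back to a uniform off-diagonal distribution;
* sparse kernel: each row keeps its K_n largest affinities (ties to the
  lower index) renormalized to sum 1 — the SNF reference convention.
  The printed alternative that normalizes neighbor rows to sum ½ is
  available as `snf_row_norm="printed"` but contracts the diffusion toward
  zero and is not the default;
* N_t simultaneous sweeps of P^m ← S^m (Σ_{t≠m} P^t / (M−1)) S^mᵀ, each
  followed by symmetrization and re-application of the full-kernel row
  rule, which keeps every kernel row-stochastic throughout;
* the fused cluster template is the symmetrized mean of the diffused
  kernels; a cluster present in only one view degenerates to that view's
  full kernel (with a warning); a cluster empty in every view is dropped
  from the final average (with a warning).

The final template is the elementwise mean of the cluster templates. SNF is
applied directly to the dissimilarity-valued CMN averages, without a
dissimilarity-to-affinity conversion: the template is then a row-stochastic
kernel (diagonal ½) rather than an attribute-unit network. This is a
deliberate fidelity choice with a visible consequence: distances and
correlations between the template and raw networks are dominated by the
scale mismatch, so centeredness numbers are meaningful for comparisons
between methods on the same population, not in absolute terms.

N_t defaults to 20 (a value at which the fused kernels have stopped moving
at double precision on the tested sizes; the diffusion has no stated
stopping rule). K_n defaults to 5 for both the subject graphs and the
sparse ROI kernels; N_c defaults to 3; K (folds) defaults to 5.

### Evaluation and discriminability

Centeredness: per view, the mean Frobenius distance (and mean matrix-wide
Pearson correlation over all N_r² entries, diagonal included; an
upper-triangle-only variant is available by flag) between the template and
every subject's network, averaged across views. Fold-wise comparisons use
seeded K-fold partitions (sizes differ by ≤ 1), the normalization
d′ = (d − mean)/(max − mean) + 1.5 per fold (exactly 1.5 at the fold mean,
2.5 at the fold max; a degenerate fold where all methods tie returns 1.5
with a warning), and a two-tailed paired t-test across folds.

Discriminative ROIs between two populations are ranked two ways:

* **Template difference.** One template per fold per group; the elementwise
  absolute differences of all K² cross-group fold pairs are accumulated
  into T; α_i = Σ_j T(i,j); ROIs are ranked by descending α with ascending
  index as tie-break.
* **SVM weights.** For every view and every cross-group fold pair, a linear
  soft-margin SVM (C default 1.0, solver tolerance 1e−6) is fitted on
  vectorized networks; absolute weights are summed over all K²·M fits,
  anti-linearized into the symmetric matrix B, and row-summed into α. No
  joint kernel-combination optimization is performed — the accumulation
  across views and fold pairs *is* the multi-kernel aggregation, and a
  linear kernel is the only choice that exposes per-feature weights
  directly.

Agreement between the rankings is the percentage overlap of their top-k
sets (k 15 or 20 by default for 35-ROI networks; 5 in the synthetic
recovery experiments with 5 planted ROIs).

### Baseline

The cluster-after-fusion baseline reverses the order of the two main
stages: each subject's M views are SNF-fused into one network, the fused
networks are k-means clustered (on their vectorized upper triangles), and
the final template is the mean of the cluster-wise mean networks. It is a
reconstruction from a one-sentence description of the original method and
is labelled "SCA-style" accordingly, not a re-implementation.

## Synthetic data

The generator emulates the population structure the pipeline assumes, at a
cortical-thickness-like scale: cluster centroids are ROI-mean vectors
`2.5 + cluster_separation · N(0, 1)` per view, subjects add
`within_noise · N(0, 1)`, and networks are built through the same absolute
mean-difference rule as real attribute data, so planted effects propagate
into edges exactly as real attribute differences would. Defaults: 60
subjects, 3 views, 35 ROIs, 3 balanced clusters, separation 0.5, noise
0.05 (separation-to-noise 10, the well-separated regime used for recovery
checks; 0.2 is used as the heterogeneous regime in centeredness
comparisons). One view may be designated *differential*, receiving an
independently shuffled copy of the partition. Two-group populations share
the same centroids — two human populations share the same underlying brain
organization — and group B adds `effect_size` (default 0.5) to the ROI
means of the designated effect ROIs in every view, shifting every edge
incident to those ROIs; subject noise is drawn independently per group, so
a zero effect size makes the groups exchangeable draws from one process.

The discriminability experiments use 100 subjects per group so that 5-fold
splits give 20-subject folds: fold sizes must comfortably exceed
n_clusters × k_neighbors, otherwise the per-fold KNN graph connects
everything and the per-fold clustering collapses. This mirrors, at desk
scale, a protocol whose folds contain dozens of subjects.

What the generator does not emulate: realistic attribute distributions and
vertex counts, spatially correlated noise across ROIs, hemispheric effects,
unbalanced cluster sizes, or view-specific noise levels. Passing tests
therefore demonstrate the pipeline's mechanics and its behavior under
planted structure, not performance claims on real morphological data.

## Numerical choices

* Symmetry tolerance for input matrices: max|X − Xᵀ| ≤ 1e−8 · max|X|;
  inputs within tolerance are symmetrized as (X + Xᵀ)/2, larger asymmetry
  is an error naming the offending file.
* ROI indices are 1-based in files and user-facing tables, 0-based in
  memory.
* KNN ties are always resolved toward the lower index after a stable sort,
  making every ranking and mask deterministic.
* k-means uses 20 restarts with a fixed seed; the SVM uses the libsvm
  solver at tolerance 1e−6; both make pipeline outputs bitwise reproducible
  from (inputs, config, seed).
* Degenerate inputs are handled explicitly rather than silently: empty
  ROIs, rank-deficient retraction inputs, constant matrices in the Pearson
  correlation, zero-variance differences in the t-test and single-class SVM
  inputs raise errors; empty clusters and degenerate folds warn.

## Known limitations

* The centeredness comparison against the cluster-after-fusion baseline
  does not favor this pipeline on the synthetic populations: both templates
  live on the SNF kernel scale, the mean Frobenius distance to raw networks
  is dominated by the shared scale mismatch, and the remaining margin
  (~10⁻⁴ relative) systematically favors the baseline's smoother average
  of per-subject kernels. The comparison is reported honestly by the
  acceptance script; on real heterogeneous data the ordering may differ,
  but that cannot be established at synthetic desk scale.
* Absolute centeredness values mix kernel-scale templates with
  attribute-scale networks (see Fusion above); use them comparatively.
* A differential view's own partition is not recoverable from the joint
  embedding at N_c equal to the consensus cluster count (see the clustering
  section for the mechanism and the N_c workaround).
* The pipeline assumes complete data: every subject must have every view.
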