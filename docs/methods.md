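# Methods

## Model

`rpmm` treats robust point matching as maximum-a-posteriori estimation in a
mixture model over putative correspondences (x_i, y_i) ∈ R^D × R^D,
D ∈ {2, 3}. A latent 1-of-(L+1) indicator assigns each pair to one of L
motion layers or to an outlier class:

* **Inlier of layer l**: y_i = T_l(x_i) + ε, ε ~ N(0, σ²I), with the
  transform written in displacement form T_l(x) = x + f_l(x). Each f_l
  lives in the vector-valued RKHS H of the scalar Gaussian kernel
  k(a, b) = exp(−β‖a−b‖²) applied identically to every output dimension,
  and carries the smoothness prior p(f_l) ∝ exp(−(λ/2)‖f_l‖²_H).
* **Outlier**: y_i uniform over a bounded region of volume a (density 1/a).

Mixing weights γ_1, …, γ_{L+1} (outlier last) lie on the simplex. The
negative log posterior — the energy monitored for convergence — is

    E(θ) = − Σ_i log[ Σ_{l≤L} γ_l N(y_i | T_l(x_i), σ²I) + γ_{L+1}/a ]
           + (λ/2) Σ_{l≤L} ‖f_l‖²_H .

Working on displacements rather than absolute positions means a zero field
is the identity map, which keeps the prior's pull ("shrink toward no
deformation") physically sensible.

## Estimation

Both point sets are first normalized to zero mean and unit total variance,
each with a single scalar scale so shapes are preserved; all parameter
defaults below refer to these normalized coordinates, and results are
mapped back through the stored normalization.

**Initialization.** Motion vectors v_i = y_i − x_i are clustered by
K-means (k-means++ seeding, 10 restarts, seeded from the config). Clusters
at least `cluster_ratio` times the size of the largest become components,
ordered by decreasing size; members of discarded clusters start as
outliers. Degenerate inputs (identical motions) short-circuit to a single
component. If no cluster is discarded, the outlier class would start with
weight exactly zero and — because the mixing-weight update is a
responsibility average — could never regain mass; it is therefore floored
at `gamma_outlier_init` (default 0.1, the customary inlier-prior ≈ 0.9
convention), with component weights rescaled accordingly.

The hard cluster assignment then plays the role of a first E-step: the
component fields and σ² are fitted from the one-hot responsibilities
*before* the soft loop starts. This ordering matters — all components
begin with identity transforms, so a premature E-step would hand every
component an identical, γ-proportional responsibility column and erase the
clustering.

**EM loop.** Each iteration: (1) E-step responsibilities in log space;
(2) per-component field refit; (3) γ update (column means of the
responsibilities); (4) σ² update (responsibility-weighted mean squared
residual per dimension, floored at `sigma2_floor`). The field refit is the
representer-theorem solve of the weighted regularized risk

    Σ_i p_il ‖(y_i − x_i) − f(x_i)‖²/(2σ²) + (λ/2)‖f‖²_H ,

whose minimizer is f(x) = Σ_j k(x, x_j) c_j with coefficients from
(diag(p)K + λσ²I)C = diag(p)(Y − X). This matrix is not symmetric for
non-uniform p, so an LU solve is used, with diagonal jitter escalating
from 1e−10 by factors of 10 up to 1e−6 before a numerical error is raised.
Note the effective ridge is λσ²: as the noise estimate shrinks, the fit is
allowed to tighten, which is what lets σ² anneal from its large initial
value down to the true noise level without an explicit schedule. Because
every update is an exact coordinate-wise minimizer of the EM bound, the
energy is non-increasing across iterations; convergence is declared when
its relative change falls below `tol`.

**Fast mode.** With `fast=True`, each field is restricted to kernels on a
random M-subset of the inputs (subset of regressors), giving the symmetric
M×M system (Uᵀdiag(p)U + λσ²V)C = Uᵀdiag(p)(Y−X) with U = k(X, X_b),
V = k(X_b, X_b), solved by Cholesky with the same jitter policy. The basis
is drawn once per run and held fixed across iterations — resampling would
change the feasible subspace mid-descent and void the monotonicity
argument. Kernel blocks (K, or U and V) are computed once per run and
shared across all iterations and components.

**Merging and pruning.** K-means with the default K=5 routinely
over-segments a single coherent motion; the resulting duplicate components
split responsibilities roughly evenly and can starve the inlier threshold.
After the loop converges, components whose fields agree within
`merge_dist`·σ (responsibility-weighted RMS over the data, default 3σ) are
merged pairwise — summed responsibilities and weights, refit field — and
EM is re-run to convergence after each merge. Since a merge changes the
model, each EM phase keeps its own monotone energy trace
(`MixtureState.energy_phases`); `energy_trace` exposes the final phase.
Finally, components with γ_l below `prune_gamma` are dropped, one more
E-step is taken, and pair i is labeled with its best component when that
responsibility exceeds τ, else outlier (argmax rule; independent
per-component thresholds would allow multi-membership and are not used).

## Parameters

| name | default | role |
| --- | --- | --- |
| β | 0.1 | inverse-square kernel width; interaction range ≈ 1/√β ≈ 3 normalized units (near-global smoothness) |
| λ | 3.0 | smoothness weight; effective ridge is λσ² |
| τ | 0.75 | responsibility threshold for declaring an inlier |
| a | bbox | outlier constant: volume of the normalized target bounding box (override: `a_fixed`) |
| kmeans_K | 5 | initial cluster count; the upper bound on L |
| cluster_ratio | 0.2 | minimum size ratio vs the largest cluster for a component seed |
| tol, max_iter | 1e−5, 100 | EM stopping rule (relative energy change) |
| n_basis | 15 | basis size in fast mode |
| merge_dist | 3.0 | duplicate-merge threshold in units of σ |
| prune_gamma | 1e−3 | minimum mixing weight to survive |
| gamma_outlier_init | 0.1 | initial outlier weight when clustering discards nothing |

The uniform constant a is held fixed during EM (it is part of the outlier
model, not a fitted parameter).

## Registration

For unpaired 2-D sets, `register` iterates a fixed number of times
(default 10): shape-context descriptors (5 radial × 12 angular log-polar
bins, radii in [1/8, 2] × the mean pairwise distance — hence exact
invariance to translation and global scaling; absolute orientation frame,
no rotation normalization), χ² histogram cost, Hungarian assignment
(rectangular costs behave as zero-padded), mixture fit on the assigned
pairs, then warping. The model moves only `warp_step` (default 0.5) of the
way toward its fitted warp each iteration, taking the full step only on
the last: committing fully to an early compromise field is what locks in
slid contour alignments, and partial steps keep the next correspondence
refresh informative. Matched model points with a confident label keep
their component; every other model point — unmatched or rejected as an
outlier — inherits the label of its nearest attributed neighbor and is
warped by that component's transform. K-means initialization is re-run at
every outer iteration (the literal reading of the procedure) with an
iteration-indexed seed. 3-D descriptors are out of scope; the 3-D
experiments in this problem area rely on external mesh features.

## Synthetic scenes

The generators reproduce the structure of the matching experiments; all
randomness flows from one integer seed.

**Multi-layer correspondence scenes.** Per layer, source points are
uniform in the configured bounds and mapped by an independent random layer
map plus isotropic Gaussian noise; outlier pairs have both endpoints
uniform in bounds. Layer maps are affine (rotation ±30°, scale
[0.8, 1.25], translation up to half the bounds extent), smooth random RBF
fields, or identity. Maps are rejection-sampled until every pair differs
by at least 5× the noise level in mean displacement, so "distinct layers"
is well defined. Scene rows are shuffled.

**Two-shape registration scenes.** The model is the union of two disjoint
parametric shapes of roughly unit size: a fish-like contour with interior
backbone, eye cluster and fin stroke, and a character-like glyph of five
heterogeneous strokes with corner hooks. The target warps each shape with
an *independent* random smooth field of mean displacement `amplitude`
(default 0.2 ≈ 25% of shape size — a large deformation) and bandwidth 0.8
(shape-scale smoothness). Two deliberate design points: warps are smooth
at the shape scale because finer-scale deformation is unresolvable by any
β = 0.1 field, for the mixture and a single-field ablation alike, which
removes the contrast the experiment is meant to show; and the shapes carry
distinctive interior/corner structure because overly regular surrogates
(bare contours, parallel strokes) admit smooth self-maps, making
index-level correspondence ambiguous in a way the real benchmark shapes
are not.

**What the generators do not emulate.** Descriptor noise in putative-match
construction (pairs are given directly), structured/clustered outliers
(false matches from repetitive texture are not uniform), anisotropic or
heteroscedastic localization noise, occlusion (every generated source
point has a counterpart), and 3-D surfaces. Passing results on these
scenes therefore demonstrate the estimator's behavior under its own model
assumptions plus moderate misspecification (affine and RBF layer maps are
not elements of the RKHS), not performance on real imagery.

## Experiment sizes and numerical notes

The packaged experiments use: two-layer scenes with 100 inliers per layer
and 100 outliers at σ = 0.02 over 20 seeds (with a kmeans_K = 1 ablation);
fast-vs-full agreement at N = 500, M = 15 over 10 seeds; noise recovery on
single-layer affine scenes at n = 500, σ ∈ {0.01, 0.05} — affine rather
than smooth layers, because at σ = 0.01 the unresolvable fine structure of
a bandwidth-0.5 random warp inflates the residual and the experiment would
measure approximation error rather than noise recovery; energy descent
over 50 small scenes; Hungarian optimality against exhaustive permutations
up to size 7; and registration over six two-shape scenes.

Degenerate inputs: identical point sets are rejected by normalization
(zero scale); identical motions yield one component; an all-outlier
initialization raises an error; a fully pruned mixture returns all-outlier
labels with a warning. Responsibility rows and mixing weights are
normalized to 1 within 1e−9 throughout; E-step densities are computed via
log-sum-exp, with all-zero rows (possible only at extreme σ²) assigned to
the outlier class under a warning.

## Limitations

* L is bounded by `kmeans_K` and chosen by the size-ratio rule plus
  merging; there is no likelihood-based model selection.
* A single shared σ² across components mismatches scenes whose layers have
  different noise levels.
* The registration loop is a damped fixed-point iteration without a full
  annealing schedule; a locally self-consistent wrong assignment that
  survives the damped early iterations (e.g. a contour matched with a
  circular shift) cannot be escaped later, and this remains the dominant
  failure mode at large deformation.
* Shape contexts use an absolute frame: rotations beyond what the EM can
  absorb (roughly ±30–45°) break the initial correspondences.
* Noise recovery inherits any systematic model misfit: when the true
  motion has structure finer than 1/√β, √σ̂² estimates noise-plus-misfit.
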