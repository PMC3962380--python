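# rpmm — robust point matching under multi-layer motion

`rpmm` establishes reliable point correspondences between two point sets
when the scene moves in several independent layers — a foreground object
and a background, two shapes deforming separately, tissue regions drifting
apart in microscopy time series. Putative correspondences produced by a
descriptor matcher always contain false matches (outliers); classical
geometric verification assumes either a parametric model (RANSAC-style) or a
*single* smooth motion, and both break down when the true motion is
non-rigid *and* discontinuous across layers.

## The model

Given putative pairs (x_i, y_i), i = 1..N, the package fits a mixture of L
non-parametric transforms T_l(x) = x + f_l(x), each displacement field f_l
living in the reproducing kernel Hilbert space (RKHS) of a Gaussian kernel
k(a, b) = exp(−β‖a−b‖²). Inlier pairs of layer l satisfy
y_i = T_l(x_i) + ε, ε ~ N(0, σ²I); outlier targets are uniform over a
bounded region of volume a. With mixing weights γ_1..γ_{L+1} (the last for
the outlier class), the MAP objective is the negative log posterior

    E = − Σ_i log[ Σ_l γ_l N(y_i | T_l(x_i), σ²I) + γ_{L+1}/a ]
        + (λ/2) Σ_l ‖f_l‖²_H ,

minimized by EM. The E-step computes responsibilities p_il; the M-step
refits each field by a representer-theorem linear solve

    (diag(p_l) K + λσ² I) C_l = diag(p_l) (Y − X),   K_ij = k(x_i, x_j),

then updates γ (column means of p) and σ² (weighted mean squared residual
per dimension). Components are seeded by K-means on the motion vectors
y_i − x_i, near-duplicate components are merged, and a pair is declared an
inlier of component l when p_il exceeds a threshold τ. A
subset-of-regressors mode (`fast=True`) restricts each field to M ≪ N
random basis points, reducing the solve from O(N³) to O(M²N).

For unpaired point sets, `register` alternates shape-context matching
(Hungarian assignment under the χ² histogram cost) with mixture fitting,
warping the model set a fixed number of iterations.

## Worked example

```python
import numpy as np
from rpmm import RpmConfig, make_multilayer_scene, precision_recall, rpm_mm

# two affine motion layers of 100 pairs each + 100 uniform outliers
scene = make_multilayer_scene([100, 100], "affine", noise_sigma=0.02,
                              n_outliers=100, seed=3)
result = rpm_mm(scene.X, scene.Y, RpmConfig(seed=3))
report = precision_recall(result.labels, scene.true_labels)
print(f"components: {result.state.L}")
print(f"inliers kept: {result.n_inliers}/{scene.n}")
print(f"precision: {report.precision:.3f}  recall: {report.recall:.3f}")
print(f"noise std recovered: {result.sigma_original:.4f}")
```

Output:

```
components: 3
inliers kept: 202/300
precision: 0.990  recall: 1.000
noise std recovered: 0.0185
```

The matcher found the two motion layers plus one residual component, kept
all 200 true inliers with 2 mistakes among the 100 outliers, and recovered
the noise level (true value 0.02). `result.labels` gives each pair's layer (0 =
outlier); `result.transforms[l]` evaluates layer l's fitted motion at
arbitrary points in the original coordinates.

The same pipeline is available from the shell:

```sh
rpmm simulate --seed 3 --out-dir scene/
rpmm match --x scene/X.tsv --y scene/Y.tsv --seed 3 --out report.json
rpmm register --model model.tsv --target target.tsv --out warped.tsv
```

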