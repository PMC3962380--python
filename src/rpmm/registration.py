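"""Non-rigid point-set registration driven by the mixture matcher.

Two unpaired 2-D point sets (a model and a target) are aligned by
alternating a geometry-only correspondence step and a motion-fitting step:

1. shape-context descriptors for both sets;
2. one-to-one assignment by the Hungarian method under the chi-squared
   histogram cost;
3. mixture fitting (:func:`rpmm.mixture_em.rpm_mm`) on the assigned pairs,
   yielding one or more smooth transforms plus inlier labels;
4. every model point is attributed to a mixture component (matched inliers
   keep theirs, all others inherit the nearest attributed neighbor's) and
   warped by its component's transform.

Iterating a fixed number of times lets grossly wrong initial assignments be
repaired once the model has moved closer to the target.  Fitting several
transforms is what allows two shapes that deform independently to be
registered jointly — a single smooth field cannot follow both motions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist

from .mixture_em import RpmConfig, rpm_mm

__all__ = [
    "ShapeContextConfig",
    "RegistrationConfig",
    "RegistrationResult",
    "RegistrationError",
    "shape_context",
    "chi2_cost",
    "hungarian_assign",
    "attribute_components",
    "register",
]


class RegistrationError(RuntimeError):
    """Raised when the matcher fails inside the registration loop."""


@dataclass(frozen=True)
class ShapeContextConfig:
    """Log-polar histogram layout.

    Radii are expressed as fractions of the mean pairwise distance of the
    set, making the descriptor invariant to translation and global uniform
    scaling.  The 5 x 12 layout over [1/8, 2] follows the descriptor's
    standard convention.
    """

    n_radial: int = 5
    n_angular: int = 12
    r_inner: float = 0.125
    r_outer: float = 2.0

    def __post_init__(self) -> None:
        if self.n_radial < 1 or self.n_angular < 1:
            raise ValueError("bin counts must be >= 1")
        if not 0 < self.r_inner < self.r_outer:
            raise ValueError("need 0 < r_inner < r_outer")


@dataclass(frozen=True)
class RegistrationConfig:
    """Outer-loop settings.

    warp_step damps the per-iteration model update: the model moves only a
    fraction of the way toward its fitted warp, so an early assignment error
    does not commit fully before the next correspondence refresh; the final
    iteration always applies the full warp.
    """

    n_iter: int = 10
    warp_step: float = 0.5
    shape_context: ShapeContextConfig = field(default_factory=ShapeContextConfig)

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not 0 < self.warp_step <= 1:
            raise ValueError("warp_step must lie in (0, 1]")


@dataclass
class RegistrationResult:
    warped_model: np.ndarray
    per_iteration: list
    n_iter: int


def shape_context(points: np.ndarray, cfg: ShapeContextConfig | None = None) -> np.ndarray:
    """Shape-context descriptors: per point, a log-polar histogram of the
    relative positions of the other points.

    Radii are normalized by the mean pairwise distance; neighbors outside
    [r_inner, r_outer] (in normalized radius) are not counted.  Returns an
    integer matrix of shape (N, n_radial * n_angular), radial-major.
    Only D=2 is supported.
    """
    if cfg is None:
        cfg = ShapeContextConfig()
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] == 3:
        raise NotImplementedError("3-D shape contexts are not supported")
    if pts.shape[1] != 2:
        raise ValueError("points must be N x 2")
    n = pts.shape[0]
    if n < 2:
        raise ValueError("need at least two points")

    dists = cdist(pts, pts)
    mean_dist = pdist(pts).mean()
    if mean_dist <= 0:
        raise ValueError("degenerate point set: all points coincide")

    r_edges = np.logspace(np.log10(cfg.r_inner), np.log10(cfg.r_outer), cfg.n_radial + 1)
    desc = np.zeros((n, cfg.n_radial * cfg.n_angular), dtype=int)
    for i in range(n):
        d = np.delete(pts, i, axis=0) - pts[i]
        r = np.delete(dists[i], i) / mean_dist
        ok = (r >= r_edges[0]) & (r <= r_edges[-1])
        if not np.any(ok):
            continue
        r_bin = np.clip(np.searchsorted(r_edges, r[ok], side="right") - 1, 0, cfg.n_radial - 1)
        theta = np.mod(np.arctan2(d[ok, 1], d[ok, 0]), 2 * np.pi)
        t_bin = np.minimum((theta / (2 * np.pi) * cfg.n_angular).astype(int), cfg.n_angular - 1)
        np.add.at(desc[i], r_bin * cfg.n_angular + t_bin, 1)
    return desc


def chi2_cost(desc_a: np.ndarray, desc_b: np.ndarray) -> np.ndarray:
    """Chi-squared histogram distance between every descriptor pair.

    ``cost(i, j) = 1/2 sum_k (h_i(k) - g_j(k))^2 / (h_i(k) + g_j(k))`` with
    zero-denominator terms contributing zero.
    """
    H = np.asarray(desc_a, dtype=float)
    G = np.asarray(desc_b, dtype=float)
    if H.shape[1] != G.shape[1]:
        raise ValueError("descriptor widths differ")
    diff2 = (H[:, None, :] - G[None, :, :]) ** 2
    denom = H[:, None, :] + G[None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(denom > 0, diff2 / denom, 0.0)
    return 0.5 * terms.sum(axis=2)


def hungarian_assign(cost: np.ndarray) -> list[tuple[int, int]]:
    """Minimum-total-cost one-to-one assignment (Hungarian method).

    Rectangular matrices are handled by assigning every element of the
    smaller side, equivalent to zero-cost padding of the missing rows or
    columns.  Returns min(N_a, N_b) index pairs.
    """
    cost = np.asarray(cost, dtype=float)
    if not np.all(np.isfinite(cost)):
        raise ValueError("costs must be finite")
    rows, cols = linear_sum_assignment(cost)
    return list(zip(rows.tolist(), cols.tolist()))


def attribute_components(
    model: np.ndarray, matched_idx: np.ndarray, matched_labels: np.ndarray
) -> np.ndarray:
    """Give every model point a mixture-component label.

    Matched points with a positive label keep it; all remaining points
    (unmatched, or matched but rejected as outliers) inherit the label of
    the nearest model point that already has one.
    """
    model = np.atleast_2d(np.asarray(model, dtype=float))
    matched_idx = np.asarray(matched_idx, dtype=int)
    matched_labels = np.asarray(matched_labels, dtype=int)
    labels = np.zeros(model.shape[0], dtype=int)
    labels[matched_idx] = matched_labels
    seeded = np.flatnonzero(labels > 0)
    if seeded.size == 0:
        raise ValueError("no labeled points to attribute from")
    rest = np.flatnonzero(labels == 0)
    if rest.size:
        tree = cKDTree(model[seeded])
        _, nn = tree.query(model[rest])
        labels[rest] = labels[seeded[nn]]
    return labels


def register(
    model: np.ndarray,
    target: np.ndarray,
    reg_cfg: RegistrationConfig | None = None,
    rpm_cfg: RpmConfig | None = None,
) -> RegistrationResult:
    """Align the model point set onto the target (2-D, fixed iteration count).

    Each iteration recomputes descriptors for the current model, assigns
    correspondences, fits the transform mixture, attributes components and
    warps; the warped model after the last iteration is the result.
    """
    if reg_cfg is None:
        reg_cfg = RegistrationConfig()
    if rpm_cfg is None:
        rpm_cfg = RpmConfig()
    model = np.atleast_2d(np.asarray(model, dtype=float))
    target = np.atleast_2d(np.asarray(target, dtype=float))
    if model.shape[1] != 2 or target.shape[1] != 2:
        raise ValueError("registration supports 2-D point sets only")
    if model.shape[0] < 2 or target.shape[0] < 2:
        raise ValueError("point sets must contain at least two points")

    desc_t = shape_context(target, reg_cfg.shape_context)
    current = model.copy()
    history = []
    for it in range(reg_cfg.n_iter):
        desc_m = shape_context(current, reg_cfg.shape_context)
        pairs = hungarian_assign(chi2_cost(desc_m, desc_t))
        mi = np.array([p[0] for p in pairs], dtype=int)
        tj = np.array([p[1] for p in pairs], dtype=int)
        try:
            res = rpm_mm(current[mi], target[tj],
                         replace(rpm_cfg, seed=(rpm_cfg.seed + it) % (2**31)))
            if res.state.L == 0 or not np.any(res.labels > 0):
                raise ValueError("matcher labeled every assigned pair an outlier")
            full_labels = attribute_components(current, mi, res.labels)
        except (ValueError, RuntimeError) as exc:
            raise RegistrationError(f"matching failed at registration iteration {it}: {exc}") from exc
        new = np.empty_like(current)
        for l, cmap in enumerate(res.transforms, start=1):
            mask = full_labels == l
            if np.any(mask):
                new[mask] = cmap(current[mask])
        history.append({"assignment": pairs, "labels": full_labels, "transforms": res.transforms})
        step = reg_cfg.warp_step if it < reg_cfg.n_iter - 1 else 1.0
        current = current + step * (new - current)
    return RegistrationResult(warped_model=current, per_iteration=history,
                              n_iter=reg_cfg.n_iter)
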