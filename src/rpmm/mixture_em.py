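"""Robust point matching with a mixture of RKHS displacement fields (RPM-MM).

Given putative correspondences ``(x_i, y_i)`` contaminated by outliers, the
model assumes each inlier pair follows one of L smooth non-rigid motions
``T_l(x) = x + f_l(x)`` with isotropic Gaussian noise of variance sigma^2,
while outlier targets are uniform over a bounded region of volume ``a``.
Latent 1-of-(L+1) indicators select the component; smoothness of each
``f_l`` is imposed through a Gaussian-kernel RKHS prior.  MAP estimation is
performed by EM: the E-step computes responsibilities, the M-step refits the
fields (a weighted representer-theorem solve per component), the mixing
coefficients and the noise variance.  Points whose best component
responsibility exceeds a threshold tau are declared inliers.

Because several independent fields are fitted jointly, the method keeps
inliers on every motion layer — e.g. foreground and background moving
differently — where a single smooth field would discard all but one layer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .kernelspace import (
    KernelConfig,
    RbfTransform,
    kernel_matrix,
    rkhs_norm_sq,
    solve_full,
    solve_sparse,
)

__all__ = [
    "NormInfo",
    "CorrespondenceSet",
    "RpmConfig",
    "MixtureState",
    "ComponentMap",
    "MatchResult",
    "normalize",
    "kmeans_motion_init",
    "init_state",
    "e_step",
    "m_step_gamma",
    "m_step_sigma2",
    "m_step_transforms",
    "energy",
    "extract_inliers",
    "rpm_mm",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormInfo:
    """Mean vector and scalar scale of one point set's normalization."""

    mean: np.ndarray
    scale: float

    def forward(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=float) - self.mean) / self.scale

    def inverse(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float) * self.scale + self.mean


@dataclass
class CorrespondenceSet:
    """Paired, normalized point arrays plus the normalization metadata.

    ``X`` and ``Y`` are stored in normalized coordinates (zero mean, unit
    total variance per set); ``norm_x`` / ``norm_y`` invert the map exactly.
    """

    X: np.ndarray
    Y: np.ndarray
    norm_x: NormInfo
    norm_y: NormInfo

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class RpmConfig:
    """Tunable parameters of the matcher.

    lam and beta jointly control smoothness regularization (lam trades data
    fit against field smoothness; beta sets the interaction range of the
    kernel); tau is the responsibility threshold declaring a pair an inlier.
    All defaults are expressed for normalized (unit-variance) coordinates.
    """

    beta: float = 0.1
    lam: float = 3.0
    tau: float = 0.75
    a_mode: str = "bbox"          # uniform-outlier constant: bbox volume or fixed
    a_fixed: float = 10.0
    kmeans_K: int = 5
    cluster_ratio: float = 0.2
    max_iter: int = 100
    tol: float = 1e-5
    sigma2_floor: float = 1e-8
    fast: bool = False
    n_basis: int = 15
    seed: int = 0
    prune_gamma: float = 1e-3
    jitter: float = 1e-10
    gamma_outlier_init: float = 0.1
    merge_dist: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.tau < 1:
            raise ValueError("tau must lie in (0, 1)")
        if self.kmeans_K < 1:
            raise ValueError("kmeans_K must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0 < self.cluster_ratio <= 1:
            raise ValueError("cluster_ratio must lie in (0, 1]")
        if self.a_mode not in ("bbox", "fixed"):
            raise ValueError("a_mode must be 'bbox' or 'fixed'")

    @property
    def kernel(self) -> KernelConfig:
        return KernelConfig(beta=self.beta, jitter=self.jitter)


@dataclass
class MixtureState:
    """EM posterior state: responsibilities, mixture weights, noise, fields."""

    P: np.ndarray                    # N x (L+1); last column = outlier
    gammas: np.ndarray               # length L+1, sums to 1
    sigma2: float
    transforms: list                 # L RbfTransforms (normalized coordinates)
    a: float                         # uniform-outlier density constant 1/a
    L: int
    # energy of each EM iteration; non-increasing within a phase.  A
    # component merge starts a new phase (the model changes), so the full
    # history is a list of monotone traces; energy_trace is the last phase.
    energy_phases: list = field(default_factory=list)

    @property
    def energy_trace(self) -> list:
        return self.energy_phases[-1] if self.energy_phases else []


@dataclass
class ComponentMap:
    """A fitted component transform evaluable at original coordinates.

    Wraps a normalized-space :class:`RbfTransform` together with the two
    normalization maps: points are normalized with the X-set parameters,
    transformed, and denormalized with the Y-set parameters.
    """

    transform: RbfTransform
    norm_x: NormInfo
    norm_y: NormInfo

    def __call__(self, Q: np.ndarray) -> np.ndarray:
        return self.norm_y.inverse(self.transform(self.norm_x.forward(Q)))


@dataclass
class MatchResult:
    """Output of :func:`rpm_mm`.

    ``labels[i]`` is the component index (1..L) of pair i, or 0 for an
    outlier.  ``transforms`` hold the L fitted motions as maps on original
    coordinates; ``state`` exposes the final EM posterior (normalized
    coordinates), including the energy trace and sigma^2.
    """

    labels: np.ndarray
    transforms: list
    state: MixtureState
    config: RpmConfig
    converged: bool
    n_iter: int
    cs: CorrespondenceSet

    @property
    def n_inliers(self) -> int:
        return int(np.sum(self.labels > 0))

    @property
    def sigma_original(self) -> float:
        """Noise std-dev mapped back to the Y set's original units."""
        return float(np.sqrt(self.state.sigma2) * self.cs.norm_y.scale)


def normalize(X: np.ndarray, Y: np.ndarray) -> CorrespondenceSet:
    """Linear re-scaling so each set has zero mean and unit total variance.

    One scalar scale per set (isotropic): ``s^2 = mean_i ||x_i - mu||^2``.
    Preserves shape; the stored :class:`NormInfo` inverts the map exactly.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape != Y.shape:
        raise ValueError(f"X {X.shape} and Y {Y.shape} must have identical shapes")
    if X.shape[0] < 2:
        raise ValueError("need at least two correspondences")

    infos = []
    out = []
    for A in (X, Y):
        mu = A.mean(axis=0)
        s = np.sqrt(np.mean(np.sum((A - mu) ** 2, axis=1)))
        if s <= 0:
            raise ValueError("degenerate point set: all points identical")
        infos.append(NormInfo(mean=mu, scale=float(s)))
        out.append((A - mu) / s)
    return CorrespondenceSet(X=out[0], Y=out[1], norm_x=infos[0], norm_y=infos[1])


def kmeans_motion_init(cs: CorrespondenceSet, cfg: RpmConfig) -> tuple[np.ndarray, int]:
    """Cluster motion vectors ``y_i - x_i`` to seed the mixture components.

    K-means (k-means++ seeding, 10 restarts) on the motion-field samples;
    clusters whose size is at least ``cluster_ratio`` times the largest
    cluster's size become components 1..L (decreasing size); members of the
    discarded small clusters start as outliers (label 0).
    """
    if cfg.kmeans_K > cs.n:
        raise ValueError("kmeans_K cannot exceed the number of correspondences")
    V = cs.Y - cs.X
    if V.std() < 1e-9:
        # one common motion (numerically): a single component, no outliers
        return np.ones(cs.n, dtype=int), 1
    n_distinct = np.unique(V, axis=0).shape[0]
    k = min(cfg.kmeans_K, cs.n, n_distinct)
    with warnings.catch_warnings():
        # fewer distinct motions than clusters is fine: empty clusters drop
        warnings.simplefilter("ignore")
        km = KMeans(n_clusters=k, n_init=10, random_state=cfg.seed % (2**31)).fit(V)
    assign = km.labels_
    sizes = np.bincount(assign, minlength=k)
    largest = sizes.max()
    # components ordered by decreasing size; stable on ties
    kept = [c for c in np.argsort(-sizes, kind="stable") if sizes[c] >= cfg.cluster_ratio * largest]
    labels0 = np.zeros(cs.n, dtype=int)
    for comp, c in enumerate(kept, start=1):
        labels0[assign == c] = comp
    return labels0, len(kept)


def _bbox_volume(pts: np.ndarray) -> float:
    ext = pts.max(axis=0) - pts.min(axis=0)
    return float(np.prod(np.maximum(ext, 1e-12)))


def init_state(cs: CorrespondenceSet, labels0: np.ndarray, cfg: RpmConfig) -> MixtureState:
    """Build the initial EM state from hard cluster labels.

    Responsibilities are the one-hot encoding of ``labels0``; gammas and
    sigma^2 follow from the usual M-step formulas with all transforms
    initialized to the identity (zero displacement coefficients).
    """
    labels0 = np.asarray(labels0, dtype=int)
    L = int(labels0.max(initial=0))
    if L == 0:
        raise ValueError("no initial inliers: every correspondence was discarded")
    n = cs.n
    P = np.zeros((n, L + 1))
    P[labels0 == 0, L] = 1.0
    for l in range(1, L + 1):
        P[labels0 == l, l - 1] = 1.0

    transforms = [RbfTransform.identity(cs.X, cfg.beta) for _ in range(L)]
    a = _bbox_volume(cs.Y) if cfg.a_mode == "bbox" else float(cfg.a_fixed)
    gammas = m_step_gamma(P)
    if gammas[-1] == 0:
        # a dead outlier class can never regain mass under the gamma update;
        # give it a small prior weight when clustering discarded nothing
        gammas = np.r_[gammas[:-1] * (1 - cfg.gamma_outlier_init),
                       cfg.gamma_outlier_init]
    state = MixtureState(P=P, gammas=gammas, sigma2=1.0,
                         transforms=transforms, a=a, L=L)
    state.sigma2 = m_step_sigma2(cs, state, cfg.sigma2_floor)
    return state


class _KernelCache:
    """Kernel blocks computed once per run and shared across EM iterations.

    In full mode holds K = k(X, X); in fast mode the cross and basis blocks
    U = k(X, X_b), V = k(X_b, X_b).  Field values at the data points are then
    matrix products with the cached block.
    """

    def __init__(self, cs: CorrespondenceSet, cfg: RpmConfig,
                 basis_idx: np.ndarray | None):
        self.basis_idx = basis_idx
        if cfg.fast and basis_idx is not None:
            Xb = cs.X[basis_idx]
            self.G = kernel_matrix(cs.X, Xb, cfg.beta)
            self.V = kernel_matrix(Xb, Xb, cfg.beta)
        else:
            self.G = kernel_matrix(cs.X, cs.X, cfg.beta)
            self.V = None


def _predictions(cs: CorrespondenceSet, state: MixtureState,
                 cache: _KernelCache | None) -> list:
    """T_l(X) for every component, via the cache when available."""
    if cache is None:
        return [t(cs.X) for t in state.transforms]
    return [cs.X + cache.G @ t.coeffs for t in state.transforms]


def e_step(cs: CorrespondenceSet, state: MixtureState, cfg: RpmConfig,
           cache: _KernelCache | None = None) -> np.ndarray:
    """Posterior responsibilities via Bayes' rule, computed in log space.

    ``p_il`` is proportional to gamma_l times the Gaussian density of the
    residual ``y_i - T_l(x_i)``; the outlier column is proportional to
    gamma_{L+1} / a.  Each row is normalized to sum to one.
    """
    if state.sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    log_p = _log_densities(cs, state, cache)
    tot = logsumexp(log_p, axis=1)
    bad = ~np.isfinite(tot)
    if np.any(bad):
        warnings.warn("zero total density for some rows; assigning them to the outlier class")
        log_p[bad] = -np.inf
        log_p[bad, state.L] = 0.0
        tot[bad] = 0.0
    return np.exp(log_p - tot[:, None])


def _log_densities(cs: CorrespondenceSet, state: MixtureState,
                   cache: _KernelCache | None = None) -> np.ndarray:
    """Per-pair, per-class log of (mixing weight times class density)."""
    n, D, L = cs.n, cs.dim, state.L
    log_p = np.empty((n, L + 1))
    with np.errstate(divide="ignore"):
        log_gam = np.log(state.gammas)
    norm_const = -0.5 * D * np.log(2 * np.pi * state.sigma2)
    preds = _predictions(cs, state, cache)
    for l in range(L):
        r2 = np.sum((cs.Y - preds[l]) ** 2, axis=1)
        log_p[:, l] = log_gam[l] + norm_const - r2 / (2 * state.sigma2)
    log_p[:, L] = log_gam[L] - np.log(state.a)
    return log_p


def m_step_gamma(P: np.ndarray) -> np.ndarray:
    """Mixing coefficients: column means of the responsibilities."""
    return P.mean(axis=0)


def m_step_sigma2(cs: CorrespondenceSet, state: MixtureState,
                  floor: float = 1e-8, cache: _KernelCache | None = None) -> float:
    """Noise variance update: responsibility-weighted mean squared residual / D."""
    num = 0.0
    den = 0.0
    preds = _predictions(cs, state, cache)
    for l in range(state.L):
        p = state.P[:, l]
        r2 = np.sum((cs.Y - preds[l]) ** 2, axis=1)
        num += float(p @ r2)
        den += float(p.sum())
    if den <= 0:
        warnings.warn("no inlier mass; sigma2 fell back to its floor")
        return floor
    return max(num / (cs.dim * den), floor)


def m_step_transforms(
    cs: CorrespondenceSet,
    state: MixtureState,
    cfg: RpmConfig,
    basis_idx: np.ndarray | None = None,
    cache: _KernelCache | None = None,
) -> list:
    """Refit every component's displacement field with soft weights.

    Each field is fitted on all N points weighted by that component's
    responsibility column, with displacement targets ``Y - X``.  In fast
    mode the subset-of-regressors solve uses ``basis_idx`` (fixed across
    EM iterations).
    """
    Ydisp = cs.Y - cs.X
    kernel = cfg.kernel
    out = []
    for l in range(state.L):
        p = state.P[:, l]
        if cfg.fast:
            if basis_idx is None:
                raise ValueError("fast mode requires basis_idx")
            UV = (cache.G, cache.V) if cache is not None else None
            out.append(solve_sparse(cs.X, Ydisp, p, state.sigma2, cfg.lam,
                                    basis_idx, kernel, UV=UV))
        else:
            K = cache.G if cache is not None else None
            C = solve_full(cs.X, Ydisp, p, state.sigma2, cfg.lam, kernel, K=K)
            out.append(RbfTransform(basis=cs.X, coeffs=C, beta=cfg.beta))
    return out


def energy(cs: CorrespondenceSet, state: MixtureState, cfg: RpmConfig,
           cache: _KernelCache | None = None) -> float:
    """Negative log posterior: mixture data term plus the RKHS regularizer.

    ``-sum_i log[ sum_l gamma_l N(y_i | T_l(x_i), sigma2 I) + gamma_{L+1}/a ]
    + (lam/2) sum_l ||f_l||^2_H``.  Non-increasing across EM iterations.
    """
    log_p = _log_densities(cs, state, cache)
    data_term = -float(np.sum(logsumexp(log_p, axis=1)))
    reg = 0.5 * cfg.lam * sum(rkhs_norm_sq(t) for t in state.transforms)
    return data_term + reg


def extract_inliers(P: np.ndarray, tau: float) -> np.ndarray:
    """Hard labels from responsibilities with threshold tau.

    Pair i gets the index of its best non-outlier component (1-based) when
    that responsibility exceeds tau, else 0.  Ties break to the smallest
    component index (argmax semantics).
    """
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    comp = P[:, :-1]
    best = comp.argmax(axis=1)
    labels = np.where(comp[np.arange(P.shape[0]), best] > tau, best + 1, 0)
    return labels.astype(int)


def _merge_once(cs: CorrespondenceSet, state: MixtureState, cfg: RpmConfig,
                cache: _KernelCache | None = None) -> bool:
    """Merge the closest pair of near-duplicate components, if any.

    Several mixture components can converge onto the same motion (K-means
    over-segments a single layer), splitting its responsibilities and
    starving the inlier threshold.  Two components are duplicates when their
    fields agree, on the points either one claims, to within
    ``merge_dist`` times the noise scale — well below the separation of
    genuinely distinct layers.  The merged component takes the summed
    responsibilities and mixing weight; True is returned if a merge happened.
    """
    if state.L < 2:
        return False
    preds = _predictions(cs, state, cache)
    best = None
    sigma = np.sqrt(state.sigma2)
    for l in range(state.L):
        for m in range(l + 1, state.L):
            w = state.P[:, l] + state.P[:, m]
            tot = w.sum()
            if tot <= 0:
                gap = 0.0
            else:
                gap = np.sqrt(
                    float(w @ np.sum((preds[l] - preds[m]) ** 2, axis=1)) / tot
                )
            if gap < cfg.merge_dist * sigma and (best is None or gap < best[0]):
                best = (gap, l, m)
    if best is None:
        return False
    _, l, m = best
    keep = [c for c in range(state.L) if c != m]
    state.P[:, l] += state.P[:, m]
    state.P = state.P[:, keep + [state.L]]
    g = state.gammas.copy()
    g[l] += g[m]
    state.gammas = g[keep + [state.L]]
    state.transforms = [state.transforms[c] for c in keep]
    state.L -= 1
    return True


def _prune(state: MixtureState, cfg: RpmConfig) -> MixtureState:
    """Drop components with negligible mixing weight; renormalize gammas."""
    keep = [l for l in range(state.L) if state.gammas[l] >= cfg.prune_gamma]
    if len(keep) == state.L:
        return state
    cols = keep + [state.L]
    gammas = state.gammas[cols]
    total = gammas.sum()
    gammas = gammas / total if total > 0 else np.r_[np.zeros(len(keep)), 1.0]
    P = state.P[:, cols]
    rs = P.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    return MixtureState(
        P=P / rs,
        gammas=gammas,
        sigma2=state.sigma2,
        transforms=[state.transforms[l] for l in keep],
        a=state.a,
        L=len(keep),
        energy_phases=state.energy_phases,
    )


def rpm_mm(X: np.ndarray, Y: np.ndarray, cfg: RpmConfig | None = None) -> MatchResult:
    """Fit the mixture of displacement fields and label each pair.

    Pipeline: normalize both sets, seed components by K-means on motion
    vectors, then iterate E-step / field refits / gamma and sigma^2 updates
    until the relative change of the MAP energy drops below ``tol`` (or
    ``max_iter`` is reached).  Components with negligible weight are pruned
    before the final labeling.
    """
    if cfg is None:
        cfg = RpmConfig()
    cs = normalize(X, Y)
    labels0, L = kmeans_motion_init(cs, cfg)
    if L == 0 or not np.any(labels0 > 0):
        raise ValueError("no initial inliers: K-means produced no usable clusters")
    state = init_state(cs, labels0, cfg)

    basis_idx = None
    if cfg.fast:
        rng = np.random.default_rng(cfg.seed)
        m = min(cfg.n_basis, cs.n)
        basis_idx = rng.choice(cs.n, size=m, replace=False)
    cache = _KernelCache(cs, cfg, basis_idx)

    # The hard cluster assignment plays the role of the first E-step: fit the
    # component fields from it before any soft update, otherwise the identical
    # identity transforms make the first E-step erase the initialization.
    state.transforms = m_step_transforms(cs, state, cfg, basis_idx, cache)
    state.sigma2 = m_step_sigma2(cs, state, cfg.sigma2_floor, cache)

    def em_phase() -> tuple[bool, int]:
        trace: list[float] = []
        state.energy_phases.append(trace)
        for it in range(1, cfg.max_iter + 1):
            state.P = e_step(cs, state, cfg, cache)
            state.transforms = m_step_transforms(cs, state, cfg, basis_idx, cache)
            state.gammas = m_step_gamma(state.P)
            state.sigma2 = m_step_sigma2(cs, state, cfg.sigma2_floor, cache)
            e = energy(cs, state, cfg, cache)
            trace.append(e)
            if len(trace) >= 2:
                prev = trace[-2]
                if abs(prev - e) < cfg.tol * max(abs(prev), 1.0):
                    return True, it
        return False, cfg.max_iter

    converged, it = em_phase()
    # collapse near-duplicate components, re-converging after each merge
    while _merge_once(cs, state, cfg, cache):
        state.transforms = m_step_transforms(cs, state, cfg, basis_idx, cache)
        state.sigma2 = m_step_sigma2(cs, state, cfg.sigma2_floor, cache)
        converged, more = em_phase()
        it += more

    state = _prune(state, cfg)
    if state.L == 0:
        logger.warning("all mixture components pruned; labeling every pair an outlier")
        labels = np.zeros(cs.n, dtype=int)
    else:
        state.P = e_step(cs, state, cfg, cache)
        labels = extract_inliers(state.P, cfg.tau)

    maps = [ComponentMap(t, cs.norm_x, cs.norm_y) for t in state.transforms]
    return MatchResult(labels=labels, transforms=maps, state=state, config=cfg,
                       converged=converged, n_iter=it, cs=cs)
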