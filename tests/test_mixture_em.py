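"""Normalization, K-means seeding, EM updates, and the full matcher."""

import numpy as np
import pytest

from rpmm.kernelspace import RbfTransform
from rpmm.mixture_em import (
    CorrespondenceSet,
    MixtureState,
    NormInfo,
    RpmConfig,
    e_step,
    energy,
    extract_inliers,
    init_state,
    kmeans_motion_init,
    m_step_gamma,
    m_step_sigma2,
    m_step_transforms,
    normalize,
    rpm_mm,
)
from rpmm.synthetic import make_multilayer_scene


def _state_for(cs, labels0, cfg=None):
    return init_state(cs, labels0, cfg or RpmConfig())


class TestNormalize:
    def test_zero_mean_unit_variance(self):
        cs = normalize(np.array([[0.0, 0.0], [2.0, 0.0]]),
                       np.array([[1.0, 1.0], [3.0, 5.0]]))
        for A in (cs.X, cs.Y):
            assert np.allclose(A.mean(axis=0), 0.0, atol=1e-12)
            assert np.mean(np.sum(A**2, axis=1)) == pytest.approx(1.0)

    def test_round_trip_exact(self, rng):
        X = rng.normal(3.0, 2.5, size=(20, 2))
        Y = rng.normal(-1.0, 0.5, size=(20, 2))
        cs = normalize(X, Y)
        assert np.allclose(cs.norm_x.inverse(cs.X), X, atol=1e-12)
        assert np.allclose(cs.norm_y.inverse(cs.Y), Y, atol=1e-12)

    def test_idempotent_on_normalized_input(self, rng):
        X = rng.normal(size=(30, 2))
        cs = normalize(X, X.copy())
        cs2 = normalize(cs.X, cs.Y)
        assert np.allclose(cs2.X, cs.X, atol=1e-12)

    def test_degenerate_set_rejected(self):
        pts = np.ones((5, 2))
        with pytest.raises(ValueError, match="degenerate"):
            normalize(pts, np.random.default_rng(0).normal(size=(5, 2)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="identical shapes"):
            normalize(np.zeros((4, 2)), np.zeros((5, 2)))


class TestKmeansInit:
    def test_identical_motion_single_component(self, rng):
        X = rng.normal(size=(30, 2))
        cs = normalize(X, X + [1.0, 0.5])
        labels0, L = kmeans_motion_init(cs, RpmConfig(seed=0))
        assert L == 1
        assert np.all(labels0 == 1)

    def test_two_modes_recovered(self, rng):
        # two tight motion modes (separation >= 10x the noise scale),
        # 50 points each, plus 10 broadly scattered vectors; built directly
        # in motion space so the modes stay tight
        X = rng.uniform(-1, 1, size=(110, 2))
        Y = X.copy()
        Y[:50] += [0.5, 0.0] + rng.normal(scale=0.02, size=(50, 2))
        Y[50:100] += [-0.5, 0.4] + rng.normal(scale=0.02, size=(50, 2))
        Y[100:] += rng.uniform(-1.5, 1.5, size=(10, 2))
        ni = NormInfo(mean=np.zeros(2), scale=1.0)
        cs = CorrespondenceSet(X=X, Y=Y, norm_x=ni, norm_y=ni)
        labels0, L = kmeans_motion_init(
            cs, RpmConfig(seed=1, kmeans_K=5, cluster_ratio=0.2))
        assert L == 2
        assigned = np.mean(labels0[:100] > 0)
        assert assigned >= 0.95

    def test_ratio_one_keeps_only_largest(self, rng):
        X = rng.uniform(-1, 1, size=(60, 2))
        Y = X.copy()
        Y[:40] += [1.0, 0.0] + rng.normal(scale=0.01, size=(40, 2))
        Y[40:] += [-1.0, 0.0] + rng.normal(scale=0.01, size=(20, 2))
        cs = normalize(X, Y)
        _, L = kmeans_motion_init(
            cs, RpmConfig(seed=0, kmeans_K=2, cluster_ratio=1.0))
        assert L == 1


class TestInitState:
    def test_gamma_count_ratio(self, rng):
        X = rng.normal(size=(4, 2))
        cs = normalize(X, X + rng.normal(size=(4, 2)))
        state = _state_for(cs, np.array([1, 1, 0, 0]))
        assert state.gammas[0] == pytest.approx(0.5)
        assert state.gammas[-1] == pytest.approx(0.5)

    def test_sigma2_from_motion_norms(self):
        # two inliers with squared motions 1 and 3 in D=2 -> sigma2 = 1
        X = np.array([[0.0, 0.0], [1.0, 1.0], [5.0, 5.0]])
        Y = X + np.array([[1.0, 0.0], [1.0, np.sqrt(2.0)], [0.0, 0.0]])
        ni = NormInfo(mean=np.zeros(2), scale=1.0)
        cs = CorrespondenceSet(X=X, Y=Y, norm_x=ni, norm_y=ni)
        state = _state_for(cs, np.array([1, 1, 0]))
        assert state.sigma2 == pytest.approx(1.0)

    def test_bbox_outlier_constant(self):
        X = np.array([[-2.0, -2.0], [2.0, 2.0], [0.0, 0.0]])
        ni = NormInfo(mean=np.zeros(2), scale=1.0)
        cs = CorrespondenceSet(X=X, Y=X.copy(), norm_x=ni, norm_y=ni)
        state = _state_for(cs, np.array([1, 1, 0]))
        assert state.a == pytest.approx(16.0)

    def test_no_initial_inliers_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        cs = normalize(X, X + rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match="no initial inliers"):
            _state_for(cs, np.zeros(5, dtype=int))


class TestEStep:
    def _tiny_state(self, cs, sigma2, a, gammas):
        L = len(gammas) - 1
        return MixtureState(
            P=np.zeros((cs.n, L + 1)), gammas=np.asarray(gammas), sigma2=sigma2,
            transforms=[RbfTransform.identity(cs.X, 1.0) for _ in range(L)],
            a=a, L=L)

    def test_equal_densities_give_half(self):
        # 1-D, zero residual, sigma2 = 1/(2 pi): inlier density = 1 = 1/a
        X = np.array([[0.0], [1.0]])
        ni = NormInfo(mean=np.zeros(1), scale=1.0)
        cs = CorrespondenceSet(X=X, Y=X.copy(), norm_x=ni, norm_y=ni)
        state = self._tiny_state(cs, sigma2=1 / (2 * np.pi), a=1.0,
                                 gammas=[0.5, 0.5])
        P = e_step(cs, state, RpmConfig())
        assert np.allclose(P[:, 0], 0.5, atol=1e-12)

    def test_huge_residual_goes_to_outlier(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0]])
        Y = X + np.array([[500.0, 0.0], [500.0, 0.0]])
        ni = NormInfo(mean=np.zeros(2), scale=1.0)
        cs = CorrespondenceSet(X=X, Y=Y, norm_x=ni, norm_y=ni)
        state = self._tiny_state(cs, sigma2=1.0, a=10.0, gammas=[0.5, 0.5])
        P = e_step(cs, state, RpmConfig())
        assert np.allclose(P[:, -1], 1.0)

    def test_matches_direct_bayes_evaluation(self, rng):
        X = rng.normal(size=(6, 2))
        Y = X + rng.normal(scale=0.5, size=(6, 2))
        ni = NormInfo(mean=np.zeros(2), scale=1.0)
        cs = CorrespondenceSet(X=X, Y=Y, norm_x=ni, norm_y=ni)
        gammas = np.array([0.3, 0.45, 0.25])
        state = MixtureState(
            P=np.zeros((6, 3)), gammas=gammas, sigma2=0.2,
            transforms=[
                RbfTransform(basis=X, coeffs=rng.normal(scale=0.1, size=(6, 2)),
                             beta=0.5)
                for _ in range(2)
            ],
            a=7.0, L=2)
        P = e_step(cs, state, RpmConfig())
        # naive arithmetic oracle
        dens = np.empty((6, 3))
        for l in range(2):
            r2 = np.sum((Y - state.transforms[l](X)) ** 2, axis=1)
            dens[:, l] = gammas[l] / (2 * np.pi * 0.2) * np.exp(-r2 / 0.4)
        dens[:, 2] = gammas[2] / 7.0
        ref = dens / dens.sum(axis=1, keepdims=True)
        assert np.allclose(P, ref, atol=1e-12)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)


class TestMSteps:
    def test_gamma_is_column_mean(self):
        P = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
        g = m_step_gamma(P)
        assert g[0] == pytest.approx(0.5)
        assert g.sum() == pytest.approx(1.0)

    def test_gamma_all_outlier(self):
        P = np.zeros((5, 3))
        P[:, 2] = 1.0
        g = m_step_gamma(P)
        assert np.allclose(g, [0.0, 0.0, 1.0])

    def test_sigma2_known_residuals(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        Y = X + np.array([[1.0, 0.0], [1.0, np.sqrt(2.0)]])
        ni = NormInfo(mean=np.zeros(2), scale=1.0)
        cs = CorrespondenceSet(X=X, Y=Y, norm_x=ni, norm_y=ni)
        state = MixtureState(
            P=np.array([[1.0, 0.0], [1.0, 0.0]]), gammas=np.array([1.0, 0.0]),
            sigma2=1.0, transforms=[RbfTransform.identity(X, 1.0)], a=1.0, L=1)
        assert m_step_sigma2(cs, state) == pytest.approx(1.0)

    def test_sigma2_floor_on_zero_residuals(self, rng):
        X = rng.normal(size=(4, 2))
        ni = NormInfo(mean=np.zeros(2), scale=1.0)
        cs = CorrespondenceSet(X=X, Y=X.copy(), norm_x=ni, norm_y=ni)
        state = MixtureState(
            P=np.ones((4, 2)) * [[1.0, 0.0]], gammas=np.array([1.0, 0.0]),
            sigma2=1.0, transforms=[RbfTransform.identity(X, 1.0)], a=1.0, L=1)
        assert m_step_sigma2(cs, state, floor=1e-8) == 1e-8

    def test_sigma2_matches_double_loop(self, rng):
        X = rng.normal(size=(7, 2))
        Y = X + rng.normal(size=(7, 2))
        ni = NormInfo(mean=np.zeros(2), scale=1.0)
        cs = CorrespondenceSet(X=X, Y=Y, norm_x=ni, norm_y=ni)
        P = rng.dirichlet(np.ones(3), size=7)
        transforms = [
            RbfTransform(basis=X, coeffs=rng.normal(scale=0.2, size=(7, 2)),
                         beta=0.5)
            for _ in range(2)
        ]
        state = MixtureState(P=P, gammas=P.mean(axis=0), sigma2=1.0,
                             transforms=transforms, a=1.0, L=2)
        num = den = 0.0
        for l in range(2):
            pred = transforms[l](X)
            for i in range(7):
                num += P[i, l] * np.sum((Y[i] - pred[i]) ** 2)
                den += P[i, l]
        assert m_step_sigma2(cs, state) == pytest.approx(num / (2 * den), rel=1e-12)

    def test_transform_refit_zero_weight_identity(self, rng):
        X = rng.normal(size=(8, 2))
        Y = X + rng.normal(size=(8, 2))
        cs = normalize(X, Y)
        P = np.zeros((8, 3))
        P[:, 1] = 1.0  # all mass on component 2; component 1 empty
        state = MixtureState(P=P, gammas=P.mean(axis=0), sigma2=0.5,
                             transforms=[RbfTransform.identity(cs.X, 0.1)] * 2,
                             a=1.0, L=2)
        out = m_step_transforms(cs, state, RpmConfig())
        assert np.all(out[0].coeffs == 0)
        assert not np.all(out[1].coeffs == 0)

    def test_disjoint_supports_fit_independently(self, rng):
        X = rng.uniform(-1, 1, size=(40, 2))
        Y = X + rng.normal(scale=0.3, size=(40, 2))
        ni = NormInfo(mean=np.zeros(2), scale=1.0)
        cs = CorrespondenceSet(X=X, Y=Y, norm_x=ni, norm_y=ni)
        P = np.zeros((40, 3))
        P[:20, 0] = 1.0
        P[20:, 1] = 1.0
        cfg = RpmConfig()
        state = MixtureState(P=P, gammas=P.mean(axis=0), sigma2=0.1,
                             transforms=[RbfTransform.identity(cs.X, cfg.beta)] * 2,
                             a=1.0, L=2)
        joint = m_step_transforms(cs, state, cfg)
        # fit each component alone on the same weights
        for l in range(2):
            alone = MixtureState(P=P[:, [l, 2]], gammas=np.array([0.5, 0.5]),
                                 sigma2=0.1,
                                 transforms=[RbfTransform.identity(cs.X, cfg.beta)],
                                 a=1.0, L=1)
            single = m_step_transforms(cs, alone, cfg)[0]
            assert np.abs(joint[l](cs.X) - single(cs.X)).max() < 1e-8


class TestEnergy:
    def _setup(self, rng, coeff_scale):
        X = rng.normal(size=(5, 2))
        Y = X + rng.normal(scale=0.4, size=(5, 2))
        ni = NormInfo(mean=np.zeros(2), scale=1.0)
        cs = CorrespondenceSet(X=X, Y=Y, norm_x=ni, norm_y=ni)
        transforms = [
            RbfTransform(basis=X, coeffs=rng.normal(scale=coeff_scale, size=(5, 2)),
                         beta=0.5)
        ]
        state = MixtureState(P=np.zeros((5, 2)), gammas=np.array([0.7, 0.3]),
                             sigma2=0.3, transforms=transforms, a=5.0, L=1)
        return cs, state

    def test_matches_naive_implementation(self, rng):
        cs, state = self._setup(rng, 0.2)
        cfg = RpmConfig(lam=2.0)
        pred = state.transforms[0](cs.X)
        dens = (state.gammas[0] / (2 * np.pi * 0.3)
                * np.exp(-np.sum((cs.Y - pred) ** 2, axis=1) / 0.6)
                + state.gammas[1] / 5.0)
        K = np.exp(-0.5 * np.sum(
            (cs.X[:, None, :] - cs.X[None, :, :]) ** 2, axis=2))
        C = state.transforms[0].coeffs
        ref = -np.log(dens).sum() + 0.5 * 2.0 * np.trace(C.T @ K @ C)
        assert energy(cs, state, cfg) == pytest.approx(ref, abs=1e-10)

    def test_zero_coeffs_zero_regularizer(self, rng):
        cs, state = self._setup(rng, 0.2)
        state.transforms = [RbfTransform.identity(cs.X, 0.5)]
        assert energy(cs, state, RpmConfig(lam=2.0)) == pytest.approx(
            energy(cs, state, RpmConfig(lam=200.0)))


class TestExtractInliers:
    def test_confident_component_wins(self):
        P = np.array([[0.7, 0.2, 0.1]])
        assert extract_inliers(P, 0.5)[0] == 1

    def test_below_threshold_is_outlier(self):
        P = np.array([[0.4, 0.4, 0.2]])
        assert extract_inliers(P, 0.5)[0] == 0

    def test_tiny_tau_keeps_everything_with_mass(self):
        P = np.array([[0.01, 0.0, 0.99], [0.0, 0.0, 1.0]])
        labels = extract_inliers(P, 1e-9)
        assert labels[0] == 1
        assert labels[1] == 0

    def test_tie_breaks_to_smallest_component(self):
        P = np.array([[0.45, 0.45, 0.1]])
        assert extract_inliers(P, 0.4)[0] == 1


class TestRpmMm:
    def test_identity_motion_all_inliers(self, rng):
        X = rng.uniform(-1, 1, size=(60, 2))
        res = rpm_mm(X, X.copy(), RpmConfig(seed=0))
        assert res.state.L >= 1
        assert np.all(res.labels > 0)
        # recovered transforms are near-identity in original coordinates
        warped = res.transforms[0](X)
        assert np.abs(warped - X).max() < 1e-3

    def test_reproducible_given_seed(self):
        scene = make_multilayer_scene([50, 50], "affine", 0.02, 30, seed=7)
        r1 = rpm_mm(scene.X, scene.Y, RpmConfig(seed=3))
        r2 = rpm_mm(scene.X, scene.Y, RpmConfig(seed=3))
        assert np.array_equal(r1.labels, r2.labels)
        assert r1.state.sigma2 == r2.state.sigma2

    def test_energy_monotone_within_phases(self):
        scene = make_multilayer_scene([50, 50], "affine", 0.02, 30, seed=5)
        res = rpm_mm(scene.X, scene.Y, RpmConfig(seed=5))
        for trace in res.state.energy_phases:
            e = np.asarray(trace)
            if len(e) > 1:
                assert np.all(np.diff(e) <= 1e-9 * np.maximum(np.abs(e[:-1]), 1.0))

    def test_responsibilities_and_gammas_normalized(self):
        scene = make_multilayer_scene([40, 40], "affine", 0.02, 20, seed=2)
        res = rpm_mm(scene.X, scene.Y, RpmConfig(seed=2))
        assert np.allclose(res.state.P.sum(axis=1), 1.0, atol=1e-9)
        assert res.state.gammas.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(res.state.P >= 0) and np.all(res.state.P <= 1 + 1e-12)

    def test_single_layer_separates_outliers(self):
        scene = make_multilayer_scene([120], "affine", 0.02, 60, seed=4)
        res = rpm_mm(scene.X, scene.Y, RpmConfig(seed=4))
        inl = res.labels > 0
        true = scene.true_labels > 0
        agree = np.mean(inl == true)
        assert agree >= 0.95
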