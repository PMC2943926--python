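"""Thin-plate splines, bending energy, relative warps, consensus shapes, PCoA."""

import numpy as np
import pytest

from conftest import random_configuration
from gryllomorph import (
    Configuration,
    align_pair,
    bending_energy,
    genus_consensus,
    gpa,
    pcoa,
    preshape,
    quadrant_of,
    relative_warps,
    tps_warp,
)
from gryllomorph.phenetics import DistanceMatrix


class TestGenusConsensus:
    def test_monotypic_genus_returns_normalized_member(self, rng):
        c = random_configuration(rng)
        out = genus_consensus({"G": [c]})
        np.testing.assert_allclose(out["G"].points, preshape(c), atol=1e-12)
        assert out["G"].specimen_id == "G"

    def test_symmetric_pair_averages_to_the_mean(self, rng):
        m = preshape(random_configuration(rng, k=12))
        z = m.ravel()
        t = rng.normal(size=z.size)
        # a pure shape direction: orthogonal to the mean, to its in-plane
        # rotation generator, and to both translations, so the symmetric
        # pair has no nuisance component and its consensus is the mean
        w = (m @ np.array([[0.0, 1.0], [-1.0, 0.0]])).ravel()
        u1 = np.tile([1.0, 0.0], m.shape[0]) / np.sqrt(m.shape[0])
        u2 = np.tile([0.0, 1.0], m.shape[0]) / np.sqrt(m.shape[0])
        for v in (z, w / np.linalg.norm(w), u1, u2):
            t -= v * (v @ t)
        t *= 1e-3 / np.linalg.norm(t)
        plus = (z + t) / np.linalg.norm(z + t)
        minus = (z - t) / np.linalg.norm(z - t)
        out = genus_consensus(
            {"G": [Configuration(plus.reshape(-1, 2)), Configuration(minus.reshape(-1, 2))]}
        )
        _, d = align_pair(out["G"], Configuration(m))
        assert d == pytest.approx(0.0, abs=1e-8)

    def test_invariant_to_member_order(self, rng):
        base = random_configuration(rng, k=8)
        members = [
            Configuration(base.points + rng.normal(scale=0.05, size=(8, 2)))
            for _ in range(5)
        ]
        a = genus_consensus({"G": members})["G"]
        b = genus_consensus({"G": members[::-1]})["G"]
        _, d = align_pair(a, b)
        assert d == pytest.approx(0.0, abs=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="no members"):
            genus_consensus({"G": []})


class TestBendingEnergy:
    @pytest.fixture
    def model(self, rng):
        return bending_energy(random_configuration(rng, k=10))

    def test_symmetric(self, model):
        np.testing.assert_allclose(model.energy_matrix, model.energy_matrix.T, atol=1e-10)

    def test_exactly_three_zero_eigenvalues(self, model):
        lam = model.eigenvalues
        scale = lam[0]
        assert np.sum(np.abs(lam) <= 1e-8 * scale) == 3
        assert np.all(lam >= -1e-8 * scale)  # positive semidefinite

    def test_affine_fields_have_zero_energy(self, model, rng):
        p = model.reference.points
        a = rng.normal(size=2)
        b = rng.normal(size=(2, 2))
        disp = a + p @ b  # affine displacement field sampled at the landmarks
        for w in disp.T:
            assert abs(w @ model.energy_matrix @ w) < 1e-9

    def test_coincident_landmarks_rejected(self):
        pts = np.array([[0.0, 0.0], [1, 0], [1, 0], [0, 1]])
        with pytest.raises(ValueError, match="[cC]oincident"):
            bending_energy(Configuration(pts))


class TestTpsWarp:
    def test_identity_when_source_equals_target(self, rng):
        c = random_configuration(rng)
        q = rng.normal(size=(20, 2))
        np.testing.assert_allclose(tps_warp(c, c, q), q, atol=1e-9)

    def test_exact_landmark_interpolation(self, rng):
        src = random_configuration(rng, k=9)
        tgt = random_configuration(rng, k=9)
        np.testing.assert_allclose(tps_warp(src, tgt, src.points), tgt.points, atol=1e-9)

    def test_affine_target_matches_fitted_affine_oracle(self, rng):
        src = random_configuration(rng, k=8)
        amat = np.array([[1.2, 0.3], [-0.1, 0.8]])
        shift = np.array([0.5, -1.0])
        tgt = Configuration(src.points @ amat + shift)
        q = rng.normal(size=(30, 2))
        # independent least-squares affine fit of the landmark correspondence
        design = np.column_stack([np.ones(src.k), src.points])
        coef, *_ = np.linalg.lstsq(design, tgt.points, rcond=None)
        oracle = np.column_stack([np.ones(len(q)), q]) @ coef
        np.testing.assert_allclose(tps_warp(src, tgt, q), oracle, atol=1e-8)

    def test_matches_scipy_thin_plate_rbf(self, rng):
        from scipy.interpolate import RBFInterpolator

        src = random_configuration(rng, k=12)
        tgt = random_configuration(rng, k=12)
        q = rng.normal(size=(25, 2))
        ref = RBFInterpolator(src.points, tgt.points, kernel="thin_plate_spline")(q)
        # kernels differ by a factor 2 (r^2 log r^2 vs r^2 log r) but the
        # fitted interpolants coincide
        np.testing.assert_allclose(tps_warp(src, tgt, q), ref, atol=1e-7)


class TestRelativeWarps:
    def _aligned(self, rng, n=10, k=12, modes=None):
        base = preshape(random_configuration(rng, k=k))
        z = base.ravel()
        if modes is None:
            modes = [rng.normal(size=2 * k) for _ in range(3)]
        configs = []
        for i in range(n):
            x = z.copy()
            for j, m in enumerate(modes):
                t = m - z * (z @ m)
                t /= np.linalg.norm(t)
                amp = rng.normal(scale=0.02 / (j + 1))
                x = x + amp * t
            x /= np.linalg.norm(x)
            configs.append(Configuration(x.reshape(-1, 2), specimen_id=f"s{i}"))
        return gpa(configs)

    def test_alpha0_matches_covariance_eigen_oracle(self, rng):
        fit = self._aligned(rng)
        rw = relative_warps(fit, alpha=0.0)
        # oracle: eigenvalues of the covariance of the same tangent residuals
        z = fit.consensus.points.ravel()
        z = z / np.linalg.norm(z)
        resid = np.array(
            [c.points.ravel() - z * (z @ c.points.ravel()) for c in fit.aligned]
        )
        resid -= resid.mean(axis=0)
        lam = np.linalg.eigvalsh(resid.T @ resid)[::-1]
        lam = lam[lam > 1e-12 * lam[0]]
        pv_oracle = 100.0 * lam / lam.sum()
        np.testing.assert_allclose(rw.percent_variance[: len(pv_oracle)], pv_oracle, atol=1e-8)

    def test_single_mode_concentrates_variance_on_rw1(self, rng):
        fit = self._aligned(rng, n=12, modes=[rng.normal(size=24)])
        rw = relative_warps(fit, alpha=0.0)
        assert rw.percent_variance[0] >= 99.9

    def test_percent_variance_sums_to_100(self, rng):
        rw = relative_warps(self._aligned(rng), alpha=0.0)
        assert rw.percent_variance.sum() == pytest.approx(100.0, abs=1e-6)

    def test_score_columns_uncorrelated(self, rng):
        rw = relative_warps(self._aligned(rng), alpha=0.0)
        cov = rw.scores.T @ rw.scores
        off = cov - np.diag(np.diag(cov))
        np.testing.assert_allclose(off, 0.0, atol=1e-8)

    def test_rank_bound(self, rng):
        n, k = 6, 20
        rw = relative_warps(self._aligned(rng, n=n, k=k), alpha=0.0)
        assert len(rw.singular_values) <= min(n - 1, 2 * k - 4)

    def test_sign_convention_is_deterministic(self, rng):
        fit = self._aligned(rng)
        a = relative_warps(fit, alpha=0.0)
        b = relative_warps(fit, alpha=0.0)
        np.testing.assert_array_equal(a.scores, b.scores)
        for vec in a.warp_vectors:
            assert vec[np.argmax(np.abs(vec))] > 0

    def test_nonzero_alpha_drops_affine_and_runs(self, rng):
        rw = relative_warps(self._aligned(rng), alpha=1.0)
        assert rw.percent_variance.sum() == pytest.approx(100.0, abs=1e-6)

    def test_fewer_than_three_rejected(self, rng):
        fit = gpa([random_configuration(rng) for _ in range(2)])
        with pytest.raises(ValueError):
            relative_warps(fit)


@pytest.mark.parametrize(
    "pt, quad",
    [
        ((1.0, 1.0), "I"),
        ((-1.0, 1.0), "II"),
        ((-1.0, -1.0), "III"),
        ((1.0, -1.0), "IV"),
        ((0.0, 3.0), "axis"),
        ((2.0, 0.0), "axis"),
    ],
)
def test_quadrant_of(pt, quad):
    assert quadrant_of(pt) == quad


class TestPcoa:
    def test_recovers_planted_planar_coordinates(self, rng):
        pts = rng.normal(size=(5, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix(labels=[f"p{i}" for i in range(5)], d=d)
        res = pcoa(dm, n_axes=2)
        # recovery is defined up to rotation/reflection of the plane
        _, dist = align_pair(
            Configuration(res.axis_scores), Configuration(pts), allow_reflection=True
        )
        assert dist == pytest.approx(0.0, abs=1e-6)

    def test_axis_scores_centered(self, rng):
        pts = rng.normal(size=(7, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix(labels=[f"p{i}" for i in range(7)], d=d), n_axes=3)
        np.testing.assert_allclose(res.axis_scores.mean(axis=0), 0.0, atol=1e-9)

    def test_all_zero_distances_give_zero_scores(self):
        dm = DistanceMatrix(labels=["a", "b", "c"], d=np.zeros((3, 3)))
        res = pcoa(dm, n_axes=2)
        np.testing.assert_array_equal(res.axis_scores, 0.0)

    def test_excess_axes_truncated_with_warning(self, rng):
        pts = rng.normal(size=(6, 1))  # rank-1 geometry: one positive axis
        d = np.abs(pts - pts.T)
        dm = DistanceMatrix(labels=[f"p{i}" for i in range(6)], d=d)
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            res = pcoa(dm, n_axes=4)
        assert res.axis_scores.shape[1] < 4

    def test_invalid_axis_count_rejected(self):
        dm = DistanceMatrix(labels=["a", "b"], d=np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            pcoa(dm, n_axes=2)
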