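"""Keypoint detection, correspondence consensus, closed-form similarity."""

import numpy as np
import pytest
from skimage.transform import SimilarityTransform, rotate

import slidealign as sa
from slidealign.errors import (DegenerateInputError,
                               InsufficientCorrespondencesError,
                               InvalidInputError)
from slidealign.registration import (detect_keypoints, estimate_global,
                                     estimate_rotation, estimate_scale,
                                     estimate_translation,
                                     match_correspondences, warp_low_level)
from slidealign.transform import rotation_about_axis

import _oracles


def _phantom_feature(seed=5, canvas=1024, n_glands=5):
    spec = sa.PhantomSpec(seed=seed, canvas=(canvas, canvas),
                          n_glands=n_glands, gland_radius=(30, 60))
    geom = sa.generate_geometry(spec)
    return sa.extract_cytoplasm_feature(sa.render_stain(geom, spec.profile_a))


def _random_similarity_pair(rng, n=15, angle=25.0, scale=1.2,
                            shift=(40.0, -25.0), noise=0.0):
    """Source points Q and targets P = S R Q + T (exact or jittered)."""
    Q = rng.uniform(0, 400, (n, 2))
    R = rotation_about_axis(angle)
    Pyx = scale * (Q[:, ::-1] @ R[:2, :2].T) + np.array([shift[1], shift[0]])
    P = Pyx[:, ::-1]
    if noise:
        P = P + rng.normal(0, noise, P.shape)
    return P, Q, R


class TestDetect:
    def test_uniform_image_empty(self):
        ks = detect_keypoints(np.full((128, 128), 80, dtype=np.uint8))
        assert len(ks) == 0

    def test_gaussian_blob_near_dog_argmax(self):
        yy, xx = np.mgrid[0:256, 0:256]
        img = 200 * np.exp(-(((yy - 100) ** 2 + (xx - 140) ** 2)
                             / (2 * 8.0 ** 2)))
        ks = detect_keypoints(img.astype(np.uint8))
        assert len(ks) > 0
        oy, ox = _oracles.dog_strongest_extremum(img)
        d = np.linalg.norm(ks.xy - np.array([ox, oy]), axis=1)
        assert d.min() <= 2.0

    def test_deterministic_on_identical_input(self):
        f = _phantom_feature()
        a, b = detect_keypoints(f), detect_keypoints(f.data.copy())
        assert np.array_equal(a.xy, b.xy)
        assert np.array_equal(a.descriptors, b.descriptors)
        assert np.all((a.xy[:, 0] >= 0) & (a.xy[:, 0] < f.data.shape[1]))
        assert np.all((a.xy[:, 1] >= 0) & (a.xy[:, 1] < f.data.shape[0]))


class TestMatch:
    def test_self_match_is_identity(self):
        f = _phantom_feature()
        ks = detect_keypoints(f)
        corr = match_correspondences(ks, ks, seed=0)
        assert np.median(corr.residuals) < 0.5
        S = estimate_scale(corr.target_xy, corr.source_xy)
        R = estimate_rotation(corr.target_xy, corr.source_xy)
        assert S == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(R, np.eye(3), atol=1e-6)

    def test_rotated_copy_consistent_with_known_rotation(self):
        f = _phantom_feature().data
        ang = 10.0
        f2 = (rotate(f.astype(float) / 255.0, ang,
                     preserve_range=True) * 255).astype(np.uint8)
        corr = match_correspondences(detect_keypoints(f),
                                     detect_keypoints(f2), seed=0)
        # skimage rotates about the center; build the known mapping
        # from rotated-image coords back to original coords
        h, w = f.shape
        known = SimilarityTransform(rotation=np.deg2rad(ang)) \
            .params  # (x, y) convention
        center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        mapped = (corr.source_xy - center) @ known[:2, :2].T + center
        d = np.linalg.norm(mapped - corr.target_xy, axis=1)
        assert (d <= 2.0).mean() >= 0.8

    def test_unstructured_noise_raises(self, rng):
        n1 = rng.integers(0, 255, (256, 256), dtype=np.uint8)
        n2 = rng.integers(0, 255, (256, 256), dtype=np.uint8)
        with pytest.raises(InsufficientCorrespondencesError):
            match_correspondences(detect_keypoints(n1), detect_keypoints(n2),
                                  seed=0)

    def test_empty_set_raises(self):
        empty = detect_keypoints(np.full((64, 64), 10, dtype=np.uint8))
        full = detect_keypoints(_phantom_feature())
        with pytest.raises(InsufficientCorrespondencesError):
            match_correspondences(empty, full, seed=0)


class TestClosedFormEstimators:
    def test_scale_identity_and_shrink(self, rng):
        P = rng.uniform(0, 100, (10, 2))
        assert estimate_scale(P, P) == pytest.approx(1.0)
        Q = (P - P.mean(axis=0)) * 0.5 + P.mean(axis=0)
        assert estimate_scale(P, Q) == pytest.approx(2.0)

    def test_scale_matches_formula_oracle(self, rng):
        P = rng.uniform(-50, 50, (12, 2))
        Q = rng.uniform(-50, 50, (12, 2))
        num = sum(np.sum((p - P.mean(axis=0)) ** 2) for p in P)
        den = sum(np.sum((q - Q.mean(axis=0)) ** 2) for q in Q)
        assert estimate_scale(P, Q) == pytest.approx(np.sqrt(num / den),
                                                     abs=1e-12)

    def test_scale_degenerate_source_raises(self):
        P = np.array([[0.0, 0.0], [1.0, 1.0]])
        Q = np.array([[2.0, 2.0], [2.0, 2.0]])
        with pytest.raises(DegenerateInputError):
            estimate_scale(P, Q)

    def test_rotation_identity(self, rng):
        P = rng.uniform(0, 100, (8, 2))
        assert np.allclose(estimate_rotation(P, P), np.eye(3), atol=1e-12)

    def test_rotation_recovers_analytic_matrix(self, rng):
        # Q is P rotated by -30 degrees about its centroid; the estimator
        # must return the +30-degree rotation mapping Q back onto P.
        P = rng.uniform(0, 100, (9, 2))
        c = P.mean(axis=0)
        Rm = rotation_about_axis(-30.0)
        Q = (P - c)[:, ::-1] @ Rm[:2, :2].T
        Q = Q[:, ::-1] + c
        R = estimate_rotation(P, Q)
        assert np.allclose(R, rotation_about_axis(30.0), atol=1e-9)

    def test_reflection_still_returns_proper_rotation(self, rng):
        P = rng.uniform(0, 100, (10, 2))
        Q = P * np.array([1.0, -1.0])  # mirrored
        R = estimate_rotation(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(R.T @ R, np.eye(3), atol=1e-9)

    def test_translation_pure_shift(self):
        P = np.array([[10.0, 20.0], [30.0, 5.0], [7.0, 9.0]])
        Q = P - np.array([7.0, 5.0])  # shift (dx, dy) = (7, 5)
        T = estimate_translation(P, Q, np.eye(3), 1.0)
        assert np.allclose(T, [5.0, 7.0, 0.0], atol=1e-12)  # (y, x, 0)
        assert estimate_translation(P, P, np.eye(3), 1.0) == \
            pytest.approx([0.0, 0.0, 0.0], abs=1e-12)

    def test_closed_form_attains_grid_search_minimum(self, rng):
        # noisy toy sets: the closed form must reach at least the best
        # residual found by exhaustive (angle, scale) sweeping
        for noise in (0.0, 1.0, 3.0):
            P, Q, _ = _random_similarity_pair(rng, n=12, angle=17.0,
                                              scale=0.95, noise=noise)
            S = estimate_scale(P, Q)
            R = estimate_rotation(P, Q)
            T = estimate_translation(P, Q, R, S)
            mine = _oracles.similarity_residual(P, Q, S, R[:2, :2], T[:2])
            grid = _oracles.grid_search_min_residual(P, Q)
            assert mine <= grid + 1e-6

    def test_agrees_with_independent_umeyama_on_exact_sets(self, rng):
        P, Q, R_true = _random_similarity_pair(rng, n=10, angle=-13.0,
                                               scale=1.07, shift=(12.0, 33.0))
        S = estimate_scale(P, Q)
        R = estimate_rotation(P, Q)
        T = estimate_translation(P, Q, R, S)
        ref = SimilarityTransform.from_estimate(Q, P)
        assert bool(ref)
        assert S == pytest.approx(ref.scale, abs=1e-9)
        assert np.rad2deg(np.arctan2(R[0, 1], R[0, 0])) == \
            pytest.approx(np.rad2deg(ref.rotation), abs=1e-9)
        # skimage translation is (x, y); ours is (y, x, 0)
        assert T[1] == pytest.approx(ref.translation[0], abs=1e-6)
        assert T[0] == pytest.approx(ref.translation[1], abs=1e-6)
        assert T[2] == 0.0
        assert np.allclose(R, R_true, atol=1e-9)

    def test_third_component_stays_inert(self, rng):
        P, Q, _ = _random_similarity_pair(rng, noise=2.0)
        R = estimate_rotation(P, Q)
        T = estimate_translation(P, Q, R, estimate_scale(P, Q))
        assert np.allclose(R[2], [0, 0, 1]) and np.allclose(R[:, 2], [0, 0, 1])
        assert T[2] == 0.0


class TestEstimateGlobal:
    def test_identical_inputs(self):
        f = _phantom_feature()
        g = estimate_global(f, f, seed=0)
        assert g.S == pytest.approx(1.0, abs=1e-3)
        assert abs(g.angle_deg) <= 0.05
        assert np.linalg.norm(g.T[:2]) < 1.0

    def test_phantom_recovery_within_tolerance(self, reg_spec, reg_pair):
        pt, ps, gt = reg_pair
        ft, fs = _oracles.low_feature_maps(pt, ps, gt)
        g = estimate_global(ft, fs, seed=1, m=reg_spec.m)
        assert abs(g.S - reg_spec.scale) / reg_spec.scale <= 0.01
        assert abs(g.angle_deg - reg_spec.angle_deg) <= 0.5
        assert np.linalg.norm(g.T[:2] - gt.transform.T[:2]) <= 2.0
        assert g.inliers >= 8 and g.mean_residual < 3.0

    def test_swapped_pair_gives_inverse(self, reg_pair, rng):
        pt, ps, gt = reg_pair
        ft, fs = _oracles.low_feature_maps(pt, ps, gt)
        g_fwd = estimate_global(ft, fs, seed=1)
        g_bwd = estimate_global(fs, ft, seed=1)
        pts = rng.uniform(100, 400, (50, 2))
        roundtrip = g_bwd.apply_xy(g_fwd.apply_xy(pts))
        assert np.linalg.norm(roundtrip - pts, axis=1).max() <= 1.5

    def test_mismatched_levels_raise(self):
        a = sa.FeatureMap(data=np.zeros((64, 64), np.uint8), level=1)
        b = sa.FeatureMap(data=np.zeros((64, 64), np.uint8), level=2)
        with pytest.raises(InvalidInputError):
            estimate_global(a, b)


class TestWarpLowLevel:
    def test_identity_bit_equal(self, reg_pair):
        _, ps, gt = reg_pair
        img = sa.fetch_region(ps, gt.l_low, 0, 0, 300, 200)
        gid = sa.GlobalTransform(S=1.0, R=np.eye(3), T=np.zeros(3),
                                 l_low=gt.l_low)
        assert np.array_equal(warp_low_level(img, gid).data, img.data)

    def test_integer_translation_exact_on_overlap(self, reg_pair):
        _, ps, gt = reg_pair
        img = sa.fetch_region(ps, gt.l_low, 0, 0, 256, 256).data
        g = sa.GlobalTransform(S=1.0, R=np.eye(3),
                               T=np.array([30.0, 50.0, 0.0]), l_low=gt.l_low)
        out = warp_low_level(sa.LevelImage(gt.l_low, img), g).data
        assert np.array_equal(out[30:, 50:], img[:-30, :-50])
        assert np.all(out[:30] == 255) and np.all(out[:, :50] == 255)

    def test_forward_then_inverse_roundtrip(self, reg_pair):
        _, ps, gt = reg_pair
        info = ps.level_info(gt.l_low)
        img = sa.fetch_region(ps, gt.l_low, 0, 0, info.width, info.height)
        g = gt.transform
        there = warp_low_level(img, g)
        back = warp_low_level(there, g.inverse()).data.astype(float)
        orig = img.data.astype(float)
        interior = slice(60, -60)
        diff = np.abs(back - orig)[interior, interior]
        assert diff.mean() <= 3.0
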