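import numpy as np
import pytest

from lvstrain.contours import ContourPointSet
from lvstrain.cost import (CostConfig, c_icp, compute_alpha_weights,
                           feature_distance, icpif_match, ssd, total_cost)
from lvstrain.transforms import AffineParams, FFDGrid, HierarchicalTransform


def pointset(points, curvatures, **kw):
    return ContourPointSet(np.asarray(points, float),
                           curvatures=np.asarray(curvatures, float), **kw)


def far_padding(n, start=500.0):
    """Inert far-away points to satisfy the 8-point contour minimum."""
    pts = [(start + 10 * i, start) for i in range(n)]
    return pts, [9.0] * n


class TestSSD:
    def test_identical_images_zero(self, rng):
        img = rng.uniform(size=(16, 16))
        assert ssd(img, img) == 0.0

    def test_unit_difference(self):
        assert ssd(np.ones((7, 5)), np.zeros((7, 5))) == 1.0

    def test_direct_substitution(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        b = np.array([[1.0, 2.0], [3.0, 0.0]])
        assert ssd(a, b) == 4.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssd(np.zeros((4, 4)), np.zeros((4, 5)))


class TestFeatureDistance:
    def test_identical_triples_zero(self):
        assert feature_distance((1, 2, 0.1), (1, 2, 0.1), 1.0, 1.0) == 0.0

    def test_positional_only(self):
        assert feature_distance((0, 0, 0.5), (3, 4, 0.9), 1.0, 0.0) == 25.0

    def test_curvature_only(self):
        d = feature_distance((0, 0, 0.05), (9, 9, 0.01), 0.0, 1.0)
        assert d == pytest.approx(0.0016)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            feature_distance((0, 0, 0), (1, 1, 1), -1.0, 0.0)


class TestAlphaWeights:
    def test_reciprocal_ranges_from_enumeration(self):
        # positional squared term range 100, curvature squared term 0.25,
        # verified by exhaustive pairwise enumeration below
        pts = [(0.0, 0.0)] * 7 + [(10.0, 0.0)]
        ks = [0.0] * 7 + [0.5]
        src = pointset(pts, ks)
        tgt = pointset(pts, ks)
        pos = np.array([[(p1[0] - p2[0])**2 + (p1[1] - p2[1])**2
                         for p2 in pts] for p1 in pts])
        feat = np.array([[(k1 - k2)**2 for k2 in ks] for k1 in ks])
        assert pos.max() - pos.min() == 100.0
        assert feat.max() - feat.min() == 0.25
        a1, a2 = compute_alpha_weights(src, tgt)
        assert (a1, a2) == (0.01, 4.0)

    def test_zero_curvature_range_gives_zero_weight(self):
        pts = [(float(i), 0.0) for i in range(8)]
        src = pointset(pts, [0.3] * 8)
        tgt = pointset(pts, [0.3] * 8)
        with pytest.warns(RuntimeWarning):
            _, a2 = compute_alpha_weights(src, tgt)
        assert a2 == 0.0

    def test_coordinate_scaling_divides_alpha1_by_square(self):
        pts = [(float(i) ** 1.3, float(i)) for i in range(8)]
        ks = np.linspace(0.0, 0.5, 8)
        a1, _ = compute_alpha_weights(pointset(pts, ks), pointset(pts, ks))
        scaled = [(2 * x, 2 * y) for x, y in pts]
        b1, _ = compute_alpha_weights(pointset(scaled, ks), pointset(scaled, ks))
        assert b1 == pytest.approx(a1 / 4.0)


class TestICPIFMatch:
    def test_identical_sets_match_identity(self):
        pts = [(np.cos(t) * 9, np.sin(t) * 9) for t in np.linspace(0, 6, 10)]
        ks = np.linspace(0.1, 0.2, 10)
        src, tgt = pointset(pts, ks), pointset(pts, ks)
        m = icpif_match(src, tgt, 1.0, 1.0)
        np.testing.assert_array_equal(m.matched_indices, np.arange(10))
        assert c_icp(m, 1.0, 1.0) == 0.0

    def test_curvature_breaks_positional_tie(self):
        # target equidistant from two candidates; curvature selects one.
        pad_pts, pad_ks = far_padding(6)
        src = pointset([(1.0, 0.0), (-1.0, 0.0)] + pad_pts,
                       [0.05, 0.30] + pad_ks)
        tgt_pad_pts, tgt_pad_ks = far_padding(7)
        tgt = pointset([(0.0, 0.0)] + tgt_pad_pts, [0.05] + tgt_pad_ks)
        m = icpif_match(src, tgt, 1.0, 1.0)
        assert m.matched_indices[0] == 0
        # enumeration oracle: distances computed longhand
        d0 = 1.0 + 0.0
        d1 = 1.0 + (0.05 - 0.30) ** 2
        assert d0 < d1

    def test_zero_feature_weight_is_plain_nearest_neighbor(self, rng):
        src_pts = rng.uniform(0, 30, size=(40, 2))
        tgt_pts = rng.uniform(0, 30, size=(25, 2))
        src = pointset(src_pts, rng.uniform(0, 1, 40))
        tgt = pointset(tgt_pts, rng.uniform(0, 1, 25))
        m = icpif_match(src, tgt, 0.7, 0.0)
        # independent plain-NN oracle
        d2 = ((tgt_pts[:, None, :] - src_pts[None, :, :]) ** 2).sum(-1)
        np.testing.assert_array_equal(m.matched_indices, d2.argmin(1))

    def test_gate_restricts_candidates_but_never_unmatches(self, rng):
        src_pts = rng.uniform(0, 30, size=(40, 2))
        tgt_pts = rng.uniform(0, 30, size=(25, 2))
        src = pointset(src_pts, rng.uniform(0, 1, 40))
        tgt = pointset(tgt_pts, rng.uniform(0, 1, 25))
        m = icpif_match(src, tgt, 1.0, 50.0, gate_radius=2.0)
        d2 = ((tgt_pts[:, None, :] - src_pts[None, :, :]) ** 2).sum(-1)
        nn = d2.argmin(1)
        for i, j in enumerate(m.matched_indices):
            assert d2[i, j] <= 4.0 or j == nn[i]

    def test_per_point_argmin_beats_random_assignments(self, rng):
        src = pointset(rng.uniform(0, 20, (30, 2)), rng.uniform(0, 0.5, 30))
        tgt = pointset(rng.uniform(0, 20, (20, 2)), rng.uniform(0, 0.5, 20))
        a1, a2 = compute_alpha_weights(src, tgt)
        m = icpif_match(src, tgt, a1, a2)
        best = c_icp(m, a1, a2)
        m1 = np.column_stack([tgt.points, tgt.curvatures])
        for _ in range(50):
            idx = rng.integers(0, 30, size=20)
            m2 = np.column_stack([src.points[idx], src.curvatures[idx]])
            assert best <= np.sum(feature_distance(m1, m2, a1, a2)) + 1e-12

    def test_empty_set_rejected(self):
        pts, ks = far_padding(8)
        with pytest.raises((ValueError, IndexError)):
            icpif_match(pointset(pts, ks), pointset([], []), 1.0, 1.0)


class TestCICP:
    def test_sum_semantics(self):
        pad_pts, pad_ks = far_padding(7)
        src = pointset([(0.0, 0.0)] + pad_pts, [0.1] + pad_ks)
        tgt = pointset([(3.0, 4.0)] + pad_pts, [0.1] + pad_ks)
        m = icpif_match(src, tgt, 1.0, 0.0)
        assert c_icp(m, 1.0, 0.0) == pytest.approx(25.0)

    def test_doubling_points_doubles_cost(self):
        t = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        for n in (16, 32):
            tt = np.linspace(0, 2 * np.pi, n, endpoint=False)
            src = pointset(np.stack([10 * np.cos(tt), 10 * np.sin(tt)], 1),
                           np.full(n, 0.1))
            tgt = pointset(np.stack([10 * np.cos(tt) + 0.5, 10 * np.sin(tt)], 1),
                           np.full(n, 0.1))
            m = icpif_match(src, tgt, 1.0, 0.0)
            if n == 16:
                base = c_icp(m, 1.0, 0.0)
            else:
                assert c_icp(m, 1.0, 0.0) == pytest.approx(2 * base, rel=0.05)


class TestTotalCost:
    def identity_transform(self, shape):
        return HierarchicalTransform(AffineParams(),
                                     FFDGrid.for_image(shape, 4.0))

    def test_identical_everything_is_zero(self, rng):
        img = rng.uniform(size=(16, 16))
        t = self.identity_transform(img.shape)
        pts = np.stack([8 + 4 * np.cos(np.linspace(0, 2 * np.pi, 12, endpoint=False)),
                        8 + 4 * np.sin(np.linspace(0, 2 * np.pi, 12, endpoint=False))], 1)
        c = ContourPointSet(pts)
        val = total_cost(img, img, t, {"endo": c}, {"endo": c},
                         CostConfig(lam=1.0))
        assert val == pytest.approx(0.0, abs=1e-18)

    def test_lambda_zero_reduces_to_ssd(self, rng):
        a = rng.uniform(size=(12, 12))
        b = rng.uniform(size=(12, 12))
        t = self.identity_transform(a.shape)
        assert total_cost(a, b, t, config=CostConfig(lam=0.0)) \
            == pytest.approx(ssd(a, b))

    def test_hand_computed_combination(self):
        # identity transform on a 4x4 image pair plus an offset contour;
        # both terms computed longhand with explicit weights
        a = np.arange(16, dtype=float).reshape(4, 4) / 16.0
        b = a.copy()
        b[2, 1] += 0.4
        t = self.identity_transform(a.shape)
        octo = np.array([(1.0, 1.0), (2.0, 1.0), (3.0, 1.0), (3.0, 2.0),
                         (3.0, 3.0), (2.0, 3.0), (1.0, 3.0), (1.0, 2.0)])
        cref = ContourPointSet(octo, curvatures=np.full(8, 0.2))
        ctgt = ContourPointSet(octo + [0.5, 0.0], curvatures=np.full(8, 0.2))
        cfg = CostConfig(lam=1.0, alpha1=1.0, alpha2=1.0,
                         recompute_curvature=False, resample_points=8)
        val = total_cost(a, b, t, {"endo": cref}, {"endo": ctgt}, cfg)
        c_sim_hand = 0.4**2 / 16.0
        # every shifted target point is nearest its own source point
        # except the two where the +0.5 x-shift crosses to the next one
        d = ((octo + [0.5, 0.0])[:, None, :] - octo[None, :, :])
        c_icp_hand = float((d ** 2).sum(-1).min(1).sum())
        assert val == pytest.approx(c_sim_hand + c_icp_hand, rel=1e-9)

    def test_monotone_in_lambda(self, rng):
        a = rng.uniform(size=(12, 12))
        t = self.identity_transform(a.shape)
        ang = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        cref = ContourPointSet(np.stack([6 + 3 * np.cos(ang), 6 + 3 * np.sin(ang)], 1))
        ctgt = ContourPointSet(np.stack([6 + 2 * np.cos(ang), 6 + 2 * np.sin(ang)], 1))
        vals = [total_cost(a, a, t, {"endo": cref}, {"endo": ctgt},
                           CostConfig(lam=lam, resample_points=16))
                for lam in (0.5, 1.0, 2.0)]
        assert vals[0] < vals[1] < vals[2]

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            CostConfig(lam=-0.1)
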