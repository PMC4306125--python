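import numpy as np
import pytest

from lvstrain.registration import DisplacementField
from lvstrain.strain import (aha_segments, circumferential_strain,
                             compute_strain_fields, deformation_gradient,
                             radial_strain, segment_curves, strain_rate,
                             strain_tensor)


def annulus_mask(size=48, r_in=9.0, r_out=16.0, center=None):
    c = (size - 1) / 2.0 if center is None else center
    ys, xs = np.mgrid[0:size, 0:size]
    r = np.hypot(xs - c, ys - c)
    return (r >= r_in) & (r <= r_out), (c, c)


def scaling_field(size, s, center):
    ys, xs = np.mgrid[0:size, 0:size]
    return np.stack([(s - 1) * (xs - center[0]),
                     (s - 1) * (ys - center[1])], axis=-1)


class TestDeformationGradient:
    def test_zero_field_gives_identity(self):
        f = deformation_gradient(np.zeros((10, 10, 2)))
        assert np.allclose(f, np.eye(2), atol=1e-14)

    def test_linear_field_exact(self):
        ys, xs = np.mgrid[0:12, 0:12].astype(float)
        u = np.stack([0.1 * xs, np.zeros_like(xs)], axis=-1)
        f = deformation_gradient(u)
        np.testing.assert_allclose(f[..., 0, 0], 1.1, atol=1e-10)
        np.testing.assert_allclose(f[..., 0, 1], 0.0, atol=1e-10)
        np.testing.assert_allclose(f[..., 1, 1], 1.0, atol=1e-10)

    @pytest.mark.parametrize("spacing", [(1.0, 1.0), (1.25, 1.92)])
    def test_quadratic_field_matches_analytic_jacobian(self, spacing):
        # central (and numpy's 2nd-order one-sided) differences are exact
        # for quadratics; jacobian derived by hand
        ys, xs = np.mgrid[0:16, 0:16].astype(float)
        sx, sy = spacing
        xm, ym = xs * sx, ys * sy       # physical coordinates
        u_mm_x = 0.01 * xm**2 + 0.02 * xm * ym
        u_mm_y = 0.03 * ym**2 - 0.01 * xm * ym
        u_px = np.stack([u_mm_x / sx, u_mm_y / sy], axis=-1)
        f = deformation_gradient(u_px, spacing)
        np.testing.assert_allclose(f[..., 0, 0], 1 + 0.02 * xm + 0.02 * ym,
                                   atol=1e-6)
        np.testing.assert_allclose(f[..., 0, 1], 0.02 * xm, atol=1e-6)
        np.testing.assert_allclose(f[..., 1, 0], -0.01 * ym, atol=1e-6)
        np.testing.assert_allclose(f[..., 1, 1], 1 + 0.06 * ym - 0.01 * xm,
                                   atol=1e-6)

    def test_accepts_displacement_field_object(self):
        fld = DisplacementField(u=np.zeros((6, 6, 2)), frame=0)
        assert np.allclose(deformation_gradient(fld), np.eye(2))


class TestStrainTensor:
    def test_identity_gives_zero(self):
        assert np.allclose(strain_tensor(np.eye(2)[None, None]), 0.0)

    def test_uniform_scaling_closed_form(self):
        f = 1.1 * np.eye(2)[None, None]
        e = strain_tensor(f)
        assert np.allclose(e, 0.105 * np.eye(2), atol=1e-12)

    def test_pure_rotation_gives_zero(self):
        th = 0.4
        r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        np.testing.assert_allclose(strain_tensor(r[None, None]), 0.0,
                                   atol=1e-14)


class TestRadialStrain:
    def test_zero_strain_is_zero_percent(self):
        e = np.zeros((8, 8, 2, 2))
        out = radial_strain(e, (3.5, 3.5))
        assert np.nanmax(np.abs(out)) == 0.0

    def test_uniform_radial_stretch(self):
        mask, c = annulus_mask()
        u = scaling_field(48, 1.1, c)
        e = strain_tensor(deformation_gradient(u))
        rad = radial_strain(e, c)
        assert abs(np.nanmean(rad[mask]) - 10.5) / 10.5 < 0.05

    def test_compression_is_negative(self):
        mask, c = annulus_mask()
        u = scaling_field(48, 0.9, c)
        e = strain_tensor(deformation_gradient(u))
        rad = radial_strain(e, c)
        assert abs(np.nanmean(rad[mask]) - (-9.5)) / 9.5 < 0.05

    def test_engineering_variant_for_small_strain(self):
        mask, c = annulus_mask()
        u = scaling_field(48, 1.1, c)
        f = deformation_gradient(u)
        e = strain_tensor(f)
        eng = radial_strain(e, c, kind="engineering", f=f)
        assert np.nanmean(eng[mask]) == pytest.approx(10.0, rel=0.05)

    def test_circumferential_matches_radial_for_isotropic_scaling(self):
        mask, c = annulus_mask()
        u = scaling_field(48, 1.05, c)
        e = strain_tensor(deformation_gradient(u))
        np.testing.assert_allclose(circumferential_strain(e, c)[mask],
                                   radial_strain(e, c)[mask], atol=1e-6)


class TestStrainRate:
    def test_constant_series_zero_rate(self):
        assert np.allclose(strain_rate(np.full(10, 0.15), 50.0), 0.0)

    def test_linear_ramp_constant_rate(self):
        s = np.linspace(0.0, 0.2, 21)          # over 1 s at 50 ms
        np.testing.assert_allclose(strain_rate(s, 50.0), 0.2, atol=1e-12)

    def test_sinusoid_matches_analytic_derivative(self):
        dt = 50.0
        t = np.arange(40) * dt / 1000.0
        w = np.pi
        s = 0.1 * np.sin(w * t)
        rate = strain_rate(s, dt)
        expected = 0.1 * w * np.cos(w * t)
        err = np.abs(rate[1:-1] - expected[1:-1]) / (0.1 * w)
        assert err.max() < 0.03

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            strain_rate(np.zeros(2), 50.0)

    def test_nonuniform_interval_rejected(self):
        with pytest.raises(ValueError):
            strain_rate(np.zeros(5), np.array([50.0, 50.0, 60.0, 50.0]))


class TestAHASegments:
    def test_basal_six_sectors_partition_mask(self):
        mask, c = annulus_mask()
        model = aha_segments(mask, c, 0.0, level="basal")
        assert model.segment_ids == tuple(range(1, 7))
        labels = model.labels
        assert np.array_equal(labels > 0, mask)          # union = mask
        counts = [np.count_nonzero(labels == s) for s in model.segment_ids]
        assert max(counts) - min(counts) <= 0.1 * np.mean(counts) + 20

    @pytest.mark.parametrize("level, n", [("basal", 6), ("mid", 6),
                                          ("apical", 4)])
    def test_sector_counts_per_level(self, level, n):
        mask, c = annulus_mask()
        model = aha_segments(mask, c, 0.3, level=level)
        assert len(model.segment_ids) == n

    def test_rotating_rv_angle_permutes_labels(self):
        mask, c = annulus_mask()
        m0 = aha_segments(mask, c, 0.0, level="basal")
        m1 = aha_segments(mask, c, np.deg2rad(60.0), level="basal")
        # advancing the reference angle by one sector width relabels each
        # pixel to the previous segment id (cyclically)
        remap = np.zeros_like(m0.labels)
        for s in m0.segment_ids:
            remap[m0.labels == (s % 6) + 1] = s
        mismatch = np.count_nonzero((remap != m1.labels) & mask)
        assert mismatch < 0.02 * np.count_nonzero(mask)  # quantization edge

    def test_empty_sector_raises_with_name(self):
        mask, c = annulus_mask()
        mask[:, :30] = False                  # wipe out most of the annulus
        with pytest.raises(ValueError, match="segment"):
            aha_segments(mask, c, 0.0, level="basal")

    def test_unknown_level_rejected(self):
        mask, c = annulus_mask()
        with pytest.raises(ValueError):
            aha_segments(mask, c, 0.0, level="apex")


class TestSegmentCurves:
    def make_fields(self, scales, size=48):
        mask, c = annulus_mask(size)
        fields = [DisplacementField(u=scaling_field(size, s, c), frame=i)
                  for i, s in enumerate(scales)]
        return compute_strain_fields(fields, mask, c), mask, c

    def test_reference_frame_curves_are_zero(self):
        sfs, mask, c = self.make_fields([1.0, 1.05, 1.1])
        model = aha_segments(mask, c, 0.0, level="mid")
        df = segment_curves(sfs, model, frame_interval=50.0)
        assert np.allclose(df[df.frame == 0].radial_strain_pct, 0.0)

    def test_uniform_deformation_makes_all_segments_equal(self):
        sfs, mask, c = self.make_fields([1.0, 1.08, 1.02])
        model = aha_segments(mask, c, 0.0, level="mid")
        df = segment_curves(sfs, model, frame_interval=50.0)
        for t in range(3):
            seg = df[(df.frame == t) & (df.segment != "global")]
            assert seg.radial_strain_pct.std() < 1e-6

    def test_global_equals_area_weighted_segment_mean(self):
        rng = np.random.default_rng(3)
        mask, c = annulus_mask()
        u = 0.5 * rng.normal(size=(48, 48, 2)).cumsum(0).cumsum(1) / 48
        sfs = compute_strain_fields([DisplacementField(u=u, frame=0)], mask, c)
        model = aha_segments(mask, c, 0.4, level="basal")
        df = segment_curves(sfs * 3, model, frame_interval=50.0)
        one = df[df.frame == 1]
        segs = one[one.segment != "global"]
        weights = np.array([np.count_nonzero(model.labels == int(s))
                            for s in segs.segment])
        weighted = np.average(segs.radial_strain_pct, weights=weights)
        global_val = one[one.segment == "global"].radial_strain_pct.iloc[0]
        assert abs(weighted - global_val) < 1e-9

    def test_strain_rate_telescopes_to_net_strain(self):
        scales = 1.0 + 0.08 * np.sin(np.linspace(0, np.pi, 12))
        sfs, mask, c = self.make_fields(list(scales))
        model = aha_segments(mask, c, 0.0, level="mid")
        df = segment_curves(sfs, model, frame_interval=50.0)
        g = df[df.segment == "global"].sort_values("frame")
        rate = g.radial_strain_rate_per_s.to_numpy()
        strain = g.radial_strain_pct.to_numpy() / 100.0
        integral = np.trapezoid(rate, dx=0.05)
        net = strain[-1] - strain[0]
        assert abs(integral - net) <= 0.01 * max(np.abs(strain).max(), 1e-9)

    def test_hypokinetic_sector_detected(self):
        from lvstrain import phantom as ph
        spec = ph.PhantomSpec(noise_sigma=0.0,
                              hypokinetic=(90.0, 60.0, 0.15))
        truth = ph.PhantomGroundTruth(spec=spec)
        mask = truth.myocardium_mask()
        fields = [truth.displacement_field(t) for t in range(spec.frames)]
        sfs = compute_strain_fields(fields, mask, spec.center,
                                    spacing=spec.pixel_spacing)
        # rv angle chosen so segment 9 (mid) is centred on the weak sector
        model = aha_segments(mask, spec.center, np.deg2rad(90.0 - 2.5 * 60.0),
                             level="mid")
        df = segment_curves(sfs, model, frame_interval=spec.frame_interval)
        peaks = {s: g.radial_strain_pct.abs().max()
                 for s, g in df.groupby("segment") if s != "global"}
        weak = peaks.pop("9")
        assert weak < 0.5 * min(peaks.values())


class TestObjectivity:
    def test_rigid_motion_produces_no_strain(self):
        from lvstrain import phantom as ph
        spec = ph.PhantomSpec(contraction=0.0, thickening=0.0,
                              rotation_deg=8.0, noise_sigma=0.0)
        truth = ph.PhantomGroundTruth(spec=spec)
        mask = truth.myocardium_mask()
        fields = [truth.displacement_field(t) for t in range(0, spec.frames, 4)]
        sfs = compute_strain_fields(fields, mask, spec.center)
        for sf in sfs:
            assert np.nanmax(np.abs(sf.radial_pct[mask])) < 0.5
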