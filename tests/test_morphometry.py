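import math

import numpy as np
import pytest

from conftest import circle_points
from fibremorph.centerline import FibrePath, resample_arclength
from fibremorph.morphometry import (
    AnalysisConfig,
    analyze_field,
    analyze_mask,
    channel_intensity_ratio,
    fibre_curvature,
    fibre_diameter,
    fibre_length,
    surface_area,
    volume_fraction,
)
from fibremorph.phantoms import (
    Helix,
    ImagingModel,
    Segment,
    TubeSpec,
    make_candelabra,
    rasterize_tube,
    render_acquisition,
)
from fibremorph.segmentation import BinaryMask


class TestVolumeFraction:
    def test_full_and_empty(self):
        full = BinaryMask(np.ones((4, 4, 4), bool), (1, 1, 1))
        empty = BinaryMask(np.zeros((4, 4, 4), bool), (1, 1, 1))
        assert volume_fraction(full) == 1.0
        assert volume_fraction(empty) == 0.0

    def test_tube_in_box(self):
        spec = TubeSpec(Segment((5, 10, 10), (55, 10, 10)), 3.0)
        mask, _ = rasterize_tube(spec, (20, 20, 61), (1, 1, 1))
        expected = math.pi * 9 * 50 / (61 * 20 * 20)
        assert volume_fraction(mask) == pytest.approx(expected, rel=0.05)

    def test_additive_over_disjoint_masks(self):
        rng = np.random.default_rng(0)
        a = rng.random((10, 10, 10)) < 0.2
        b = (rng.random((10, 10, 10)) < 0.2) & ~a
        va = volume_fraction(BinaryMask(a, (1, 1, 1)))
        vb = volume_fraction(BinaryMask(b, (1, 1, 1)))
        vab = volume_fraction(BinaryMask(a | b, (1, 1, 1)))
        assert vab == pytest.approx(va + vb, abs=1e-12)


class TestSurfaceArea:
    def test_digital_sphere(self):
        from skimage.morphology import ball

        mask = BinaryMask(np.pad(ball(10), 2), (1, 1, 1))
        assert surface_area(mask) == pytest.approx(4 * math.pi * 100, rel=0.05)

    def test_straight_tube_with_caps(self, straight_tube):
        mask, _ = straight_tube
        expected = 2 * math.pi * 3 * 50 + 2 * math.pi * 9
        assert surface_area(mask) == pytest.approx(expected, rel=0.08)

    def test_single_voxel_positive(self):
        vox = np.zeros((5, 5, 5), bool)
        vox[2, 2, 2] = True
        assert surface_area(BinaryMask(vox, (1, 1, 1))) > 0

    def test_empty_mask_warns_zero(self):
        with pytest.warns(UserWarning):
            assert surface_area(BinaryMask(np.zeros((3, 3, 3), bool), (1, 1, 1))) == 0.0

    def test_error_non_increasing_when_spacing_halves(self):
        from skimage.morphology import ball

        exp = 4 * math.pi * 100
        coarse = BinaryMask(np.pad(ball(10), 2), (1, 1, 1))
        fine = BinaryMask(np.pad(ball(20), 2), (0.5, 0.5, 0.5))
        err_c = abs(surface_area(coarse) / exp - 1)
        err_f = abs(surface_area(fine) / exp - 1)
        assert err_f <= err_c


class TestFibreLength:
    def test_straight(self):
        pts = np.stack([np.arange(51.0), np.zeros(51), np.zeros(51)], axis=1)
        assert fibre_length(FibrePath(pts)) == pytest.approx(50.0)

    def test_quarter_arc_chord_sum(self):
        dense = circle_points(20.0, 0.01)
        quarter = dense[: int(len(dense) / 4) + 1]
        path = resample_arclength(quarter, 1.0)
        assert fibre_length(path) == pytest.approx(math.pi * 20 / 2, rel=0.01)

    def test_identical_points_error(self):
        with pytest.raises(ValueError):
            fibre_length(FibrePath(np.zeros((2, 3))))


class TestFibreCurvature:
    def test_collinear_zero(self):
        pts = np.stack([np.arange(20.0), np.zeros(20), np.zeros(20)], axis=1)
        assert fibre_curvature(FibrePath(pts)) == 0.0

    def test_circle_closed_form_chord_identity(self):
        R, ds = 10.0, 1.0
        pts = circle_points(R, ds, 40)
        expected = 2 * R * (1 - math.cos(ds / R)) / ds**2
        got = fibre_curvature(FibrePath(pts, step_um=ds))
        assert got == pytest.approx(expected, rel=1e-9)
        assert got == pytest.approx(1 / R, rel=1e-3)

    def test_helix_against_dense_numerical_oracle(self):
        hel = Helix(a=4.0, c=3.0, turns=2.0)
        path = resample_arclength(hel.sample(0.01), 1.0)
        got = fibre_curvature(path)

        # oracle: curvature of the analytic helix from dense finite differences
        h = 1e-4
        s = np.array([hel.length / 2])
        d2 = (hel.point(s + h) - 2 * hel.point(s) + hel.point(s - h)) / h**2
        oracle = float(np.linalg.norm(d2))
        assert oracle == pytest.approx(4 / 25, rel=1e-4)
        assert got == pytest.approx(oracle, rel=0.02)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(5)
        pts = circle_points(10.0, 1.0, 30) + rng.normal(0, 0.05, (30, 3))
        k0 = fibre_curvature(FibrePath(pts))
        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = pts @ q.T + np.array([5.0, -3.0, 11.0])
        k1 = fibre_curvature(FibrePath(moved))
        assert k1 == pytest.approx(k0, rel=1e-9)

    def test_too_few_points_absent(self):
        assert fibre_curvature(FibrePath(np.zeros((2, 3)) + [[0, 0, 0], [1, 0, 0]])) is None


class TestFibreDiameter:
    def test_straight_tube_axis_aligned(self, straight_tube):
        mask, _ = straight_tube
        pts = np.stack(
            [np.arange(8.0, 53.0), np.full(45, 10.0), np.full(45, 10.0)], axis=1
        )
        d = fibre_diameter(FibrePath(pts), mask)
        assert d == pytest.approx(6.0, abs=0.5)

    def test_diagonal_tube_orientation_invariance(self):
        spec = TubeSpec(Segment((8, 8, 8), (38, 38, 38)), 3.0)
        mask, _ = rasterize_tube(spec, (46, 46, 46), (1, 1, 1))
        t = np.linspace(12, 34, 23)
        pts = np.stack([t, t, t], axis=1)
        d = fibre_diameter(FibrePath(pts), mask)
        assert d == pytest.approx(6.0, abs=1.0)

    def test_two_point_path_defined(self):
        spec = TubeSpec(Segment((5, 8, 8), (25, 8, 8)), 2.0)
        mask, _ = rasterize_tube(spec, (16, 16, 32), (1, 1, 1))
        pts = np.array([[14.0, 8.0, 8.0], [16.0, 8.0, 8.0]])
        d = fibre_diameter(FibrePath(pts), mask)
        assert d == pytest.approx(4.0, abs=1.0)

    def test_edt_fallback_agrees_on_straight_tube(self, straight_tube):
        mask, _ = straight_tube
        pts = np.stack(
            [np.arange(8.0, 53.0), np.full(45, 10.0), np.full(45, 10.0)], axis=1
        )
        d_cs = fibre_diameter(FibrePath(pts), mask, method="cross_section")
        d_edt = fibre_diameter(FibrePath(pts), mask, method="edt")
        assert abs(d_cs - d_edt) <= 1.0

    def test_unknown_method(self, straight_tube):
        mask, _ = straight_tube
        with pytest.raises(ValueError):
            fibre_diameter(FibrePath(np.zeros((3, 3))), mask, method="nope")


class TestIntensityRatio:
    def test_exact_ratios(self, straight_tube):
        mask, _ = straight_tube
        base = np.random.default_rng(0).random(mask.shape) + 1.0
        assert channel_intensity_ratio(mask, 2 * base, base) == pytest.approx(2.0)
        assert channel_intensity_ratio(mask, base, base) == pytest.approx(1.0)

    def test_empty_mask_errors(self):
        m = BinaryMask(np.zeros((3, 3, 3), bool), (1, 1, 1))
        with pytest.raises(ValueError):
            channel_intensity_ratio(m, np.ones((3, 3, 3)), np.ones((3, 3, 3)))

    def test_zero_denominator_errors(self, straight_tube):
        mask, _ = straight_tube
        with pytest.raises(ValueError):
            channel_intensity_ratio(mask, np.ones(mask.shape), np.zeros(mask.shape))


class TestFullPipeline:
    def test_straight_tube_stack_recovery(self, straight_tube):
        mask, truth = straight_tube
        stack = render_acquisition(mask, ImagingModel(seed=0), 100.0)
        m = analyze_field(stack, AnalysisConfig())
        assert m.n_fibres == 1
        assert m.n_branches == 0
        assert m.mean_length_um == pytest.approx(truth.length_um, rel=0.03)
        assert m.mean_diameter_um == pytest.approx(6.0, abs=1.0)
        assert m.mean_curvature_per_um < 0.01

    def test_blank_stack_empty_flag(self):
        from fibremorph.volume_io import ImageStack

        stack = ImageStack(np.zeros((1, 10, 10, 10)), (1, 1, 1), ["tropoelastin"])
        m = analyze_field(stack, AnalysisConfig())
        assert m.empty
        assert m.n_fibres == 0

    def test_noisy_candelabra_branch_recovery(self):
        mask, truth = make_candelabra(
            5, base_depth=30, prong_length=18, tube_radius=2.0, jitter_sd=0.5, seed=3
        )
        model = ImagingModel(psf_sigma=(0.5, 0.5, 0.5), gaussian_sd=5.0, seed=17)
        stack = render_acquisition(mask, model, 100.0)
        m = analyze_field(stack, AnalysisConfig())
        assert m.n_branches == truth.branch_count

    def test_deterministic(self, straight_tube):
        mask, _ = straight_tube
        stack = render_acquisition(
            mask, ImagingModel(gaussian_sd=3.0, seed=1), 100.0
        )
        m1 = analyze_field(stack, AnalysisConfig())
        m2 = analyze_field(stack, AnalysisConfig())
        assert m1.as_dict() == m2.as_dict()

    def test_anisotropic_stack(self):
        spec = TubeSpec(Segment((5, 10, 10), (45, 10, 10)), 3.0)
        mask, truth = rasterize_tube(spec, (26, 20, 52), (0.8, 1.0, 1.0))
        stack = render_acquisition(mask, ImagingModel(seed=0), 100.0)
        m = analyze_field(stack, AnalysisConfig())
        assert m.n_fibres == 1
        assert m.mean_length_um == pytest.approx(truth.length_um, rel=0.05)
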