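"""Forward model: phantoms, anisotropic PSF rendering, rotation and
multi-view simulation."""

import numpy as np
import pytest
from scipy import ndimage

from corrtomo import corr
from corrtomo.errors import GeometryError, ValidationError
from corrtomo.phantom import generate_phantom
from corrtomo.psf import PSFModel, render_psf, rotation_matrix_y
from corrtomo.simulate import (NoiseModel, ShiftLaw, blur_with_rotated_psf,
                               rotate_volume, simulate_views)


class TestPhantom:
    def test_empty_bead_field_is_zero(self):
        v = generate_phantom("bead_field", (24, 24, 24), seed=0, margin=6,
                             n_beads=0)
        assert not np.any(v)

    def test_seed_determinism_bit_identical(self):
        kw = dict(seed=5, margin=8)
        for kind in ("bead_field", "vessel_tree", "shell"):
            a = generate_phantom(kind, (32, 32, 32), **kw)
            b = generate_phantom(kind, (32, 32, 32), **kw)
            assert np.array_equal(a, b)

    @pytest.mark.parametrize("k", [1, 5, 9])
    def test_bead_count_matches_request(self, k):
        v = generate_phantom("bead_field", (40, 40, 40), seed=2, margin=10,
                             n_beads=k)
        _, n = ndimage.label(v > 0)
        assert n == k

    def test_margin_is_respected(self):
        v = generate_phantom("vessel_tree", (40, 40, 40), seed=3, margin=10)
        assert not np.any(v[:10]) and not np.any(v[-10:])
        assert not np.any(v[:, :10]) and not np.any(v[:, -10:])
        assert not np.any(v[:, :, :10]) and not np.any(v[:, :, -10:])

    def test_impossible_margin_raises(self):
        with pytest.raises(GeometryError):
            generate_phantom("bead_field", (12, 12, 12), seed=0, margin=6)

    def test_vessel_walls_are_hollow(self):
        v = generate_phantom("vessel_tree", (48, 48, 48), seed=9, margin=12,
                             wall_radius=3.0, lumen_radius=1.5)
        filled = ndimage.binary_fill_holes(v > 0)
        assert filled.sum() > (v > 0).sum()  # interior carved out


class TestRenderPsf:
    def test_angle_zero_axis_aligned(self, small_psf):
        h = render_psf(small_psf, 0.0)
        assert np.isclose(h.sum(), 1.0)
        assert np.unravel_index(np.argmax(h), h.shape) == tuple(
            s // 2 for s in h.shape)
        # separable when axis-aligned: zero zx cross-moment
        grids = np.indices(h.shape).astype(float)
        c = [(g * h).sum() for g in grids]
        m_zx = ((grids[0] - c[0]) * (grids[2] - c[2]) * h).sum()
        assert abs(m_zx) < 1e-10

    def test_half_turn_symmetry(self, small_psf):
        np.testing.assert_allclose(render_psf(small_psf, 180.0),
                                   render_psf(small_psf, 0.0), atol=1e-12)

    @pytest.mark.parametrize("angle", [0.0, 35.0, 90.0, 217.0])
    def test_second_moments_match_rotated_covariance(self, angle):
        model = PSFModel(1.0, 1.0, 3.0)
        # generous support so the moment oracle is not truncation-limited
        h = render_psf(model, angle, support=(33, 13, 33))
        grids = np.indices(h.shape).astype(float)
        mean = [(g * h).sum() for g in grids]
        u = [g - m for g, m in zip(grids, mean)]
        cov = np.array([[(u[i] * u[j] * h).sum() for j in range(3)]
                        for i in range(3)])
        R = rotation_matrix_y(-angle)
        expected = R @ np.diag([9.0, 1.0, 1.0]) @ R.T
        assert np.max(np.abs(cov - expected)) / np.max(np.abs(expected)) < 0.01

    def test_support_too_small_raises(self, small_psf):
        with pytest.raises(GeometryError):
            render_psf(small_psf, 0.0, support=(5, 5, 5))

    def test_invalid_sigmas_rejected(self):
        with pytest.raises(ValidationError):
            PSFModel(1.0, 1.0, 0.5)  # scan shorter than lateral
        with pytest.raises(ValidationError):
            PSFModel(0.0, 1.0, 1.0)


class TestRotateVolume:
    def test_angle_zero_is_identity(self, rng):
        v = rng.random((8, 8, 8))
        assert np.array_equal(rotate_volume(v, 0.0), v)

    def test_quarter_turn_maps_x_axis_to_z_axis(self):
        v = np.zeros((9, 9, 9))
        v[4, 4, 7] = 1.0  # +x at radius 3
        r = rotate_volume(v, 90.0, order=1)
        assert np.unravel_index(np.argmax(r), r.shape) == (7, 4, 4)  # +z

    def test_round_trip_interior_error_small(self, tiny_phantom):
        smooth_psf = PSFModel(2.0, 2.0, 2.0)
        h = corr.embed_centered(render_psf(smooth_psf), tiny_phantom.shape)
        smooth = corr.convolve(tiny_phantom, h, mode="circular")
        back = rotate_volume(rotate_volume(smooth, 30.0, 3), -30.0, 3)
        interior = (slice(6, -6),) * 3
        err = np.abs(back - smooth)[interior].max() / smooth.max()
        assert err < 2e-2


class TestSimulateViews:
    def test_base_case_equals_convolution(self, tiny_phantom, small_psf):
        vs = simulate_views(tiny_phantom, small_psf, [0.0],
                            ShiftLaw(max_abs=0), NoiseModel(), seed=1)
        h = corr.embed_centered(render_psf(small_psf), tiny_phantom.shape)
        expected = corr.convolve(tiny_phantom, h, mode="circular")
        np.testing.assert_allclose(vs.views[0], expected, atol=1e-12)

    def test_full_turn_30_degree_steps_gives_12_views(self, tiny_phantom,
                                                      small_psf):
        angles = np.arange(0.0, 360.0, 30.0)
        vs = simulate_views(tiny_phantom, small_psf, angles,
                            ShiftLaw(max_abs=1), NoiseModel(), seed=2,
                            order=1)
        assert len(vs) == 12

    def test_two_path_equivalence_quarter_turn(self, tiny_phantom, small_psf):
        """Rotate-then-blur equals blur-with-rotated-PSF (computed without
        any rotation) once the view is brought back to the reference
        frame; at 90 degrees the rotation is grid-exact."""
        vs = simulate_views(tiny_phantom, small_psf, [0.0, 90.0],
                            ShiftLaw(max_abs=0), NoiseModel(), seed=3,
                            order=3)
        back = rotate_volume(vs.views[1], -90.0, order=3)
        alt = blur_with_rotated_psf(tiny_phantom, small_psf, 90.0)
        assert np.max(np.abs(back - alt)) / alt.max() < 1e-3

    def test_acorr_shift_invariance_end_to_end(self, tiny_phantom, small_psf):
        """The property the method rests on: a view's auto-correlation
        does not see its rigid misalignment."""
        quiet = simulate_views(tiny_phantom, small_psf, [0.0, 90.0],
                               ShiftLaw(max_abs=0), NoiseModel(), seed=4,
                               order=1)
        shifted = [np.roll(v, (3, -4, 2), axis=(0, 1, 2))
                   for v in quiet.views]
        for v, s in zip(quiet.views, shifted):
            a1 = corr.autocorrelate(v, "circular").data
            a2 = corr.autocorrelate(s, "circular").data
            assert np.array_equal(a1, a2)

    def test_mass_conservation_under_rotation(self, tiny_phantom, small_psf):
        vs = simulate_views(tiny_phantom, small_psf, [0.0, 30.0, 60.0],
                            ShiftLaw(max_abs=0), NoiseModel(), seed=5)
        for v in vs.views:
            assert abs(v.sum() - tiny_phantom.sum()) / tiny_phantom.sum() < 5e-3

    def test_seed_determinism(self, tiny_phantom, small_psf):
        kw = dict(seed=6, order=1)
        noise = NoiseModel("poisson+gaussian", gaussian_sigma=0.01)
        a = simulate_views(tiny_phantom, small_psf, [0.0, 90.0],
                           ShiftLaw(2), noise, **kw)
        b = simulate_views(tiny_phantom, small_psf, [0.0, 90.0],
                           ShiftLaw(2), noise, **kw)
        for va, vb in zip(a.views, b.views):
            assert np.array_equal(va, vb)
        assert np.array_equal(a.true_shifts, b.true_shifts)

    def test_reference_view_pinned_to_zero_shift(self, tiny_phantom,
                                                 small_psf):
        vs = simulate_views(tiny_phantom, small_psf, [0.0, 90.0, 180.0],
                            ShiftLaw(max_abs=4), NoiseModel(), seed=8,
                            order=1)
        assert not np.any(vs.true_shifts[vs.reference_index])

    def test_missing_seed_rejected(self, tiny_phantom, small_psf):
        with pytest.raises(ValidationError):
            simulate_views(tiny_phantom, small_psf, [0.0], seed=None)

    def test_bad_noise_kind_rejected(self):
        with pytest.raises(ValidationError):
            NoiseModel("salt-and-pepper")
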