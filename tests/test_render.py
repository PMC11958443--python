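"""Rendering primitives: plateau parameterization, Gaussian fields,
soft-edged shapes, compositing, noise, and quantization."""

import math

import numpy as np
import pytest

from leyes.render import (
    CollarettePolygon,
    FrozenCollarette,
    GaussianFeature,
    SceneSpec,
    SoftEdgeEllipse,
    UniformBackground,
    add_pixel_noise,
    collarette_outline,
    compose_scene,
    eval_gaussian_field,
    freeze_collarette,
    plateau_sigma,
    render_collarette,
    render_soft_ellipse,
)


class TestPlateauSigma:
    @pytest.mark.parametrize(
        "r, A, expected",
        [
            (4.0, math.e**2, 2.0),
            (5.0, math.e**0.5, 5.0),
            (10.0, 20000.0, 10.0 / math.sqrt(2.0 * math.log(20000.0))),
        ],
    )
    def test_values(self, r, A, expected):
        assert plateau_sigma(r, A) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("A", [1.0, 0.5, 0.0, -3.0])
    def test_invalid_amplitude(self, A):
        with pytest.raises(ValueError):
            plateau_sigma(4.0, A)

    def test_plateau_identity_random(self, rng):
        """Field equals exactly 1 at distance r along each principal axis,
        for any amplitude in the pipelines' range."""
        for _ in range(1000):
            r_minor = rng.uniform(0.5, 30.0)
            r_major = r_minor * rng.uniform(1.0, 1.5)
            A = math.exp(rng.uniform(math.log(2.0), math.log(20000.0)))
            theta = rng.uniform(0.0, math.pi)
            f = GaussianFeature(
                x_c=0.0, y_c=0.0, r_minor=r_minor, r_major=r_major,
                A=A, theta=theta,
            )
            # minor axis lies along (cos theta, sin theta)
            from leyes.render import eval_gaussian_at

            v_minor = eval_gaussian_at(
                f, r_minor * math.cos(theta), r_minor * math.sin(theta)
            )
            v_major = eval_gaussian_at(
                f, -r_major * math.sin(theta), r_major * math.cos(theta)
            )
            assert abs(v_minor - 1.0) < 1e-9
            assert abs(v_major - 1.0) < 1e-9


class TestGaussianField:
    def test_value_at_center_is_amplitude(self):
        f = GaussianFeature(x_c=10.0, y_c=12.0, r_minor=3.0, r_major=4.0, A=7.5)
        field = eval_gaussian_field(f, 30, 30)
        assert field[12, 10] == pytest.approx(7.5)

    def test_plateau_edge_at_integer_radius(self):
        f = GaussianFeature(x_c=10.0, y_c=10.0, r_minor=5.0, r_major=8.0,
                            A=40.0, theta=0.0)
        field = eval_gaussian_field(f, 30, 30)
        assert field[10, 15] == pytest.approx(1.0, abs=1e-12)

    def test_rotation_oracle_45_degrees(self, rng):
        """Evaluating the rotated Gaussian equals evaluating the unrotated
        one at explicitly rotated sample points."""
        from leyes.render import eval_gaussian_at

        f0 = GaussianFeature(x_c=0.0, y_c=0.0, r_minor=3.0, r_major=6.0,
                             A=50.0, theta=0.0)
        f45 = GaussianFeature(x_c=0.0, y_c=0.0, r_minor=3.0, r_major=6.0,
                              A=50.0, theta=math.pi / 4)
        pts = rng.uniform(-10, 10, size=(200, 2))
        c, s = math.cos(math.pi / 4), math.sin(math.pi / 4)
        # rotating the evaluation points by -45 deg undoes the feature rotation
        xr = pts[:, 0] * c + pts[:, 1] * s
        yr = -pts[:, 0] * s + pts[:, 1] * c
        np.testing.assert_allclose(
            eval_gaussian_at(f45, pts[:, 0], pts[:, 1]),
            eval_gaussian_at(f0, xr, yr),
            atol=1e-9,
        )

    def test_half_turn_symmetry(self):
        f0 = GaussianFeature(x_c=15.0, y_c=15.0, r_minor=3.0, r_major=6.0,
                             A=100.0, theta=0.7)
        f_pi = GaussianFeature(x_c=15.0, y_c=15.0, r_minor=3.0, r_major=6.0,
                               A=100.0, theta=0.7 + math.pi)
        a = eval_gaussian_field(f0, 31, 31)
        b = eval_gaussian_field(f_pi, 31, 31)
        assert np.max(np.abs(a - b)) < 1e-9


class TestComposeScene:
    def test_empty_scene_is_background(self):
        spec = SceneSpec(width=16, height=16,
                         background=UniformBackground(128.0))
        img = compose_scene(spec, 0)
        np.testing.assert_array_equal(img.pixels, 128.0 / 255.0)

    def test_bright_cr_plateau_is_full_white(self):
        cr = GaussianFeature(x_c=8.0, y_c=8.0, r_minor=3.0, r_major=3.0,
                             A=4.0, L=255.0, polarity="bright")
        spec = SceneSpec(width=17, height=17,
                         background=UniformBackground(128.0), layers=(cr,))
        img = compose_scene(spec, 0)
        assert img.pixels[8, 8] == 1.0
        assert img.pixels[8, 10] == 1.0  # within plateau radius

    def test_dark_pupil_plateau_luminance_exact(self):
        pupil = GaussianFeature(x_c=8.0, y_c=8.0, r_minor=3.0, r_major=3.0,
                                A=4.0, L=1.0, polarity="dark")
        spec = SceneSpec(width=17, height=17,
                         background=UniformBackground(128.0), layers=(pupil,))
        img = compose_scene(spec, 0)
        assert img.pixels[8, 8] == pytest.approx(1.0 / 255.0)

    def test_quantization_and_range(self, rng):
        layers = tuple(
            GaussianFeature(
                x_c=rng.uniform(0, 32), y_c=rng.uniform(0, 32),
                r_minor=2.0, r_major=3.0, A=10.0,
                L=rng.uniform(0, 255),
                polarity=rng.choice(["bright", "dark"]),
            )
            for _ in range(4)
        )
        spec = SceneSpec(width=32, height=32,
                         background=UniformBackground(90.0),
                         layers=layers, sigma_n=12.0)
        img = compose_scene(spec, 42)
        scaled = img.pixels * 255.0
        np.testing.assert_allclose(scaled, np.round(scaled), atol=1e-9)
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0

    def test_same_seed_bit_identical(self):
        cr = GaussianFeature(x_c=10.0, y_c=10.0, r_minor=2.0, r_major=2.0,
                             A=5.0, L=255.0)
        spec = SceneSpec(width=24, height=24,
                         background=UniformBackground(100.0),
                         layers=(cr,), sigma_n=20.0)
        a = compose_scene(spec, 7)
        b = compose_scene(spec, 7)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_off_canvas_layer_cropped_silently(self):
        far = GaussianFeature(x_c=500.0, y_c=500.0, r_minor=2.0, r_major=2.0,
                              A=5.0, L=255.0)
        spec = SceneSpec(width=16, height=16,
                         background=UniformBackground(50.0), layers=(far,))
        img = compose_scene(spec, 0)
        np.testing.assert_array_equal(img.pixels, 50.0 / 255.0)

    def test_empty_canvas_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(width=0, height=5, background=UniformBackground(0.0))

    def test_centroid_oracle_symmetric_cr(self, rng):
        """Intensity-weighted centroid of (image - background) recovers the
        continuous CR center to hundredths of a pixel, for soft-edged
        features whose edge spans several 8-bit levels (steep edges are
        limited by pixel sampling, not by the renderer)."""
        for _ in range(10):
            x_c = 50.0 + rng.uniform(-0.5, 0.5)
            y_c = 50.0 + rng.uniform(-0.5, 0.5)
            r = rng.uniform(12.0, 25.0)
            A = math.exp(rng.uniform(math.log(2), math.log(50)))
            cr = GaussianFeature(x_c=x_c, y_c=y_c, r_minor=r, r_major=r,
                                 A=A, L=255.0)
            spec = SceneSpec(width=101, height=101,
                             background=UniformBackground(128.0), layers=(cr,))
            img = compose_scene(spec, 0)
            diff = img.pixels - 128.0 / 255.0
            diff[diff < 0] = 0.0
            yy, xx = np.indices(diff.shape)
            w = diff.sum()
            assert abs((xx * diff).sum() / w - x_c) < 0.02
            assert abs((yy * diff).sum() / w - y_c) < 0.02


class TestSoftEllipse:
    def test_zero_edge_width_is_binary(self):
        e = SoftEdgeEllipse(x_c=20.0, y_c=20.0, r_minor=5.0, r_major=8.0,
                            edge_width=0.0)
        coeff = render_soft_ellipse(e, 41, 41)
        assert set(np.unique(coeff)) <= {0.0, 1.0}
        assert coeff[20, 20] == 1.0
        assert coeff[20, 25] == 1.0  # on the minor-axis boundary (inclusive)
        assert coeff[20, 26] == 0.0

    def test_band_midpoint_is_half(self):
        e = SoftEdgeEllipse(x_c=20.0, y_c=20.0, r_minor=5.0, r_major=5.0,
                            edge_width=4.0)
        coeff = render_soft_ellipse(e, 41, 41)
        # along +x: boundary at 25, band to 29, midpoint at 27
        assert coeff[20, 27] == pytest.approx(0.5, abs=1e-9)

    def test_monotone_decay_along_rays(self):
        from leyes.render import soft_ellipse_coefficient

        e = SoftEdgeEllipse(x_c=40.0, y_c=40.0, r_minor=10.0, r_major=16.0,
                            theta=0.3, edge_width=6.0)
        rs = np.arange(0.0, 35.0, 0.25)
        for ang in np.linspace(0, 2 * np.pi, 100, endpoint=False):
            vals = soft_ellipse_coefficient(
                e, 40 + rs * np.cos(ang), 40 + rs * np.sin(ang)
            )
            assert np.all(np.diff(vals) <= 1e-9)


class TestCollarette:
    def test_outline_point_count(self, rng):
        c = CollarettePolygon(x_c=0.0, y_c=0.0, n_vertices=13, r_col=10.0)
        frozen = freeze_collarette(c, rng)
        outline = collarette_outline(frozen)
        assert outline.shape == (65, 2)

    def test_outline_closed(self, rng):
        c = CollarettePolygon(x_c=5.0, y_c=5.0, n_vertices=17, r_col=8.0)
        outline = collarette_outline(freeze_collarette(c, rng))
        np.testing.assert_allclose(outline[0], outline[-1], atol=1e-9)

    def test_zero_jitter_is_near_circular(self, rng):
        c = CollarettePolygon(x_c=0.0, y_c=0.0, n_vertices=20, r_col=12.0,
                              jitter_lo=0.0, jitter_hi=0.0)
        outline = collarette_outline(freeze_collarette(c, rng))
        radii = np.hypot(outline[:, 0], outline[:, 1])
        assert np.max(np.abs(radii - 12.0)) < 0.02 * 12.0

    def test_jitter_bounds(self, rng):
        c = CollarettePolygon(x_c=0.0, y_c=0.0, n_vertices=15, r_col=10.0,
                              jitter_lo=0.05, jitter_hi=0.2)
        frozen = freeze_collarette(c, rng)
        dev = np.abs(np.array(frozen.radii) - 10.0)
        assert np.all(dev >= 0.05 * 10.0 - 1e-12)
        assert np.all(dev <= 0.2 * 10.0 + 1e-12)

    def test_render_fills_interior(self, rng):
        c = CollarettePolygon(x_c=20.0, y_c=20.0, n_vertices=16, r_col=10.0,
                              jitter_lo=0.0, jitter_hi=0.05, edge_width=2.0)
        coeff, outline = render_collarette(c, 41, 41, rng)
        assert coeff[20, 20] == 1.0
        assert coeff[0, 0] == 0.0
        assert outline.shape == (80, 2)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            CollarettePolygon(x_c=0.0, y_c=0.0, n_vertices=10, r_col=0.0)


class TestPixelNoise:
    def test_zero_sigma_is_identity(self):
        img = np.full((8, 8), 100.0)
        out = add_pixel_noise(img, 0.0, 1)
        np.testing.assert_array_equal(out, img)

    def test_sample_sd_recovered(self):
        img = np.full((256, 256), 128.0)
        out = add_pixel_noise(img, 10.0, 3)
        sd = np.std(out - img)
        assert 9.5 < sd < 10.5

    def test_deterministic_given_seed(self):
        img = np.zeros((16, 16))
        np.testing.assert_array_equal(
            add_pixel_noise(img, 5.0, 99), add_pixel_noise(img, 5.0, 99)
        )

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            add_pixel_noise(np.zeros((4, 4)), -1.0, 0)
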