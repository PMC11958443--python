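"""VR pipelines: constellation geometry, segmentation scenes, dropout,
spurious-reflection suppression."""

import math

import numpy as np
import pytest
from scipy import ndimage

from leyes.pipelines import (
    ConstellationConfig,
    EDS2019Config,
    HouseConstellationSpec,
    OctagonConstellationSpec,
    build_house_constellation,
    build_octagon_constellation,
    gen_chugh_scene,
    gen_eds2019_scene,
    gen_eds2020_scene,
    sample_house_spec,
    sample_octagon_spec,
    sample_spurious,
)
from leyes.render import GaussianFeature, eval_gaussian_at, eval_gaussian_field


def clockwise_angles(points: np.ndarray) -> np.ndarray:
    """Angles about the centroid, unwrapped along the vertex order.

    With x right and y down, increasing angle from +x toward +y is
    screen-clockwise.
    """
    c = points.mean(axis=0)
    ang = np.arctan2(points[:, 1] - c[1], points[:, 0] - c[0])
    return np.unwrap(ang)


class TestHouseConstellation:
    def test_hand_geometry(self):
        spec = HouseConstellationSpec(w=40.0, f_b=1.0, h=22.0, h_r=10.0, phi=0.0)
        pts = build_house_constellation(spec)
        np.testing.assert_allclose(pts[0], [0.0, -21.0], atol=1e-12)
        np.testing.assert_allclose(pts[1], [20.0, -11.0], atol=1e-12)
        np.testing.assert_allclose(pts[2], [20.0, 11.0], atol=1e-12)
        np.testing.assert_allclose(pts[3], [-20.0, 11.0], atol=1e-12)
        np.testing.assert_allclose(pts[4], [-20.0, -11.0], atol=1e-12)

    def test_mirror_symmetry_unrotated(self):
        spec = HouseConstellationSpec(w=30.0, f_b=0.1, h=16.0, h_r=9.0, phi=0.0)
        pts = build_house_constellation(spec)
        mirrored = pts.copy()
        mirrored[:, 0] *= -1
        # apex maps to itself; right vertices map to left ones
        np.testing.assert_allclose(pts[0], mirrored[0], atol=1e-12)
        np.testing.assert_allclose(pts[1], mirrored[4], atol=1e-12)
        np.testing.assert_allclose(pts[2], mirrored[3], atol=1e-12)

    def test_apex_is_topmost_and_order_clockwise(self, rng):
        for _ in range(200):
            spec = sample_house_spec(rng, center=(64.0, 64.0))
            pts = build_house_constellation(spec)
            if abs(spec.phi) < 10:  # apex stays topmost under small rotation
                assert np.argmin(pts[:, 1]) == 0
            ang = clockwise_angles(pts)
            assert np.all(np.diff(ang) > 0)

    def test_sampled_width_range(self, rng):
        ws = [sample_house_spec(rng, center=(0, 0)).w for _ in range(2000)]
        assert 12.8 <= min(ws) and max(ws) <= 57.6

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            HouseConstellationSpec(w=-1.0, f_b=0.1, h=10.0, h_r=5.0)
        with pytest.raises(ValueError):
            HouseConstellationSpec(w=10.0, f_b=0.0, h=10.0, h_r=5.0)


class TestOctagonConstellation:
    def test_circumradius_exact(self):
        pts = build_octagon_constellation(OctagonConstellationSpec(m=10.0))
        np.testing.assert_allclose(np.hypot(pts[:, 0], pts[:, 1]), 10.0,
                                   atol=1e-9)

    def test_regular_45_degree_spacing(self):
        pts = build_octagon_constellation(
            OctagonConstellationSpec(m=7.0, phi=0.3)
        )
        ang = clockwise_angles(pts)
        np.testing.assert_allclose(np.diff(ang), np.pi / 4.0, atol=1e-9)

    def test_first_vertex_bottom_right(self):
        pts = build_octagon_constellation(OctagonConstellationSpec(m=5.0))
        assert pts[0, 0] > 0 and pts[0, 1] > 0

    def test_sampled_radius_range(self, rng):
        ms = [sample_octagon_spec(rng, center=(0, 0)).m for _ in range(2000)]
        assert 19.2 <= min(ms) and max(ms) <= 51.2


class TestEDS2019Scene:
    def test_collarette_radius_on_iris(self):
        cfg = EDS2019Config()
        for i in range(100):
            s = gen_eds2019_scene(cfg, np.random.default_rng(i), render=False)
            iris = s.params["iris"]
            col = s.params["collarette"]
            assert 0.3 * iris.r_major <= col.r_col <= 0.6 * iris.r_major

    def test_background_far_from_features_is_sclera(self):
        """Noiseless pixels whose perturbation from every feature tail is
        provably below the local quantization margin equal the sampled
        sclera luminance exactly."""
        cfg = EDS2019Config(noise_range=(0.0, 0.0))
        checked = 0
        for i in range(30):
            s = gen_eds2019_scene(cfg, np.random.default_rng(i))
            iris = s.params["iris"]
            pupil = s.params["pupil"]
            l_s = s.params["L_s"]
            q = np.floor(l_s + 0.5)
            margin = min(l_s - (q - 0.5), (q + 0.5) - l_s)
            if margin < 1e-3:  # L_s lands on a rounding boundary; skip scene
                continue
            xx = np.arange(cfg.width, dtype=float)
            yy = np.arange(cfg.height, dtype=float)[:, None]
            dist_iris = np.hypot(xx - iris.x_c, yy - iris.y_c)
            far = dist_iris > iris.r_major + iris.edge_width + 2.0
            # the dark pupil pulls L_s down by (L_s - L_p) * field: require
            # that stays inside the quantization margin
            p_field = eval_gaussian_field(pupil, cfg.width, cfg.height)
            far &= (l_s - pupil.L) * p_field < 0.9 * margin
            for cr in s.params["crs"]:
                far &= 255.0 * eval_gaussian_field(cr, cfg.width, cfg.height) < l_s
            if far.any():
                np.testing.assert_allclose(s.image.pixels[far], q / 255.0,
                                           atol=1e-12)
                checked += 1
        assert checked >= 20

    def test_mask_centroid_matches_pupil_center(self):
        """For symmetric (circular) noiseless pupils, the mask's center of
        mass recovers the labeled center."""
        cfg = EDS2019Config(noise_range=(0.0, 0.0),
                            pupil_major_factor=(1.0, 1.0))
        for i in range(30):
            s = gen_eds2019_scene(cfg, np.random.default_rng(i), render=False)
            mask = s.masks["pupil"]
            assert mask.any()
            cy, cx = ndimage.center_of_mass(mask)
            px, py = s.pupil_center
            assert math.hypot(cx - px, cy - py) < 0.5

    def test_pupil_plateau_inside_iris(self):
        cfg = EDS2019Config()
        for i in range(200):
            s = gen_eds2019_scene(cfg, np.random.default_rng(i), render=False)
            iris = s.params["iris"]
            pupil = s.params["pupil"]
            d = math.hypot(pupil.x_c - iris.x_c, pupil.y_c - iris.y_c)
            assert d + pupil.r_major <= iris.r_minor + 1e-9


class TestConstellationScenes:
    def test_canvas_and_labels_in_canvas(self):
        for gen in (gen_chugh_scene, gen_eds2020_scene):
            for i in range(100):
                s = gen(rng=np.random.default_rng(i), render=False)
                for cr in s.cr_labels:
                    assert 0.0 <= cr.x <= 127.0 and 0.0 <= cr.y <= 127.0
                px, py = s.pupil_center
                assert 0.0 <= px <= 127.0 and 0.0 <= py <= 127.0

    def test_chugh_has_five_ids_eds2020_eight(self):
        s5 = gen_chugh_scene(rng=np.random.default_rng(0), render=False)
        s8 = gen_eds2020_scene(rng=np.random.default_rng(0), render=False)
        assert [c.identity for c in s5.cr_labels] == list(range(5))
        assert [c.identity for c in s8.cr_labels] == list(range(8))

    def test_identity_zero_is_apex(self):
        """The first labeled CR is the one generated at the apex vertex."""
        for i in range(100):
            s = gen_chugh_scene(rng=np.random.default_rng(i), render=False)
            verts = s.params["vertices"]
            lab0 = s.cr_labels[0]
            np.testing.assert_allclose([lab0.x, lab0.y], verts[0], atol=1e-12)

    def test_clockwise_identity_order(self):
        for gen in (gen_chugh_scene, gen_eds2020_scene):
            for i in range(100):
                s = gen(rng=np.random.default_rng(i), render=False)
                ang = clockwise_angles(s.params["vertices"])
                assert np.all(np.diff(ang) > 0)

    def test_chugh_stage2_rotation_bound(self):
        phis = [
            gen_chugh_scene(stage=2, rng=np.random.default_rng(i),
                            render=False).params["phi"]
            for i in range(1000)
        ]
        assert max(abs(p) for p in phis) <= 35.0

    def test_eds2020_rotation_bound(self):
        phis = [
            gen_eds2020_scene(rng=np.random.default_rng(i),
                              render=False).params["phi"]
            for i in range(1000)
        ]
        assert max(abs(p) for p in phis) <= 0.57

    def test_eds2020_pupil_luminance_weibull(self):
        """Offset 18 respected; sample mean matches 18 + 25*Gamma(1.5)."""
        lums = np.array([
            gen_eds2020_scene(rng=np.random.default_rng(i),
                              render=False).params["pupil"].L
            for i in range(5000)
        ])
        assert lums.min() >= 18.0
        expected = 18.0 + 25.0 * math.gamma(1.5)
        assert abs(lums.mean() - expected) / expected < 0.02

    def test_dropout_rate_plausible(self):
        present = np.array([
            [not c.absent for c in gen_chugh_scene(
                rng=np.random.default_rng(i), render=False).cr_labels]
            for i in range(2000)
        ])
        rate = present.mean(axis=0)
        assert np.all(rate > 0.80) and np.all(rate < 0.88)

    def test_absent_crs_not_rendered(self):
        """A dropped CR contributes nothing: no bright plateau at its vertex."""
        found = 0
        for i in range(50):
            s = gen_chugh_scene(rng=np.random.default_rng(i))
            dropped = [c for c in s.cr_labels if c.absent]
            layers = s.params["scene"].layers
            for c in dropped:
                for lay in layers:
                    if lay.polarity == "bright":
                        assert math.hypot(lay.x_c - c.x, lay.y_c - c.y) > 1e-9
                found += 1
        assert found >= 5


class TestSpurious:
    def _pupil(self):
        return GaussianFeature(x_c=64.0, y_c=64.0, r_minor=15.0, r_major=18.0,
                               A=1000.0, L=5.0, polarity="dark")

    def test_never_on_plateau(self, rng):
        pupil = self._pupil()
        spurs = sample_spurious(200, pupil, 128, 128, rng)
        for s in spurs:
            assert eval_gaussian_at(pupil, s.x_c, s.y_c) < 1.0

    def test_far_field_mostly_accepted(self, rng):
        """Far from the pupil, placement is essentially unconstrained: the
        empirical density approaches uniform."""
        pupil = self._pupil()
        spurs = sample_spurious(2000, pupil, 128, 128, rng)
        xs = np.array([s.x_c for s in spurs])
        ys = np.array([s.y_c for s in spurs])
        far = np.hypot(xs - 64, ys - 64) > 50
        # uniform over [0,127]^2: P(distance from center > 50) ~ 0.54
        assert far.mean() > 0.45

    def test_suppression_inside_plateau(self, rng):
        pupil = self._pupil()
        spurs = sample_spurious(5000, pupil, 128, 128, rng)
        xs = np.array([s.x_c for s in spurs])
        ys = np.array([s.y_c for s in spurs])
        inside = eval_gaussian_at(pupil, xs, ys) >= 1.0
        assert inside.sum() == 0

    def test_shape_ranges(self, rng):
        spurs = sample_spurious(500, self._pupil(), 128, 128, rng)
        for s in spurs:
            assert 1.0 <= s.r_minor <= 2.5
            assert s.r_minor <= s.r_major <= 2.5 * s.r_minor + 1e-9
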