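"""Feature detection, homography estimation, and warping."""

import numpy as np
import pytest
from skimage.feature import match_descriptors

from uristrip.errors import RegistrationError
from uristrip.registration import (
    RegistrationConfig,
    detect_features,
    match_and_estimate,
    register,
    warp_to_template,
)
from uristrip.synth import SceneSpec, random_warp, render_scene


class TestDetectFeatures:
    def test_uniform_image_fails(self):
        img = np.full((128, 128, 3), 128, dtype=np.uint8)
        with pytest.raises(RegistrationError):
            detect_features(img)

    def test_tiny_image_fails(self):
        img = np.zeros((32, 32, 3), dtype=np.uint8)
        with pytest.raises(RegistrationError, match="small"):
            detect_features(img)

    def test_template_has_ample_features(self, template_features):
        assert len(template_features) >= 50

    def test_rotation_robustness(self, template):
        rotated = np.rot90(template).copy()
        fs1 = detect_features(template)
        fs2 = detect_features(rotated)
        matches = match_descriptors(
            fs1.descriptors, fs2.descriptors, cross_check=True, max_ratio=0.75
        )
        assert len(matches) > 10


class TestMatchAndEstimate:
    def test_self_registration_is_identity(self, template_features):
        res = match_and_estimate(template_features, template_features)
        assert np.allclose(res.homography, np.eye(3), atol=1e-2)

    def test_known_warp_recovered(self, layout, template_features, rng):
        H0, shape = random_warp(layout, 0.12, rng)
        spec = SceneSpec(
            layout=layout,
            grade_assignment={a.name: 0 for a in layout.analytes},
            warp=H0,
            scene_shape=shape,
        )
        scene = render_scene(spec).image
        res = match_and_estimate(detect_features(scene), template_features)
        truth = np.linalg.inv(H0)
        truth /= truth[2, 2]
        # 2% relative per element, with absolute floors matched to each
        # element's scale (translation in px; perspective terms are ~1e-4
        # and meaningless to compare relatively)
        floors = np.array(
            [[1e-3, 1e-3, 0.2], [1e-3, 1e-3, 0.2], [1e-5, 1e-5, 0.0]]
        )
        assert (
            np.abs(res.homography - truth) <= 0.02 * np.abs(truth) + floors
        ).all()

    def test_unrelated_textures_fail_or_low_ratio(self):
        r1 = np.random.default_rng(1).integers(0, 256, (200, 200, 3)).astype(np.uint8)
        r2 = np.random.default_rng(2).integers(0, 256, (200, 200, 3)).astype(np.uint8)
        try:
            res = match_and_estimate(detect_features(r1), detect_features(r2))
        except RegistrationError:
            return
        assert res.inlier_ratio < 0.3

    def test_parameter_recovery_over_random_warps(self, layout, template_features):
        """Bounded perspective warps are recovered with sub-2px patch error."""
        rng = np.random.default_rng(99)
        centers = np.array(
            [g.patch_center for a in layout.analytes for g in a.grades]
            + [a.pad_center for a in layout.analytes]
        )
        P = np.hstack([centers, np.ones((len(centers), 1))])
        n_ok = 0
        for i in range(10):
            H0, shape = random_warp(layout, 0.15, rng)
            spec = SceneSpec(
                layout=layout,
                grade_assignment={a.name: 0 for a in layout.analytes},
                warp=H0, scene_shape=shape, noise_sigma=2.0, seed=i,
            )
            scene = render_scene(spec).image
            res = match_and_estimate(
                detect_features(scene), template_features, RegistrationConfig(seed=i)
            )
            sp = (H0 @ P.T).T
            sp = sp[:, :2] / sp[:, 2:3]
            back = (res.homography @ np.hstack([sp, np.ones((len(sp), 1))]).T).T
            back = back[:, :2] / back[:, 2:3]
            if np.linalg.norm(back - centers, axis=1).max() <= 2.0:
                n_ok += 1
        assert n_ok >= 9

    def test_illumination_robustness(self, layout, template_features, rng):
        H0, shape = random_warp(layout, 0.10, rng)
        for gain in (0.6, 1.0, 1.4):
            spec = SceneSpec(
                layout=layout,
                grade_assignment={a.name: 0 for a in layout.analytes},
                warp=H0, scene_shape=shape, illumination_gain=gain,
            )
            scene = render_scene(spec).image
            res = match_and_estimate(detect_features(scene), template_features)
            assert res.n_inliers >= 10


class TestWarpToTemplate:
    def test_identity_preserves_image(self, template):
        out, mask = warp_to_template(template, np.eye(3), template.shape[:2])
        assert mask.all()
        assert np.abs(out.astype(int) - template.astype(int)).max() <= 1

    def test_round_trip_interior(self, layout, rng):
        # smooth fixture: geometric error would displace the gradients and
        # show up as large diffs, while bilinear interpolation loss stays
        # small (sharp edges would confound the two)
        yy, xx = np.indices((layout.height, layout.width), dtype=float)
        img = np.stack(
            [
                100 + 80 * np.sin(xx / 30),
                100 + 80 * np.sin(yy / 25),
                60 + 40 * np.cos((xx + yy) / 40),
            ],
            axis=-1,
        ).astype(np.uint8)
        H0, shape = random_warp(layout, 0.10, rng)
        fwd, _ = warp_to_template(img, H0, shape)
        back, mask = warp_to_template(fwd, np.linalg.inv(H0), img.shape[:2])
        interior = np.zeros_like(mask)
        interior[20:-20, 20:-20] = True
        sel = mask & interior
        diff = np.abs(back.astype(float) - img.astype(float))[sel]
        assert diff.mean() < 2.0

    def test_black_image_stays_black(self, rng):
        img = np.zeros((100, 100, 3), dtype=np.uint8)
        H, _ = random_warp_like(rng)
        out, _ = warp_to_template(img, H, (100, 100))
        assert out.max() == 0

    def test_invalid_homography_rejected(self):
        img = np.zeros((100, 100, 3), dtype=np.uint8)
        with pytest.raises(RegistrationError):
            warp_to_template(img, np.zeros((3, 3)), (100, 100))


def random_warp_like(rng):
    from skimage.transform import ProjectiveTransform

    src = np.array([[0, 0], [100, 0], [100, 100], [0, 100]], dtype=float)
    dst = src + rng.uniform(-8, 8, size=(4, 2))
    t = ProjectiveTransform.from_estimate(src, dst)
    return t.params / t.params[2, 2], (100, 100)


class TestFullRegister:
    def test_register_compose(self, layout, template, rng):
        H0, shape = random_warp(layout, 0.10, rng)
        spec = SceneSpec(
            layout=layout,
            grade_assignment={a.name: 1 for a in layout.analytes},
            warp=H0, scene_shape=shape,
        )
        scene = render_scene(spec).image
        aligned, mask, res = register(scene, template)
        assert aligned.shape == template.shape
        # chart area must be fully covered by real scene content
        assert mask[24:-24, 24:-24].all()
        assert res.inlier_ratio > 0.5
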