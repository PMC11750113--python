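"""Scene-to-template registration.

A photographed strip+chart scene is never perfectly positioned: the phone
sits above the light box by hand, so the chart appears translated, rotated
and mildly perspective-distorted.  Before any color can be sampled, the
scene is aligned to the layout's template frame by feature-based matching:
detect scale/rotation/lighting-robust keypoints in both images, match
descriptors with a ratio test plus cross-check, and estimate a full 8-DOF
projective homography by RANSAC.  The homography maps scene (x, y) into
template (x, y); the scene is then resampled into template space with
bilinear interpolation so the layout's patch coordinates apply directly.

The detector is configurable behind :func:`detect_features`; the default
is SIFT, a nonlinear multi-scale detector of the same family as the
KAZE/AKAZE detectors used by handheld colorimetry readers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import SIFT, ORB, match_descriptors
from skimage.measure import ransac
from skimage.transform import ProjectiveTransform, warp

from .errors import RegistrationError

__all__ = [
    "FeatureSet",
    "RegistrationConfig",
    "RegistrationResult",
    "detect_features",
    "match_and_estimate",
    "warp_to_template",
    "register",
]


@dataclass
class FeatureSet:
    """Keypoints (N×2, x then y, subpixel) with one descriptor per keypoint."""

    keypoints: np.ndarray
    descriptors: np.ndarray

    def __post_init__(self):
        if len(self.keypoints) != len(self.descriptors):
            raise ValueError("keypoint/descriptor count mismatch")

    def __len__(self) -> int:
        return len(self.keypoints)


@dataclass
class RegistrationConfig:
    """Tunables of the matching stage, community-standard defaults."""

    detector: str = "sift"
    min_keypoints: int = 10
    ratio: float = 0.75           # Lowe ratio-test threshold
    residual_threshold: float = 3.0  # RANSAC reprojection tolerance, px
    min_matches: int = 4
    min_inliers: int = 10
    min_inlier_ratio: float = 0.3
    max_trials: int = 2000
    seed: int = 0


@dataclass
class RegistrationResult:
    """Estimated homography plus the diagnostics that justify trusting it."""

    homography: np.ndarray  # 3x3, scene -> template, H[2,2] == 1
    n_scene_keypoints: int
    n_template_keypoints: int
    n_matches: int
    n_inliers: int

    @property
    def inlier_ratio(self) -> float:
        return self.n_inliers / self.n_matches if self.n_matches else 0.0


def _to_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 3:
        return rgb2gray(img)
    return img.astype(float) / 255.0 if img.dtype == np.uint8 else img


def detect_features(img: np.ndarray, config: RegistrationConfig | None = None) -> FeatureSet:
    """Detect keypoints and descriptors in an RGB or grayscale image."""
    config = config or RegistrationConfig()
    img = np.asarray(img)
    h, w = img.shape[:2]
    if h < 64 or w < 64:
        raise RegistrationError(f"image {w}x{h} too small to register (min 64x64)")
    gray = _to_gray(img)
    if config.detector == "sift":
        det = SIFT()
    elif config.detector == "orb":
        det = ORB(n_keypoints=1000)
    else:
        raise RegistrationError(f"unknown detector {config.detector!r}")
    try:
        det.detect_and_extract(gray)
        kp = det.keypoints  # (row, col)
        desc = det.descriptors
    except (RuntimeError, ValueError) as exc:
        raise RegistrationError(f"feature detection failed: {exc}") from exc
    if kp is None or len(kp) < config.min_keypoints:
        n = 0 if kp is None else len(kp)
        raise RegistrationError(
            f"only {n} keypoints found (minimum {config.min_keypoints}); "
            "scene lacks texture"
        )
    # store as (x, y)
    return FeatureSet(keypoints=kp[:, ::-1].astype(float), descriptors=np.asarray(desc))


def match_and_estimate(
    scene: FeatureSet,
    template: FeatureSet,
    config: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Ratio-test matching then RANSAC homography, scene → template."""
    config = config or RegistrationConfig()
    if len(scene) == 0 or len(template) == 0:
        raise RegistrationError("empty feature set")
    matches = match_descriptors(
        scene.descriptors,
        template.descriptors,
        cross_check=True,
        max_ratio=config.ratio,
    )
    if len(matches) < config.min_matches:
        raise RegistrationError(
            f"only {len(matches)} descriptor matches survive the ratio test "
            f"(minimum {config.min_matches}); scene={len(scene)} "
            f"template={len(template)} keypoints"
        )
    src = scene.keypoints[matches[:, 0]]
    dst = template.keypoints[matches[:, 1]]
    try:
        model, inliers = ransac(
            (src, dst),
            ProjectiveTransform,
            min_samples=4,
            residual_threshold=config.residual_threshold,
            max_trials=config.max_trials,
            rng=config.seed,
        )
    except ValueError as exc:
        raise RegistrationError(f"homography estimation failed: {exc}") from exc
    if model is None or inliers is None or model.params is None:
        raise RegistrationError("homography estimation failed (degenerate matches)")
    n_inliers = int(inliers.sum())
    n_matches = len(matches)
    H = np.asarray(model.params, dtype=float)
    if not np.all(np.isfinite(H)) or abs(np.linalg.det(H)) < 1e-12 or H[2, 2] == 0:
        raise RegistrationError(
            f"degenerate homography (det={np.linalg.det(H):.3g}); "
            f"matches={n_matches} inliers={n_inliers}"
        )
    if n_inliers < config.min_inliers or n_inliers / n_matches < config.min_inlier_ratio:
        raise RegistrationError(
            f"registration rejected: {n_inliers}/{n_matches} inliers "
            f"(need >= {config.min_inliers} and ratio >= {config.min_inlier_ratio})"
        )
    return RegistrationResult(
        homography=H / H[2, 2],
        n_scene_keypoints=len(scene),
        n_template_keypoints=len(template),
        n_matches=n_matches,
        n_inliers=n_inliers,
    )


def warp_to_template(img: np.ndarray, H: np.ndarray, out_shape) -> tuple[np.ndarray, np.ndarray]:
    """Resample a scene into template space.

    ``H`` maps scene (x, y) to template (x, y).  Returns the warped uint8
    image and a boolean validity mask; pixels with no source data (outside
    the scene's footprint) are False in the mask and zero in the image.
    """
    H = np.asarray(H, dtype=float)
    if H.shape != (3, 3) or not np.all(np.isfinite(H)) or abs(np.linalg.det(H)) < 1e-12:
        raise RegistrationError("invalid homography for warping")
    img = np.asarray(img)
    imgf = img.astype(float) / 255.0 if img.dtype == np.uint8 else img.astype(float)
    # warp() maps output coords through the given transform to input coords:
    # template -> scene is the inverse of H.
    tform = ProjectiveTransform(matrix=np.linalg.inv(H))
    out = warp(imgf, tform, output_shape=tuple(out_shape), order=1, cval=0.0)
    ones = np.ones(img.shape[:2], dtype=float)
    cover = warp(ones, tform, output_shape=tuple(out_shape), order=1, cval=0.0)
    mask = cover > 0.999
    out8 = np.clip(np.floor(out * 255.0 + 0.5), 0, 255).astype(np.uint8)
    out8[~mask] = 0
    return out8, mask


def register(
    scene_img: np.ndarray,
    template_img: np.ndarray,
    config: RegistrationConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, RegistrationResult]:
    """Full registration: features, homography, warp.

    Returns (aligned uint8 image in template space, validity mask, result).
    """
    config = config or RegistrationConfig()
    scene_fs = detect_features(scene_img, config)
    template_fs = detect_features(template_img, config)
    res = match_and_estimate(scene_fs, template_fs, config)
    aligned, mask = warp_to_template(
        scene_img, res.homography, np.asarray(template_img).shape[:2]
    )
    return aligned, mask, res
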