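"""Grade judgment: turn sampled colors into an analyte grade call.

The default reading is the *approximate selection* method: the strip pad is
assigned the grade of the chart patch with the smallest CIEDE2000 distance,
i.e. the nearest reference color in perceptual space.  Two alternative
readings used by human assessors are also provided: *round down* (if the
pad has not reached a chart color, call the lower concentration) and
*round up* (if the pad is even slightly darker, call the higher one).
These are operationalised as the floor/ceiling of the pad's fractional
position along the piecewise-linear path through the grade colors in Lab
space — the closest computational interpretation of the visual rules; they
are selectable but non-default.

Ties in the approximate method break toward the lower rank: a screening
read should not over-call on ambiguity.  The tie is flagged in the result.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from enum import Enum
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .color import ciede2000
from .errors import JudgmentError
from .layout import ChartLayout, PanelObservation, extract_observations
from .registration import RegistrationConfig, RegistrationResult, register

__all__ = [
    "JudgingMethod",
    "JudgmentResult",
    "SceneReport",
    "judge",
    "judge_aligned",
    "judge_scene",
    "fractional_position",
]


class JudgingMethod(str, Enum):
    APPROXIMATE = "approximate"
    ROUND_DOWN = "round_down"
    ROUND_UP = "round_up"


@dataclass
class JudgmentResult:
    """A grade call for one analyte, with its full ΔE00 audit trail."""

    analyte: str
    chosen_rank: int
    chosen_label: str
    delta_e: tuple[float, ...]
    method: JudgingMethod
    tied: bool = False


@dataclass
class SceneReport:
    """End-to-end output for one photographed scene."""

    results: list[JudgmentResult]
    registration: RegistrationResult | None

    def to_json(self) -> str:
        doc = {
            "results": [
                {**asdict(r), "method": r.method.value} for r in self.results
            ],
            "registration": None
            if self.registration is None
            else {
                "homography": self.registration.homography.tolist(),
                "n_matches": self.registration.n_matches,
                "n_inliers": self.registration.n_inliers,
                "inlier_ratio": self.registration.inlier_ratio,
            },
        }
        return json.dumps(doc, indent=2)

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as f:
            w = csv.writer(f, quoting=csv.QUOTE_NONNUMERIC)
            w.writerow(["analyte", "label", "rank", "min_delta_e", "method"])
            for r in self.results:
                w.writerow(
                    [r.analyte, r.chosen_label, r.chosen_rank,
                     round(min(r.delta_e), 4), r.method.value]
                )


def fractional_position(strip_lab, grade_labs) -> float:
    """Position of the strip color along the grade-color path in Lab space.

    The grade colors form a polyline in Lab; the strip color is orthogonally
    projected onto each segment (parameter clamped to the segment) and the
    closest projection wins, ties toward the lower segment.  The result is
    a real number in [0, n-1] whose floor/ceil are the round-down/round-up
    grade calls.
    """
    pts = np.asarray(grade_labs, dtype=float)
    p = np.asarray(strip_lab, dtype=float)
    best = (np.inf, 0.0)
    for k in range(len(pts) - 1):
        d = pts[k + 1] - pts[k]
        denom = float(d @ d)
        t = 0.0 if denom == 0 else float(np.clip((p - pts[k]) @ d / denom, 0.0, 1.0))
        dist = float(np.linalg.norm(p - (pts[k] + t * d)))
        if dist < best[0] - 1e-12:
            best = (dist, k + t)
    return best[1]


def judge(obs: PanelObservation, method: JudgingMethod = JudgingMethod.APPROXIMATE) -> JudgmentResult:
    """Call the grade for one analyte observation."""
    method = JudgingMethod(method)
    if len(obs.grade_colors) < 2:
        raise JudgmentError(
            f"analyte {obs.analyte!r}: need >= 2 grade colors, got {len(obs.grade_colors)}"
        )
    de = tuple(ciede2000(obs.strip_color, g) for g in obs.grade_colors)
    if method is JudgingMethod.APPROXIMATE:
        rank = int(np.argmin(de))  # argmin takes the first == lowest rank on ties
        tied = sum(1 for v in de if v == de[rank]) > 1
    else:
        pos = fractional_position(obs.strip_color, obs.grade_colors)
        rank = int(np.floor(pos)) if method is JudgingMethod.ROUND_DOWN else int(np.ceil(pos))
        rank = int(np.clip(rank, 0, len(obs.grade_colors) - 1))
        tied = False
    return JudgmentResult(
        analyte=obs.analyte,
        chosen_rank=rank,
        chosen_label=obs.grade_labels[rank],
        delta_e=de,
        method=method,
        tied=tied,
    )


def judge_aligned(
    aligned: np.ndarray,
    layout: ChartLayout,
    method: JudgingMethod = JudgingMethod.APPROXIMATE,
    valid_mask: np.ndarray | None = None,
    aggregate: str = "mean",
) -> list[JudgmentResult]:
    """Judge every analyte of an image already in template space."""
    obs = extract_observations(aligned, layout, valid_mask=valid_mask, aggregate=aggregate)
    return [judge(o, method) for o in obs]


def judge_scene(
    image,
    layout: ChartLayout,
    template,
    method: JudgingMethod = JudgingMethod.APPROXIMATE,
    reg_config: RegistrationConfig | None = None,
    aggregate: str = "mean",
) -> SceneReport:
    """Full pipeline: registration → warping → sampling → judgment.

    ``image`` and ``template`` may be file paths (PNG/JPEG) or uint8 arrays.
    """
    img = iio.imread(image) if isinstance(image, (str, Path)) else np.asarray(image)
    tmpl = iio.imread(template) if isinstance(template, (str, Path)) else np.asarray(template)
    if img.ndim == 3 and img.shape[2] == 4:  # drop alpha from RGBA PNGs
        img = img[:, :, :3]
    if tmpl.ndim == 3 and tmpl.shape[2] == 4:
        tmpl = tmpl[:, :, :3]
    aligned, mask, res = register(img, tmpl, reg_config)
    results = judge_aligned(aligned, layout, method, valid_mask=mask, aggregate=aggregate)
    return SceneReport(results=results, registration=res)
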