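"""Synthetic strip+chart scenes with known ground truth.

No public image set of reacted urine strips photographed next to their
reference chart exists, so the pipeline is validated on rendered scenes:
a template-space canvas carrying the reference chart (nominal grade
colors), a strip whose pads take the colors of an assigned grade
(optionally nudged part-way toward the neighbouring grade to mimic
intermediate reaction intensities), and a textured fiducial border that
gives the feature detector material to work with — flat color patches
alone would starve it.  The scene is then degraded the way a handheld
photograph is: a global illumination gain, a perspective warp, and i.i.d.
Gaussian sensor noise clipped to 8 bits.  Everything is deterministic
given the spec's seed, and the renderer's manifest of true grades is the
oracle for every downstream stage.

The demo layout's grade labels and colors are plausible urinalysis ramps
authored for this package; they are synthetic stand-ins, not the
proprietary colors of any commercial chart.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.transform import ProjectiveTransform, warp as sk_warp

from .color import LabColor, srgb_to_lab
from .errors import ConfigError, UristripError
from .judgment import JudgingMethod, judge_aligned, judge_scene
from .layout import AnalyteDef, ChartLayout, GradeDef

__all__ = [
    "SceneSpec",
    "SceneTruth",
    "demo_layout",
    "render_template",
    "render_scene",
    "random_warp",
    "generate_cohort",
    "judge_cohort",
]

# template geometry (pixels)
_BORDER = 24      # textured fiducial ring
_MARGIN = 8       # quiet zone inside the ring
_PITCH = 24       # patch-to-patch spacing
_PATCH = 18       # drawn patch square
_TEXTURE_SEED = 20220601  # fixed: the template is a constant artifact

# grade series: (label, (r, g, b)) — plausible dipstick ramps, darkening /
# hue-shifting with concentration the way real reagent pads do.  The ramps
# are defined on the full 8-bit range and then scaled by _EXPOSURE so the
# brightest patch keeps headroom below saturation: a judgment is only
# illumination-invariant while no channel clips, so a well-exposed scene
# must tolerate the ±25% gain range without touching 255.
_EXPOSURE = 0.8  # max scaled channel 200 < 255/1.25
_DEMO_SERIES: dict[str, list[tuple[str, tuple[int, int, int]]]] = {
    "protein": [
        ("-", (238, 232, 130)), ("+-", (216, 226, 132)), ("1+", (186, 214, 140)),
        ("2+", (148, 198, 150)), ("3+", (108, 180, 156)), ("4+", (70, 160, 160)),
    ],
    "glucose": [
        ("-", (120, 190, 190)), ("+-", (140, 186, 150)), ("1+", (162, 176, 110)),
        ("2+", (176, 150, 80)), ("3+", (170, 115, 60)), ("4+", (150, 80, 45)),
    ],
    "urobilinogen": [
        ("0.1", (250, 230, 210)), ("2", (245, 200, 185)),
        ("4", (235, 160, 150)), ("8", (215, 110, 115)),
    ],
    "bilirubin": [
        ("-", (250, 240, 200)), ("1+", (240, 220, 170)),
        ("2+", (225, 195, 140)), ("3+", (205, 165, 115)),
    ],
    "ketone": [
        ("-", (245, 230, 200)), ("+-", (230, 200, 190)), ("1+", (205, 160, 175)),
        ("2+", (170, 110, 150)), ("3+", (130, 60, 115)),
    ],
    "specific gravity": [
        ("1.000", (30, 90, 120)), ("1.005", (60, 110, 115)), ("1.010", (95, 130, 105)),
        ("1.015", (130, 150, 95)), ("1.020", (165, 170, 85)), ("1.025", (200, 185, 75)),
        ("1.030", (225, 200, 65)),
    ],
    "occult blood": [
        ("-", (235, 220, 100)), ("+-", (210, 210, 105)), ("1+", (150, 185, 115)),
        ("2+", (90, 150, 120)), ("3+", (40, 110, 110)),
    ],
    "pH": [
        ("5", (235, 150, 70)), ("6", (230, 185, 80)), ("7", (190, 195, 90)),
        ("8", (120, 175, 130)), ("9", (60, 140, 160)),
    ],
    "leukocytes": [
        ("-", (250, 240, 220)), ("+-", (240, 220, 210)), ("1+", (220, 185, 195)),
        ("2+", (190, 140, 170)), ("3+", (150, 95, 145)),
    ],
    "nitrite": [
        ("-", (250, 245, 235)), ("+", (240, 170, 180)),
    ],
    "creatinine": [
        ("10", (245, 215, 120)), ("50", (230, 185, 100)), ("100", (210, 150, 85)),
        ("200", (185, 115, 70)), ("300", (160, 85, 55)),
    ],
    "albumin": [
        ("10", (225, 230, 180)), ("30", (185, 210, 165)),
        ("80", (140, 185, 155)), ("150", (95, 160, 150)),
    ],
}


def demo_layout(window: int = 10) -> ChartLayout:
    """The packaged 12-analyte demo layout (synthetic colors, see module doc)."""
    n_cols = max(len(v) for v in _DEMO_SERIES.values())  # 7
    x0 = _BORDER + _MARGIN
    y0 = _BORDER + _MARGIN
    strip_x = x0 + n_cols * _PITCH + 16
    width = strip_x + _PATCH + _MARGIN + _BORDER + 6
    height = y0 + len(_DEMO_SERIES) * _PITCH + _MARGIN + _BORDER
    half = _PATCH // 2
    analytes = []
    for i, (name, series) in enumerate(_DEMO_SERIES.items()):
        cy = y0 + i * _PITCH + half
        grades = tuple(
            GradeDef(
                label=label,
                reference_color=tuple(
                    int(np.floor(c * _EXPOSURE + 0.5)) for c in color
                ),
                patch_center=(x0 + j * _PITCH + half, cy),
                rank=j,
            )
            for j, (label, color) in enumerate(series)
        )
        analytes.append(
            AnalyteDef(name=name, grades=grades, pad_center=(strip_x + half, cy))
        )
    layout = ChartLayout(
        width=width,
        height=height,
        analytes=tuple(analytes),
        window=window,
        metadata={"patch_size": _PATCH, "texture_seed": _TEXTURE_SEED,
                  "synthetic": True},
    )
    layout.validate()
    return layout


@dataclass
class SceneSpec:
    """Everything needed to render one ground-truth scene deterministically."""

    layout: ChartLayout
    grade_assignment: dict[str, int]
    warp: np.ndarray | None = None          # 3x3, template -> scene coords
    scene_shape: tuple[int, int] | None = None  # (height, width) of the render
    noise_sigma: float = 0.0
    illumination_gain: float = 1.0
    pad_offset: float = 0.0  # fraction toward the neighbouring grade's color
    seed: int = 0
    specimen_id: str = "s0000"

    def validate(self) -> None:
        if self.noise_sigma < 0:
            raise ConfigError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.illumination_gain <= 0:
            raise ConfigError(f"illumination_gain must be > 0, got {self.illumination_gain}")
        if not 0.0 <= self.pad_offset <= 1.0:
            raise ConfigError(f"pad_offset must be in [0, 1], got {self.pad_offset}")
        for a in self.layout.analytes:
            if a.name not in self.grade_assignment:
                raise ConfigError(f"grade_assignment missing analyte {a.name!r}")
            r = self.grade_assignment[a.name]
            if not 0 <= r < len(a.grades):
                raise ConfigError(
                    f"analyte {a.name!r}: assigned rank {r} outside 0..{len(a.grades) - 1}"
                )
        if self.warp is not None:
            H = np.asarray(self.warp, dtype=float)
            if H.shape != (3, 3) or not np.all(np.isfinite(H)) or abs(np.linalg.det(H)) < 1e-12:
                raise ConfigError("invalid warp matrix")


@dataclass
class SceneTruth:
    """A rendered scene plus the oracle the tests judge against."""

    image: np.ndarray
    manifest: dict[str, int]
    true_lab: dict[str, LabColor]  # pad colors after gain, before warp/noise
    spec: SceneSpec = field(repr=False, default=None)


def _patch_rect(center, size: int):
    cx, cy = (int(round(center[0])), int(round(center[1])))
    half = size // 2
    return slice(cy - half, cy - half + size), slice(cx - half, cx - half + size)


def _base_canvas(layout: ChartLayout, pad_rgb: dict[str, tuple[int, int, int]]) -> np.ndarray:
    size = int(layout.metadata.get("patch_size", _PATCH))
    canvas = np.full((layout.height, layout.width, 3), 200, dtype=np.uint8)
    # fiducial ring: block texture + pixel noise, fixed seed — the template
    # is a printed artifact, identical in every scene
    rng = np.random.default_rng(int(layout.metadata.get("texture_seed", _TEXTURE_SEED)))
    blocks = rng.integers(0, 256, size=(layout.height // 8 + 1, layout.width // 8 + 1, 3))
    block_tex = np.kron(blocks, np.ones((8, 8, 1)))[: layout.height, : layout.width]
    pixel_tex = rng.integers(0, 256, size=(layout.height, layout.width, 3))
    tex = (0.6 * block_tex + 0.4 * pixel_tex).astype(np.uint8)
    b = _BORDER
    canvas[:b, :] = tex[:b, :]
    canvas[-b:, :] = tex[-b:, :]
    canvas[:, :b] = tex[:, :b]
    canvas[:, -b:] = tex[:, -b:]
    # strip backing: a white band behind the pad column
    pad_xs = [a.pad_center[0] for a in layout.analytes]
    pad_ys = [a.pad_center[1] for a in layout.analytes]
    x_lo = int(min(pad_xs)) - size // 2 - 3
    x_hi = int(max(pad_xs)) + size // 2 + 3
    y_lo = int(min(pad_ys)) - size // 2 - 6
    y_hi = int(max(pad_ys)) + size // 2 + 6
    canvas[y_lo:y_hi, x_lo:x_hi] = 245
    for a in layout.analytes:
        for g in a.grades:
            ys, xs = _patch_rect(g.patch_center, size)
            canvas[ys, xs] = g.reference_color
        ys, xs = _patch_rect(a.pad_center, size)
        canvas[ys, xs] = pad_rgb[a.name]
    return canvas


def render_template(layout: ChartLayout) -> np.ndarray:
    """The registration template: chart at nominal colors, pads neutral gray."""
    return _base_canvas(layout, {a.name: (170, 170, 170) for a in layout.analytes})


def _pad_color(analyte: AnalyteDef, rank: int, offset: float) -> np.ndarray:
    c0 = np.asarray(analyte.grades[rank].reference_color, dtype=float)
    if offset == 0.0:
        return c0
    # nudge toward the next grade up (or down, at the top of the scale)
    other = rank + 1 if rank + 1 < len(analyte.grades) else rank - 1
    c1 = np.asarray(analyte.grades[other].reference_color, dtype=float)
    return (1.0 - offset) * c0 + offset * c1


def render_scene(spec: SceneSpec) -> SceneTruth:
    """Render a ground-truth scene: draw → gain → warp → noise → clip."""
    spec.validate()
    layout = spec.layout
    pad_drawn = {
        a.name: np.floor(
            _pad_color(a, spec.grade_assignment[a.name], spec.pad_offset) + 0.5
        ).astype(int)
        for a in layout.analytes
    }
    # the truth Lab is the drawn pad color after the same gain+rounding the
    # rendered pixels undergo, so a noise-free identity render samples back
    # to it exactly
    gained = {
        name: np.clip(np.floor(c * spec.illumination_gain + 0.5), 0, 255).astype(int)
        for name, c in pad_drawn.items()
    }
    canvas = _base_canvas(layout, {n: tuple(int(v) for v in c) for n, c in pad_drawn.items()})
    img = np.clip(canvas.astype(float) * spec.illumination_gain, 0, 255)
    if spec.warp is not None:
        H = np.asarray(spec.warp, dtype=float)
        shape = spec.scene_shape or (layout.height, layout.width)
        # warp() maps output (scene) coords to input (template) coords: inv(H)
        img = sk_warp(
            img / 255.0,
            ProjectiveTransform(matrix=np.linalg.inv(H)),
            output_shape=shape,
            order=1,
            cval=0.75,
        ) * 255.0
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    out = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    true_lab = {name: srgb_to_lab(tuple(c)) for name, c in gained.items()}
    return SceneTruth(
        image=out,
        manifest=dict(spec.grade_assignment),
        true_lab=true_lab,
        spec=spec,
    )


def random_warp(
    layout: ChartLayout, max_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, tuple[int, int]]:
    """A bounded random perspective: corners displaced ≤ ``max_frac``·min(W, H).

    Returns the template→scene homography and the scene canvas shape, which
    is padded so the displaced content stays fully visible.
    """
    w, h = layout.width, layout.height
    d = max_frac * min(w, h)
    margin = int(np.ceil(d))
    src = np.array([[0, 0], [w, 0], [w, h], [0, h]], dtype=float)
    dst = src + rng.uniform(-d, d, size=(4, 2)) + margin
    tform = ProjectiveTransform.from_estimate(src, dst)
    if not tform:
        raise UristripError("degenerate random warp (should not happen)")
    H = tform.params / tform.params[2, 2]
    return H, (h + 2 * margin, w + 2 * margin)


def _normalise_distribution(grade_distribution, layout: ChartLayout) -> dict[str, np.ndarray]:
    probs: dict[str, np.ndarray] = {}
    for a in layout.analytes:
        k = len(a.grades)
        if grade_distribution == "uniform":
            p = np.full(k, 1.0 / k)
        elif isinstance(grade_distribution, dict):
            p = np.asarray(grade_distribution[a.name], dtype=float)
        else:
            p = np.asarray(grade_distribution, dtype=float)
        if len(p) != k:
            raise ConfigError(
                f"analyte {a.name!r}: distribution has {len(p)} entries, needs {k}"
            )
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigError(
                f"analyte {a.name!r}: grade distribution must be non-negative and sum to 1"
            )
        probs[a.name] = p
    return probs


def generate_cohort(
    n: int,
    layout: ChartLayout | None = None,
    grade_distribution="uniform",
    diagnostic_analyte: str = "albumin",
    diagnostic_threshold_rank: int = 1,
    noise_sigma: float = 0.0,
    illumination_gain: float = 1.0,
    pad_offset: float = 0.0,
    warp_frac: float | None = None,
    seed: int = 0,
) -> tuple[list[SceneSpec], pd.DataFrame]:
    """Simulate a specimen cohort: scene specs plus the reference truth table.

    Each specimen gets an independent grade assignment drawn from
    ``grade_distribution`` per analyte, and (for the diagnostic analyte) a
    binary disease label ``true_rank >= diagnostic_threshold_rank`` — the
    microalbuminuria-style positivity rule.
    """
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    layout = layout or demo_layout()
    probs = _normalise_distribution(grade_distribution, layout)
    master = np.random.default_rng(seed)
    specs: list[SceneSpec] = []
    rows = []
    for i in range(n):
        sid = f"s{i:04d}"
        assignment = {
            a.name: int(master.choice(len(a.grades), p=probs[a.name]))
            for a in layout.analytes
        }
        if warp_frac:
            H, shape = random_warp(layout, warp_frac, master)
        else:
            H, shape = None, None
        specs.append(
            SceneSpec(
                layout=layout,
                grade_assignment=assignment,
                warp=H,
                scene_shape=shape,
                noise_sigma=noise_sigma,
                illumination_gain=illumination_gain,
                pad_offset=pad_offset,
                seed=int(master.integers(0, 2**31 - 1)),
                specimen_id=sid,
            )
        )
        for a in layout.analytes:
            r = assignment[a.name]
            rows.append(
                {
                    "specimen_id": sid,
                    "analyte": a.name,
                    "reference_rank": r,
                    "reference_label": a.grades[r].label,
                    "disease": bool(r >= diagnostic_threshold_rank)
                    if a.name == diagnostic_analyte
                    else None,
                }
            )
    return specs, pd.DataFrame(rows)


def judge_cohort(
    specs: list[SceneSpec],
    method: JudgingMethod = JudgingMethod.APPROXIMATE,
    register: bool = False,
    template: np.ndarray | None = None,
) -> pd.DataFrame:
    """Render and judge every scene of a cohort.

    With ``register=False`` (identity-warp cohorts) the rendered scene is
    judged directly in template space; with ``register=True`` the full
    feature-matching pipeline runs against ``template`` (rendered from the
    layout if not supplied).
    """
    rows = []
    for spec in specs:
        truth = render_scene(spec)
        if register:
            tmpl = template if template is not None else render_template(spec.layout)
            report = judge_scene(truth.image, spec.layout, tmpl, method=method)
            results = report.results
        else:
            if spec.warp is not None:
                raise ConfigError(
                    "cohort scene has a perspective warp; judge with register=True"
                )
            results = judge_aligned(truth.image, spec.layout, method)
        for r in results:
            rows.append(
                {
                    "specimen_id": spec.specimen_id,
                    "analyte": r.analyte,
                    "program_rank": r.chosen_rank,
                    "program_label": r.chosen_label,
                    "min_delta_e": min(r.delta_e),
                }
            )
    return pd.DataFrame(rows)
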