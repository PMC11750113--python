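"""Chart layout description and patch color sampling.

A :class:`ChartLayout` describes, in template pixel coordinates, where every
reference-chart color patch and every strip reagent pad sits, which grade
label and nominal color each patch carries, and how large the sampling
window is.  Coordinates are 0-based, x to the right, y down, matching the
raster convention of the image stack.

Sampling convention: a ``window``×``window`` block is read around each
center.  For an even window the block is anchored so the nominal center is
the lower-right pixel of the four central ones, i.e. the block spans the
half-open ranges ``[c - w//2, c - w//2 + w)`` on each axis (for odd ``w``
this is the usual centered block).  The block is reduced channel-wise by
the arithmetic mean (median selectable for robustness to dust or glare)
and rounded half-up back to 8 bits.

Nominal grade colors in the layout serve validation and scene synthesis;
at judgment time the chart patches are sampled from the photographed scene
itself, so chart and strip share one imaging path and global illumination
shifts cancel in the comparison.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .color import LabColor, ciede2000, srgb_to_lab
from .errors import ConfigError, ExtractionError, SamplingError

__all__ = [
    "GradeDef",
    "AnalyteDef",
    "ChartLayout",
    "PanelObservation",
    "load_layout",
    "save_layout",
    "sample_patch",
    "extract_observations",
    "ANALYTE_NAMES",
]

#: The 12 analytes a full urinalysis strip carries.
ANALYTE_NAMES = (
    "protein",
    "glucose",
    "urobilinogen",
    "bilirubin",
    "ketone",
    "specific gravity",
    "occult blood",
    "pH",
    "leukocytes",
    "nitrite",
    "creatinine",
    "albumin",
)


@dataclass(frozen=True)
class GradeDef:
    """One color block of an analyte's reference series."""

    label: str
    reference_color: tuple[int, int, int]
    patch_center: tuple[float, float]
    rank: int


@dataclass(frozen=True)
class AnalyteDef:
    """An analyte panel: its ordered grade series and its strip pad."""

    name: str
    grades: tuple[GradeDef, ...]
    pad_center: tuple[float, float]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(g.label for g in self.grades)

    def rank_of(self, label: str) -> int:
        for g in self.grades:
            if g.label == label:
                return g.rank
        raise KeyError(label)


@dataclass
class ChartLayout:
    """Template-space geometry plus reference colors for a chart+strip scene."""

    width: int
    height: int
    analytes: tuple[AnalyteDef, ...]
    window: int = 10
    metadata: dict = field(default_factory=dict)

    def analyte(self, name: str) -> AnalyteDef:
        for a in self.analytes:
            if a.name == name:
                return a
        raise KeyError(name)

    def validate(self) -> None:
        """Check every structural invariant; raise ConfigError naming the offender."""
        if self.window < 1:
            raise ConfigError(f"window must be >= 1, got {self.window}")
        if not self.analytes:
            raise ConfigError("layout defines no analytes")
        names = [a.name for a in self.analytes]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ConfigError(f"duplicate analyte names: {dup}")
        half = self.window // 2
        centers: list[tuple[str, str, tuple[float, float]]] = []
        for a in self.analytes:
            if len(a.grades) < 2:
                raise ConfigError(f"analyte {a.name!r} needs >= 2 grades")
            ranks = [g.rank for g in a.grades]
            if ranks != list(range(len(a.grades))):
                raise ConfigError(
                    f"analyte {a.name!r}: ranks must be consecutive from 0, got {ranks}"
                )
            labs = [srgb_to_lab(g.reference_color) for g in a.grades]
            for i in range(len(labs)):
                for j in range(i + 1, len(labs)):
                    if ciede2000(labs[i], labs[j]) <= 0.5:
                        raise ConfigError(
                            f"analyte {a.name!r}: grades {a.grades[i].label!r} and "
                            f"{a.grades[j].label!r} have nearly identical reference "
                            "colors (dE00 <= 0.5); judgment would be ill-posed"
                        )
            centers.append((a.name, "pad", a.pad_center))
            centers.extend((a.name, f"grade {g.label!r}", g.patch_center) for g in a.grades)
        for name, what, (cx, cy) in centers:
            if not (half <= cx <= self.width - half and half <= cy <= self.height - half):
                raise ConfigError(
                    f"analyte {name!r} {what}: center ({cx}, {cy}) is closer than "
                    f"half a window ({half} px) to the border of the "
                    f"{self.width}x{self.height} template"
                )
        # overlapping sampling windows are suspicious but not fatal
        pts = [(c, f"{n}/{w}") for n, w, c in centers]
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                (x1, y1), id1 = pts[i]
                (x2, y2), id2 = pts[j]
                if abs(x1 - x2) < self.window and abs(y1 - y2) < self.window:
                    warnings.warn(
                        f"sampling windows overlap: {id1} and {id2}", stacklevel=2
                    )


@dataclass
class PanelObservation:
    """Sampled Lab colors for one analyte: the strip pad and its grade series."""

    analyte: str
    strip_color: LabColor
    grade_colors: tuple[LabColor, ...]
    grade_labels: tuple[str, ...]


def _as_center(value, where: str) -> tuple[float, float]:
    try:
        x, y = value
        return (float(x), float(y))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: expected a 2-element center, got {value!r}") from exc


def _as_color(value, where: str) -> tuple[int, int, int]:
    try:
        r, g, b = (int(v) for v in value)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: expected an RGB triple, got {value!r}") from exc
    if not all(0 <= v <= 255 for v in (r, g, b)):
        raise ConfigError(f"{where}: RGB channel out of [0, 255]: {value!r}")
    return (r, g, b)


def load_layout(path) -> ChartLayout:
    """Parse and validate a layout config file (YAML or JSON)."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read layout file {path}: {exc}") from exc
    try:
        doc = yaml.safe_load(text)  # JSON is a YAML subset
    except yaml.YAMLError as exc:
        raise ConfigError(f"layout file {path} is not valid YAML/JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"layout file {path} is empty or not a mapping")
    try:
        tmpl = doc["template"]
        width, height = int(tmpl["width"]), int(tmpl["height"])
        raw_analytes = doc["analytes"]
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"layout file {path}: missing field {exc}") from exc
    analytes = []
    for ra in raw_analytes:
        if "name" not in ra:
            raise ConfigError(f"layout file {path}: analyte entry without 'name'")
        name = str(ra["name"])
        grades = []
        for k, rg in enumerate(ra.get("grades", [])):
            where = f"analyte {name!r} grade #{k}"
            if "label" not in rg:
                raise ConfigError(f"{where}: missing 'label'")
            grades.append(
                GradeDef(
                    label=str(rg["label"]),
                    reference_color=_as_color(rg.get("color"), where),
                    patch_center=_as_center(rg.get("center"), where),
                    rank=k,
                )
            )
        analytes.append(
            AnalyteDef(
                name=name,
                grades=tuple(grades),
                pad_center=_as_center(ra.get("pad_center"), f"analyte {name!r} pad_center"),
            )
        )
    layout = ChartLayout(
        width=width,
        height=height,
        analytes=tuple(analytes),
        window=int(doc.get("window", 10)),
        metadata=dict(doc.get("metadata", {})),
    )
    layout.validate()
    return layout


def save_layout(layout: ChartLayout, path) -> None:
    """Serialise a layout to YAML (or JSON if the suffix is .json)."""
    doc = {
        "template": {"width": layout.width, "height": layout.height},
        "window": layout.window,
        "metadata": layout.metadata,
        "analytes": [
            {
                "name": a.name,
                "pad_center": [float(a.pad_center[0]), float(a.pad_center[1])],
                "grades": [
                    {
                        "label": g.label,
                        "color": list(g.reference_color),
                        "center": [float(g.patch_center[0]), float(g.patch_center[1])],
                    }
                    for g in a.grades
                ],
            }
            for a in layout.analytes
        ],
    }
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def _window_slices(center, window: int):
    cx, cy = (int(round(center[0])), int(round(center[1])))
    x0 = cx - window // 2
    y0 = cy - window // 2
    return slice(y0, y0 + window), slice(x0, x0 + window)


def sample_patch(img: np.ndarray, center, window: int, aggregate: str = "mean"):
    """Representative 8-bit color of a window×window block around ``center``.

    Returns an ``(r, g, b)`` tuple of Python ints (mean or median per
    channel, rounded half-up).  Raises :class:`SamplingError` if the block
    does not fit inside the image.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise SamplingError(f"expected an HxWx3 image, got shape {img.shape}")
    ys, xs = _window_slices(center, window)
    h, w = img.shape[:2]
    if ys.start < 0 or xs.start < 0 or ys.stop > h or xs.stop > w:
        raise SamplingError(
            f"sampling window {window}px at center {tuple(center)} exceeds "
            f"image bounds {w}x{h}"
        )
    block = img[ys, xs].astype(float)
    if aggregate == "mean":
        vals = block.mean(axis=(0, 1))
    elif aggregate == "median":
        vals = np.median(block, axis=(0, 1))
    else:
        raise ConfigError(f"unknown aggregate {aggregate!r}")
    r, g, b = (int(v) for v in np.floor(vals + 0.5))
    return (r, g, b)


def extract_observations(
    aligned: np.ndarray,
    layout: ChartLayout,
    valid_mask: np.ndarray | None = None,
    aggregate: str = "mean",
) -> list[PanelObservation]:
    """Sample every pad and patch of an aligned (template-space) image.

    ``valid_mask``, if given, marks pixels that carry real scene content
    (False where the warp had no source data); a window touching invalid
    pixels raises :class:`ExtractionError` naming the analyte and patch.
    """
    out: list[PanelObservation] = []
    w = layout.window

    def _check_mask(center, what: str, analyte: str):
        if valid_mask is None:
            return
        ys, xs = _window_slices(center, w)
        if not bool(valid_mask[ys, xs].all()):
            raise ExtractionError(
                f"analyte {analyte!r} {what}: sampling window touches "
                "out-of-warp (sentinel) pixels"
            )

    for a in layout.analytes:
        _check_mask(a.pad_center, "strip pad", a.name)
        strip = srgb_to_lab(sample_patch(aligned, a.pad_center, w, aggregate))
        grade_labs = []
        for g in a.grades:
            _check_mask(g.patch_center, f"grade patch {g.label!r}", a.name)
            grade_labs.append(srgb_to_lab(sample_patch(aligned, g.patch_center, w, aggregate)))
        out.append(
            PanelObservation(
                analyte=a.name,
                strip_color=strip,
                grade_colors=tuple(grade_labs),
                grade_labels=a.labels,
            )
        )
    return out
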