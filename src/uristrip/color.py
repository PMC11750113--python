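"""Color-space conversions and the CIEDE2000 color difference.

Strip pads and chart patches are compared in CIELAB because Euclidean-ish
distances there track perceived color difference far better than raw RGB.
The conversion chain is the standard one: 8-bit gamma-encoded sRGB →
linear RGB (0.04045 breakpoint) → CIE XYZ (D65) → L*a*b* with the D65/2°
white point.  Grade judgment itself uses the full CIEDE2000 formula
(lightness, chroma and hue terms, G chroma correction, and the blue-region
rotation term R_T), which is the CIE-recommended successor to CIE76/CIE94.

Inputs are 8-bit integers by contract: a float channel is almost always a
sign the caller forgot whether its data are in [0, 1] or [0, 255], so it is
rejected rather than silently rescaled.
"""

from __future__ import annotations

import math
import numbers
from typing import NamedTuple

import numpy as np

from .errors import ColorInputError

__all__ = [
    "D65_WHITE",
    "LabColor",
    "srgb_to_xyz",
    "srgb_to_lab",
    "xyz_to_lab",
    "ciede2000",
]

#: D65 reference white, 2° observer, Y normalised to 100.
D65_WHITE = (95.047, 100.0, 108.883)

# Rec. 709 primaries / D65, the sRGB specification matrix.
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)


class LabColor(NamedTuple):
    """A CIELAB coordinate triple (L* in [0, 100] for in-gamut sRGB)."""

    L: float
    a: float
    b: float


def _validate_srgb(c) -> np.ndarray:
    arr = np.asarray(c)
    if arr.shape != (3,):
        raise ColorInputError(f"expected 3 channels, got shape {arr.shape}")
    for v in arr.tolist() if arr.dtype != object else list(arr):
        if isinstance(v, bool) or not isinstance(v, (numbers.Integral, np.integer)):
            raise ColorInputError(f"sRGB channels must be integers, got {v!r}")
    arr = arr.astype(np.int64)
    if (arr < 0).any() or (arr > 255).any():
        raise ColorInputError(f"sRGB channel out of [0, 255]: {tuple(arr)}")
    return arr


def srgb_to_xyz(c) -> tuple[float, float, float]:
    """Convert an 8-bit sRGB triple to CIE XYZ (D65, Y_white = 100)."""
    arr = _validate_srgb(c)
    v = arr / 255.0
    lin = np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)
    X, Y, Z = 100.0 * (_SRGB_TO_XYZ @ lin)
    return (float(X), float(Y), float(Z))


def _f(t: np.ndarray) -> np.ndarray:
    # CIE 1976 cube-root compression with the linear toe below (6/29)^3
    eps = (6.0 / 29.0) ** 3
    return np.where(t > eps, np.cbrt(t), t / (3 * (6.0 / 29.0) ** 2) + 4.0 / 29.0)


def xyz_to_lab(xyz, white=D65_WHITE) -> LabColor:
    """CIE XYZ → L*a*b* under the given reference white."""
    x = np.asarray(xyz, dtype=float)
    if x.shape != (3,) or not np.all(np.isfinite(x)):
        raise ColorInputError(f"invalid XYZ input: {xyz!r}")
    fx, fy, fz = _f(x / np.asarray(white, dtype=float))
    return LabColor(
        float(116.0 * fy - 16.0), float(500.0 * (fx - fy)), float(200.0 * (fy - fz))
    )


def srgb_to_lab(c, white=D65_WHITE) -> LabColor:
    """Convert an 8-bit sRGB triple to CIELAB (D65/2° by default)."""
    return xyz_to_lab(srgb_to_xyz(c), white=white)


def ciede2000(x, y, kL: float = 1.0, kC: float = 1.0, kH: float = 1.0) -> float:
    """CIEDE2000 color difference ΔE00 between two Lab colors.

    Implements the full formula: arithmetic-mean chroma with the G
    correction, hue angles with wraparound-aware means and differences,
    the weighting functions S_L, S_C, S_H, and the rotation term R_T that
    fixes the blue-region behaviour of CIE94.  Symmetric in its arguments;
    zero iff ``x == y``.  ``kL``, ``kC``, ``kH`` are the parametric
    factors, all 1 in the reference viewing conditions.
    """
    L1, a1, b1 = (float(v) for v in x)
    L2, a2, b2 = (float(v) for v in y)
    for v in (L1, a1, b1, L2, a2, b2):
        if not math.isfinite(v):
            raise ColorInputError("non-finite Lab input")

    C1 = math.hypot(a1, b1)
    C2 = math.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    G = 0.5 * (1.0 - math.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = math.hypot(a1p, b1)
    C2p = math.hypot(a2p, b2)

    # hue angles in degrees in [0, 360); undefined (set to 0) at zero chroma
    h1p = math.degrees(math.atan2(b1, a1p)) % 360.0 if C1p > 0.0 else 0.0
    h2p = math.degrees(math.atan2(b2, a2p)) % 360.0 if C2p > 0.0 else 0.0

    dLp = L2 - L1
    dCp = C2p - C1p

    if C1p * C2p == 0.0:
        dhp = 0.0
    else:
        dhp = h2p - h1p
        if dhp > 180.0:
            dhp -= 360.0
        elif dhp < -180.0:
            dhp += 360.0
    dHp = 2.0 * math.sqrt(C1p * C2p) * math.sin(math.radians(dhp) / 2.0)

    Lbar = 0.5 * (L1 + L2)
    Cbarp = 0.5 * (C1p + C2p)
    if C1p * C2p == 0.0:
        hbarp = h1p + h2p
    elif abs(h1p - h2p) <= 180.0:
        hbarp = 0.5 * (h1p + h2p)
    elif h1p + h2p < 360.0:
        hbarp = 0.5 * (h1p + h2p + 360.0)
    else:
        hbarp = 0.5 * (h1p + h2p - 360.0)

    T = (
        1.0
        - 0.17 * math.cos(math.radians(hbarp - 30.0))
        + 0.24 * math.cos(math.radians(2.0 * hbarp))
        + 0.32 * math.cos(math.radians(3.0 * hbarp + 6.0))
        - 0.20 * math.cos(math.radians(4.0 * hbarp - 63.0))
    )
    dtheta = 30.0 * math.exp(-(((hbarp - 275.0) / 25.0) ** 2))
    RC = 2.0 * math.sqrt(Cbarp**7 / (Cbarp**7 + 25.0**7))
    SL = 1.0 + 0.015 * (Lbar - 50.0) ** 2 / math.sqrt(20.0 + (Lbar - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbarp
    SH = 1.0 + 0.015 * Cbarp * T
    RT = -math.sin(math.radians(2.0 * dtheta)) * RC

    tL = dLp / (kL * SL)
    tC = dCp / (kC * SC)
    tH = dHp / (kH * SH)
    return math.sqrt(tL * tL + tC * tC + tH * tH + RT * tC * tH)
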