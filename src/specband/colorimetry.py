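"""Colorimetric primitives: sRGB linearization, RGB→XYZ, XYZ→Lab, CIEDE2000.

Conventions used throughout the package:

* gamma-encoded sRGB channels are floats in [0, 1] (8-bit values / 255);
* tristimulus values are on the 0–100 scale, so the adopted white has
  Y = 100;
* every XYZ triple carries a provenance tag — ``camera`` (derived from an
  endoscope frame), ``spectrum`` (integrated from a measured reflectance
  spectrum) or ``corrected`` (camera XYZ after polynomial correction).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np

__all__ = [
    "SRGB_TO_XYZ_STANDARD",
    "SRGB_TO_XYZ_PUBLISHED_VARIANT",
    "D65_WHITE",
    "TristimulusXYZ",
    "LabColor",
    "linearize_component",
    "linearize",
    "gamma_encode",
    "srgb_to_xyz",
    "xyz_to_lab",
    "delta_e_2000",
    "rgb_to_xyz_matrix",
]

#: Standard IEC 61966-2-1 linear-sRGB → XYZ (D65) matrix.
SRGB_TO_XYZ_STANDARD = np.array(
    [
        [0.4124, 0.3576, 0.1805],
        [0.2126, 0.7152, 0.0722],
        [0.0193, 0.1192, 0.9505],
    ]
)

#: A published variant with a perturbed first row (0.4104 and a duplicated
#: 0.3576); not a valid sRGB matrix, offered for reproducing pipelines that
#: used it. Select with ``rgb_to_xyz_matrix("published")``.
SRGB_TO_XYZ_PUBLISHED_VARIANT = np.array(
    [
        [0.4104, 0.3576, 0.3576],
        [0.2126, 0.7152, 0.0722],
        [0.0193, 0.1192, 0.9505],
    ]
)

#: D65 reference white on the 0–100 scale (row sums of the standard matrix).
D65_WHITE = tuple(SRGB_TO_XYZ_STANDARD.sum(axis=1) * 100.0)

_SRGB_LINEAR_THRESHOLD = 0.04045
_LAB_EPS = (6.0 / 29.0) ** 3  # ≈ 0.008856
_LAB_KAPPA_SLOPE = 7.787
_LAB_OFFSET = 4.0 / 29.0  # ≈ 0.137931


@dataclasses.dataclass(frozen=True)
class TristimulusXYZ:
    """An (X, Y, Z) triple on the 0–100 scale with a provenance tag."""

    x: float
    y: float
    z: float
    provenance: str = "camera"

    _TAGS = ("camera", "spectrum", "corrected")

    def __post_init__(self) -> None:
        if self.provenance not in self._TAGS:
            raise ValueError(
                f"provenance must be one of {self._TAGS}, got {self.provenance!r}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a: Iterable[float], provenance: str) -> "TristimulusXYZ":
        x, y, z = (float(v) for v in a)
        return cls(x, y, z, provenance)


@dataclasses.dataclass(frozen=True)
class LabColor:
    """CIELAB coordinates (L*, a*, b*)."""

    l_star: float
    a_star: float
    b_star: float

    def as_array(self) -> np.ndarray:
        return np.array([self.l_star, self.a_star, self.b_star], dtype=float)


def rgb_to_xyz_matrix(variant: str = "standard") -> np.ndarray:
    """Return the linear-RGB→XYZ matrix for ``variant`` ('standard' | 'published')."""
    if variant == "standard":
        return SRGB_TO_XYZ_STANDARD.copy()
    if variant == "published":
        return SRGB_TO_XYZ_PUBLISHED_VARIANT.copy()
    raise ValueError(f"unknown matrix variant {variant!r}")


def linearize_component(v: float, channel: str = "value") -> float:
    """Remove sRGB gamma from a single channel value in [0, 1].

    Piecewise: ``v / 12.92`` below the 0.04045 knee, otherwise
    ``((v + 0.055) / 1.055) ** 2.4``.
    """
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"sRGB channel {channel} out of range [0, 1]: {v!r}")
    if v <= _SRGB_LINEAR_THRESHOLD:
        return v / 12.92
    return ((v + 0.055) / 1.055) ** 2.4


def linearize(rgb: np.ndarray) -> np.ndarray:
    """Vectorized sRGB linearization; input array values must lie in [0, 1]."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.size and (rgb.min() < 0.0 or rgb.max() > 1.0):
        raise ValueError("sRGB values out of range [0, 1]")
    return np.where(
        rgb <= _SRGB_LINEAR_THRESHOLD,
        rgb / 12.92,
        ((rgb + 0.055) / 1.055) ** 2.4,
    )


def gamma_encode(linear: np.ndarray) -> np.ndarray:
    """Inverse of :func:`linearize` on [0, 1] (values clipped before encoding)."""
    lin = np.clip(np.asarray(linear, dtype=float), 0.0, 1.0)
    return np.where(
        lin <= _SRGB_LINEAR_THRESHOLD / 12.92,
        lin * 12.92,
        1.055 * lin ** (1.0 / 2.4) - 0.055,
    )


def srgb_to_xyz(
    rgb: Iterable[float],
    matrix: np.ndarray | None = None,
    adaptation: Iterable[float] | None = None,
) -> TristimulusXYZ:
    """Map a gamma-encoded sRGB triple to camera tristimulus values.

    ``XYZ = diag(adaptation) · matrix · linearize(rgb) × 100``. The diagonal
    chromatic-adaptation ratios (source white over capture white, per
    channel) default to identity; they must be strictly positive.
    """
    arr = srgb_to_xyz_array(np.asarray(list(rgb), dtype=float), matrix, adaptation)
    return TristimulusXYZ.from_array(arr, "camera")


def srgb_to_xyz_array(
    rgb: np.ndarray,
    matrix: np.ndarray | None = None,
    adaptation: Iterable[float] | None = None,
) -> np.ndarray:
    """Vectorized form of :func:`srgb_to_xyz` for (..., 3) arrays → (..., 3)."""
    if matrix is None:
        matrix = SRGB_TO_XYZ_STANDARD
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape[-1] != 3:
        raise ValueError("expected trailing dimension of 3 (R, G, B)")
    lin = linearize(rgb)
    xyz = lin @ matrix.T * 100.0
    if adaptation is not None:
        diag = np.asarray(list(adaptation), dtype=float)
        if diag.shape != (3,) or np.any(diag <= 0.0):
            raise ValueError("adaptation diagonal must be 3 strictly positive ratios")
        xyz = xyz * diag
    return xyz


def _lab_f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(t > _LAB_EPS, np.cbrt(t), _LAB_KAPPA_SLOPE * t + _LAB_OFFSET)


def xyz_to_lab(
    xyz: TristimulusXYZ | Iterable[float],
    white: Iterable[float] = D65_WHITE,
) -> LabColor:
    """Convert tristimulus values to CIELAB under the given reference white."""
    arr = xyz.as_array() if isinstance(xyz, TristimulusXYZ) else np.asarray(list(xyz), float)
    lab = xyz_to_lab_array(arr, white)
    return LabColor(*lab)


def xyz_to_lab_array(
    xyz: np.ndarray, white: Iterable[float] = D65_WHITE
) -> np.ndarray:
    """Vectorized XYZ→Lab for (..., 3) arrays on the 0–100 scale."""
    wp = np.asarray(list(white), dtype=float)
    if wp.shape != (3,) or np.any(wp <= 0.0):
        raise ValueError("white point must be 3 strictly positive values")
    xyz = np.asarray(xyz, dtype=float)
    f = _lab_f(xyz / wp)
    l_star = 116.0 * f[..., 1] - 16.0
    a_star = 500.0 * (f[..., 0] - f[..., 1])
    b_star = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([l_star, a_star, b_star], axis=-1)


def delta_e_2000(
    c1: LabColor | Iterable[float],
    c2: LabColor | Iterable[float],
    kl: float = 1.0,
    kc: float = 1.0,
    kh: float = 1.0,
) -> float:
    """CIEDE2000 color difference between two CIELAB colors.

    Implements the standard formula (lightness, chroma and hue terms with
    the rotation correction), with the usual unit parametric factors.
    """
    a = c1.as_array() if isinstance(c1, LabColor) else np.asarray(list(c1), float)
    b = c2.as_array() if isinstance(c2, LabColor) else np.asarray(list(c2), float)
    return float(delta_e_2000_array(a, b, kl, kc, kh))


def delta_e_2000_array(
    lab1: np.ndarray,
    lab2: np.ndarray,
    kl: float = 1.0,
    kc: float = 1.0,
    kh: float = 1.0,
) -> np.ndarray:
    """Vectorized CIEDE2000 for (..., 3) Lab arrays."""
    lab1 = np.asarray(lab1, dtype=float)
    lab2 = np.asarray(lab2, dtype=float)
    l1, a1, b1 = lab1[..., 0], lab1[..., 1], lab1[..., 2]
    l2, a2, b2 = lab2[..., 0], lab2[..., 1], lab2[..., 2]

    c1 = np.hypot(a1, b1)
    c2 = np.hypot(a2, b2)
    c_bar = 0.5 * (c1 + c2)
    g = 0.5 * (1.0 - np.sqrt(c_bar**7 / (c_bar**7 + 25.0**7)))
    a1p = (1.0 + g) * a1
    a2p = (1.0 + g) * a2
    c1p = np.hypot(a1p, b1)
    c2p = np.hypot(a2p, b2)

    h1p = np.degrees(np.arctan2(b1, a1p)) % 360.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360.0
    # hue angle is undefined for zero chroma
    h1p = np.where(c1p == 0.0, 0.0, h1p)
    h2p = np.where(c2p == 0.0, 0.0, h2p)

    dlp = l2 - l1
    dcp = c2p - c1p

    dh = h2p - h1p
    dh = np.where(dh > 180.0, dh - 360.0, dh)
    dh = np.where(dh < -180.0, dh + 360.0, dh)
    dh = np.where(c1p * c2p == 0.0, 0.0, dh)
    dhp = 2.0 * np.sqrt(c1p * c2p) * np.sin(np.radians(0.5 * dh))

    lbp = 0.5 * (l1 + l2)
    cbp = 0.5 * (c1p + c2p)

    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbp = np.where(
        c1p * c2p == 0.0,
        hsum,
        np.where(
            habs <= 180.0,
            0.5 * hsum,
            np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)),
        ),
    )

    t = (
        1.0
        - 0.17 * np.cos(np.radians(hbp - 30.0))
        + 0.24 * np.cos(np.radians(2.0 * hbp))
        + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
        - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0))
    )
    dtheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    rc = 2.0 * np.sqrt(cbp**7 / (cbp**7 + 25.0**7))
    sl = 1.0 + 0.015 * (lbp - 50.0) ** 2 / np.sqrt(20.0 + (lbp - 50.0) ** 2)
    sc = 1.0 + 0.045 * cbp
    sh = 1.0 + 0.015 * cbp * t
    rt = -np.sin(np.radians(2.0 * dtheta)) * rc

    term_l = dlp / (kl * sl)
    term_c = dcp / (kc * sc)
    term_h = dhp / (kh * sh)
    return np.sqrt(
        term_l**2 + term_c**2 + term_h**2 + rt * term_c * term_h
    )
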