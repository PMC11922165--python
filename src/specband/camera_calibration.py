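"""Polynomial color correction of camera tristimulus values.

An endoscope camera's XYZ estimates differ from spectrometer-derived XYZ
through nonlinear response, dark current and color crosstalk. The correction
regresses spectrometer XYZ on a 20-term cubic expansion V of camera XYZ:

    C = XYZ_spectrum · pinv(V),      XYZ_corrected = C · V(XYZ_camera)

where V stacks every monomial of (X, Y, Z) up to third order plus a
constant regressor absorbing the signal-independent dark offset.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from .colorimetry import (
    TristimulusXYZ,
    delta_e_2000_array,
    xyz_to_lab_array,
)

__all__ = [
    "EXPANSION_TERMS",
    "COLOR_EXPANSION_TERMS",
    "build_expansion_vector",
    "expansion_matrix",
    "color_expansion_vector",
    "color_expansion_matrix",
    "CorrectionMatrix",
    "CalibrationTarget",
    "CalibrationReport",
    "fit_correction_matrix",
    "apply_correction",
    "apply_correction_array",
    "calibration_report",
]

#: Frozen order of the 20 expansion terms (dark-current slot is the
#: trailing constant).
EXPANSION_TERMS = (
    "X3", "Y3", "Z3", "X2Y", "X2Z", "Y2Z", "XY2", "XZ2", "YZ2", "XYZ",
    "X2", "Y2", "Z2", "XY", "XZ", "YZ", "X", "Y", "Z", "1",
)

#: The 7-term color sub-expansion used by the spectral-reconstruction stage.
COLOR_EXPANSION_TERMS = ("X", "Y", "Z", "XY", "XZ", "YZ", "XYZ")


def _expand(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    one = np.ones_like(x)
    return np.stack(
        [
            x**3, y**3, z**3,
            x**2 * y, x**2 * z, y**2 * z, x * y**2, x * z**2, y * z**2,
            x * y * z,
            x**2, y**2, z**2,
            x * y, x * z, y * z,
            x, y, z,
            one,
        ],
        axis=0,
    )


def build_expansion_vector(xyz: TristimulusXYZ | Sequence[float]) -> np.ndarray:
    """Return the 20 cubic monomials of one XYZ triple, constant term last."""
    arr = xyz.as_array() if isinstance(xyz, TristimulusXYZ) else np.asarray(xyz, float)
    return _expand(arr[0], arr[1], arr[2]).ravel()


def expansion_matrix(xyz: np.ndarray) -> np.ndarray:
    """Stack expansion vectors of an (n, 3) XYZ array into a (20, n) matrix."""
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    return _expand(xyz[:, 0], xyz[:, 1], xyz[:, 2])


def color_expansion_vector(xyz: TristimulusXYZ | Sequence[float]) -> np.ndarray:
    """Return the 7-term color expansion (X, Y, Z, XY, XZ, YZ, XYZ)."""
    arr = xyz.as_array() if isinstance(xyz, TristimulusXYZ) else np.asarray(xyz, float)
    x, y, z = arr
    return np.array([x, y, z, x * y, x * z, y * z, x * y * z])


def color_expansion_matrix(xyz: np.ndarray) -> np.ndarray:
    """Stack color expansions of an (n, 3) XYZ array into a (7, n) matrix."""
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    x, y, z = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    return np.stack([x, y, z, x * y, x * z, y * z, x * y * z], axis=0)


@dataclasses.dataclass
class CorrectionMatrix:
    """A fitted 3×20 correction matrix with its frozen term order."""

    matrix: np.ndarray
    term_order: tuple[str, ...] = EXPANSION_TERMS
    rcond: float = 1e-10

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, len(self.term_order)):
            raise ValueError(f"correction matrix must be 3x{len(self.term_order)}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("correction matrix has non-finite entries")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "matrix": self.matrix.tolist(),
            "term_order": list(self.term_order),
            "rcond": self.rcond,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CorrectionMatrix":
        payload = json.loads(Path(path).read_text())
        return cls(
            np.array(payload["matrix"], dtype=float),
            tuple(payload["term_order"]),
            float(payload.get("rcond", 1e-10)),
        )


@dataclasses.dataclass
class CalibrationTarget:
    """24-patch calibration data: captured sRGB values and measured spectra.

    ``rgb`` is (n_patches, 3) gamma-encoded sRGB in [0, 1]; ``spectra`` is
    (n_patches, 401) reflectance in [0, 1]; ``patch_ids`` names the patches.
    """

    rgb: np.ndarray
    spectra: np.ndarray
    patch_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=float)
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.rgb.ndim != 2 or self.rgb.shape[1] != 3:
            raise ValueError("rgb must be (n_patches, 3)")
        if self.spectra.ndim != 2 or self.spectra.shape[1] != 401:
            raise ValueError("spectra must be (n_patches, 401)")
        if self.rgb.shape[0] != self.spectra.shape[0]:
            raise ValueError("one spectrum per captured patch required")
        if self.patch_ids is None:
            self.patch_ids = tuple(
                f"patch_{i + 1:02d}" for i in range(self.rgb.shape[0])
            )

    @property
    def n_patches(self) -> int:
        return self.rgb.shape[0]


@dataclasses.dataclass(frozen=True)
class CalibrationReport:
    """Per-patch and mean calibration quality (XYZ RMSE and ΔE00)."""

    per_patch_rmse: np.ndarray
    per_patch_delta_e: np.ndarray
    mean_rmse: float
    mean_delta_e: float


def fit_correction_matrix(
    camera_xyz: np.ndarray,
    spectrum_xyz: np.ndarray,
    rcond: float = 1e-10,
    min_patches: int = 20,
) -> CorrectionMatrix:
    """Fit C mapping expanded camera XYZ onto spectrometer XYZ.

    Least-squares optimal in the Frobenius norm via the Moore–Penrose
    pseudoinverse of the (20, n) expansion matrix; rank deficiency (fewer
    patches than ``min_patches``) warns but does not fail.
    """
    camera_xyz = np.atleast_2d(np.asarray(camera_xyz, dtype=float))
    spectrum_xyz = np.atleast_2d(np.asarray(spectrum_xyz, dtype=float))
    if camera_xyz.shape != spectrum_xyz.shape or camera_xyz.shape[1] != 3:
        raise ValueError("camera and spectrum XYZ must both be (n, 3) and aligned")
    n = camera_xyz.shape[0]
    if n < min_patches:
        warnings.warn(
            f"only {n} patches (< {min_patches}); expansion may be rank deficient",
            stacklevel=2,
        )
    v = expansion_matrix(camera_xyz)  # (20, n)
    c = spectrum_xyz.T @ np.linalg.pinv(v, rcond=rcond)
    return CorrectionMatrix(c, rcond=rcond)


def apply_correction(
    xyz: TristimulusXYZ | Sequence[float], c: CorrectionMatrix
) -> TristimulusXYZ:
    """Apply a fitted correction to one camera XYZ triple."""
    v = build_expansion_vector(xyz)
    return TristimulusXYZ.from_array(c.matrix @ v, "corrected")


def apply_correction_array(xyz: np.ndarray, c: CorrectionMatrix) -> np.ndarray:
    """Vectorized correction for an (n, 3) camera-XYZ array → (n, 3)."""
    return (c.matrix @ expansion_matrix(xyz)).T


def calibration_report(
    corrected_xyz: np.ndarray,
    spectrum_xyz: np.ndarray,
    white: Sequence[float] | None = None,
) -> CalibrationReport:
    """Per-patch RMSE over (X, Y, Z) and CIEDE2000 after Lab conversion.

    The reference white for the Lab conversion defaults to D65; calibration
    reports are in-sample, matching the single-target fitting procedure.
    """
    corrected_xyz = np.atleast_2d(np.asarray(corrected_xyz, dtype=float))
    spectrum_xyz = np.atleast_2d(np.asarray(spectrum_xyz, dtype=float))
    if corrected_xyz.shape != spectrum_xyz.shape:
        raise ValueError("misaligned XYZ arrays")
    rmse = np.sqrt(np.mean((corrected_xyz - spectrum_xyz) ** 2, axis=1))
    kwargs = {} if white is None else {"white": white}
    lab_c = xyz_to_lab_array(corrected_xyz, **kwargs)
    lab_s = xyz_to_lab_array(spectrum_xyz, **kwargs)
    de = delta_e_2000_array(lab_c, lab_s)
    return CalibrationReport(
        per_patch_rmse=rmse,
        per_patch_delta_e=de,
        mean_rmse=float(rmse.mean()),
        mean_delta_e=float(de.mean()),
    )
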