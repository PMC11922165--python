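"""Spectrometer-side math and per-pixel spectral reconstruction.

The reconstruction model represents a reflectance spectrum as a low-rank
expansion over a PCA basis fitted to the 24 calibration-patch spectra:

    S(λ) ≈ mean(λ) + Eᵀ · M · V_color(XYZ_corrected)

with E the (k, 401) orthonormal basis, M the (k, 7) regression transform
from the 7-term color expansion onto the basis scores, and XYZ_corrected
the polynomial-corrected camera tristimulus values. Applied pixel-wise,
an RGB endoscope frame becomes an H×W×401 reflectance cube.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from . import datasets
from .camera_calibration import (
    CorrectionMatrix,
    apply_correction_array,
    color_expansion_matrix,
    color_expansion_vector,
)
from .colorimetry import TristimulusXYZ, srgb_to_xyz_array

__all__ = [
    "SpectralBasis",
    "SpectralTransform",
    "SpectralCube",
    "spectrum_to_xyz",
    "spectra_to_xyz_array",
    "fit_spectral_basis",
    "fit_spectral_transform",
    "reconstruct_spectrum",
    "reconstruct_spectra_array",
    "rgb_image_to_cube",
]

_RANK_TOL = 1e-9


def spectrum_to_xyz(
    reflectance: np.ndarray,
    illuminant: np.ndarray,
    cmf: np.ndarray | None = None,
    limits: tuple[float, float] = (380.0, 780.0),
) -> TristimulusXYZ:
    """Integrate a reflectance spectrum into tristimulus values.

    ``X = k ∫ S(λ) R(λ) x̄(λ) dλ`` (trapezoidal on the 1 nm grid), likewise
    Y and Z, with ``k = 100 / ∫ S(λ) ȳ(λ) dλ`` so a perfect reflector has
    Y = 100. ``limits`` restricts the integration range (default: the full
    380–780 nm grid; a 400–700 nm option is available for pipelines that
    integrate over the narrower range).
    """
    xyz = spectra_to_xyz_array(
        np.asarray(reflectance, dtype=float)[None, :], illuminant, cmf, limits
    )[0]
    return TristimulusXYZ.from_array(xyz, "spectrum")


def spectra_to_xyz_array(
    reflectance: np.ndarray,
    illuminant: np.ndarray,
    cmf: np.ndarray | None = None,
    limits: tuple[float, float] = (380.0, 780.0),
) -> np.ndarray:
    """Vectorized spectrum→XYZ for an (n, 401) reflectance array → (n, 3)."""
    if cmf is None:
        cmf = datasets.color_matching_functions()
    reflectance = np.asarray(reflectance, dtype=float)
    illuminant = np.asarray(illuminant, dtype=float)
    wl = datasets.WAVELENGTHS
    if reflectance.shape[-1] != wl.size or illuminant.shape != (wl.size,):
        raise ValueError("spectra must live on the 380–780 nm, 1 nm grid")
    if np.all(illuminant == 0.0):
        raise ValueError("illuminant is identically zero; normalization undefined")
    sel = (wl >= limits[0]) & (wl <= limits[1])
    if not np.any(sel):
        raise ValueError(f"empty integration range {limits}")
    w = wl[sel]
    s = illuminant[sel]
    bars = cmf[sel]
    denom = np.trapezoid(s * bars[:, 1], w)
    if denom <= 0.0:
        raise ValueError("illuminant has no overlap with the luminance curve")
    k = 100.0 / denom
    weighted = s[:, None] * bars  # (m, 3)
    r = reflectance[..., sel]
    xyz = k * np.trapezoid(r[..., None] * weighted, w, axis=-2)
    return xyz


@dataclasses.dataclass
class SpectralBasis:
    """Top-k orthonormal spectral eigenvectors with variance bookkeeping."""

    components: np.ndarray  # (k, 401), rows orthonormal
    variance_ratio: np.ndarray  # (k,), non-increasing
    mean_spectrum: np.ndarray  # (401,); zeros when fitted without centering
    centered: bool = True

    @property
    def k(self) -> int:
        return self.components.shape[0]


#: Alias clarifying intent at call sites; the transform is a plain (k, 7) array
#: wrapped with its shape contract.
@dataclasses.dataclass
class SpectralTransform:
    """(k, 7) regression transform from color-expansion terms to scores."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 7:
            raise ValueError("spectral transform must have shape (k, 7)")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("spectral transform has non-finite entries")

    @property
    def k(self) -> int:
        return self.matrix.shape[0]


def fit_spectral_basis(
    spectra: np.ndarray, k: int = 12, center: bool = True
) -> tuple[SpectralBasis, np.ndarray]:
    """Fit the top-k PCA basis of patch spectra and project their scores.

    ``spectra`` is (n_patches, 401). Returns ``(basis, scores)`` with scores
    shaped (k, n_patches): scoresᵀ = spectraᵀ-projected through pinv of the
    basis (which, for orthonormal rows, is plain projection). ``k`` beyond
    the numerical rank of the (centered) spectra is truncated with a warning.
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2 or spectra.shape[1] != datasets.N_BANDS:
        raise ValueError("spectra must be (n_patches, 401)")
    n = spectra.shape[0]
    if not 1 <= k <= min(n, datasets.N_BANDS):
        raise ValueError(f"k must be in [1, {min(n, datasets.N_BANDS)}]")

    mean = spectra.mean(axis=0) if center else np.zeros(datasets.N_BANDS)
    centered = spectra - mean
    sv = np.linalg.svd(centered, compute_uv=False)
    rank = int(np.sum(sv > _RANK_TOL * max(sv[0], 1.0))) if sv.size else 0
    if k > rank:
        warnings.warn(
            f"requested k={k} exceeds data rank {rank}; truncating", stacklevel=2
        )
        k = rank
    if k == 0:
        basis = SpectralBasis(
            components=np.empty((0, datasets.N_BANDS)),
            variance_ratio=np.empty(0),
            mean_spectrum=mean,
            centered=center,
        )
        return basis, np.empty((0, n))

    if center:
        pca = PCA(n_components=k, svd_solver="full")
        pca.fit(spectra)
        components = pca.components_
        variance_ratio = pca.explained_variance_ratio_
    else:
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        components = vt[:k]
        total = float(np.sum(s**2))
        variance_ratio = (s[:k] ** 2) / total if total > 0 else np.zeros(k)

    basis = SpectralBasis(
        components=components,
        variance_ratio=np.asarray(variance_ratio, dtype=float),
        mean_spectrum=mean,
        centered=center,
    )
    # scoresᵀ = centered-spectra · pinv(E); E has orthonormal rows so
    # pinv(E) = Eᵀ and this is an orthogonal projection.
    scores = (centered @ np.linalg.pinv(components)).T
    return basis, scores


def fit_spectral_transform(
    scores: np.ndarray, corrected_xyz: np.ndarray
) -> SpectralTransform:
    """Regress basis scores on the color expansion: M = scores · pinv(V_color)."""
    scores = np.asarray(scores, dtype=float)
    corrected_xyz = np.atleast_2d(np.asarray(corrected_xyz, dtype=float))
    if scores.ndim != 2 or corrected_xyz.shape != (scores.shape[1], 3):
        raise ValueError(
            "scores must be (k, n) aligned with (n, 3) corrected XYZ"
        )
    vcolor = color_expansion_matrix(corrected_xyz)  # (7, n)
    m = scores @ np.linalg.pinv(vcolor)
    return SpectralTransform(m)


def reconstruct_spectrum(
    xyz: TristimulusXYZ | Sequence[float],
    basis: SpectralBasis,
    transform: SpectralTransform,
    clip: bool = False,
) -> np.ndarray:
    """Reconstruct one 401-sample reflectance spectrum from corrected XYZ."""
    arr = xyz.as_array() if isinstance(xyz, TristimulusXYZ) else np.asarray(xyz, float)
    v = color_expansion_vector(arr)
    s = basis.mean_spectrum + basis.components.T @ (transform.matrix @ v)
    return np.clip(s, 0.0, 1.0) if clip else s


def reconstruct_spectra_array(
    xyz: np.ndarray,
    basis: SpectralBasis,
    transform: SpectralTransform,
    clip: bool = False,
) -> np.ndarray:
    """Vectorized reconstruction: (n, 3) corrected XYZ → (n, 401) spectra."""
    vcolor = color_expansion_matrix(xyz)  # (7, n)
    spectra = basis.mean_spectrum[None, :] + (
        basis.components.T @ (transform.matrix @ vcolor)
    ).T
    return np.clip(spectra, 0.0, 1.0) if clip else spectra


@dataclasses.dataclass
class SpectralCube:
    """H×W×401 reflectance raster on the canonical wavelength grid."""

    data: np.ndarray
    wavelengths: np.ndarray = dataclasses.field(
        default_factory=lambda: datasets.WAVELENGTHS.copy()
    )
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be (H, W, bands)")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError("band count must match the wavelength grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def rgb_image_to_cube(
    image: np.ndarray,
    correction: CorrectionMatrix,
    basis: SpectralBasis,
    transform: SpectralTransform,
    matrix: np.ndarray | None = None,
) -> SpectralCube:
    """Reconstruct a full spectral cube from an 8-bit RGB frame.

    Per pixel: sRGB→camera XYZ→polynomial correction→basis reconstruction.
    Deterministic; the cube metadata records hashes of every calibration
    artifact so cubes can be traced to the rig that produced them.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    h, w, _ = image.shape
    rgb = image.reshape(-1, 3).astype(float)
    if image.dtype == np.uint8:
        rgb = rgb / 255.0
    camera = srgb_to_xyz_array(rgb, matrix=matrix)
    corrected = apply_correction_array(camera, correction)
    spectra = reconstruct_spectra_array(corrected, basis, transform)
    meta = {
        "correction_sha": _digest(correction.matrix),
        "basis_sha": _digest(basis.components),
        "transform_sha": _digest(transform.matrix),
        "clipped": False,
    }
    return SpectralCube(spectra.reshape(h, w, datasets.N_BANDS), metadata=meta)
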