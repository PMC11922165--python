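"""Synthetic fixtures: checker spectra, camera forward models, tissue frames.

Nothing in this package requires measured data; this module generates every
input the pipeline consumes.

* Color-checker reflectances — 18 smooth chromatic patches (squashed
  Gaussian mixtures) plus 6 flat neutral grays, mimicking the structure of
  a 24-patch calibration target.
* A parametric camera forward model — spectral integration to XYZ, a 3×3
  mixing matrix, per-channel polynomial distortion (up to cubic), dark
  offset, additive noise and sRGB gamma encoding.
* Bleeding / non-bleeding tissue frames — mucosa-like baseline reflectance
  with hemoglobin-style absorption bands (a strong Soret-like band near
  415 nm and weaker Q-like bands near 540/577 nm), textured spatially and
  rendered through the camera model, with ground-truth cubes retained.

All randomness flows from explicit seeds; no global random state is used.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from . import datasets
from .colorimetry import SRGB_TO_XYZ_STANDARD, gamma_encode
from .spectral_model import SpectralCube, spectra_to_xyz_array

__all__ = [
    "NEUTRAL_LEVELS",
    "SyntheticCameraModel",
    "ideal_camera",
    "distorted_camera",
    "make_checker_spectra",
    "make_low_rank_checker_spectra",
    "forward_capture",
    "forward_capture_array",
    "TissueSpectrumParams",
    "LabeledFrame",
    "LabeledFrameSet",
    "make_tissue_frames",
]

#: Reflectance levels of the six neutral patches (white → black ramp).
NEUTRAL_LEVELS = (0.90, 0.59, 0.36, 0.19, 0.09, 0.03)


def _gauss(wl: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - mu) / sigma) ** 2)


def make_checker_spectra(seed: int, n_chromatic: int = 18) -> np.ndarray:
    """Generate (n_chromatic + 6, 401) checker reflectances in [0, 1].

    Chromatic patches are Gaussian mixtures passed through a gentle
    logistic squash (keeping them smooth and strictly inside [0, 1]);
    neutral patches are exactly flat at the :data:`NEUTRAL_LEVELS`.
    """
    rng = np.random.default_rng(seed)
    wl = datasets.WAVELENGTHS
    spectra = []
    for _ in range(n_chromatic):
        base = rng.uniform(0.15, 0.6)
        r = np.full(wl.size, base)
        for _ in range(rng.integers(2, 5)):
            amp = rng.uniform(-0.5, 0.6)
            mu = rng.uniform(400.0, 750.0)
            sigma = rng.uniform(30.0, 90.0)
            r = r + amp * _gauss(wl, mu, sigma)
        # smooth squash into (0.02, 0.98): keeps second differences bounded
        spectra.append(0.02 + 0.96 * expit(2.5 * (r - 0.5)))
    for level in NEUTRAL_LEVELS:
        spectra.append(np.full(wl.size, level))
    return np.array(spectra)


def make_low_rank_checker_spectra(
    seed: int, n_patches: int = 24, rank: int = 3
) -> np.ndarray:
    """Generate checker spectra confined to a rank-``rank`` linear family.

    Spectra are ``Σ c_i f_i(λ)`` over ``rank`` fixed smooth modes — a
    positive base mode (coefficient near 1) plus small chromatic modes —
    a through-origin subspace, never clipped. Because a camera observes
    only three tristimulus degrees of freedom, and the color expansion
    carries exact information only in its linear terms, this is the family
    the full pipeline can reconstruct exactly (fit the basis uncentered
    with ``k = rank``): the fixture for closure tests.
    """
    if rank < 1 or rank > 6:
        raise ValueError("rank must be in [1, 6]")
    rng = np.random.default_rng(seed)
    wl = datasets.WAVELENGTHS
    base = 0.45 + 0.10 * np.sin((wl - 380.0) / 400.0 * np.pi)
    centers = np.linspace(440.0, 690.0, max(rank - 1, 1))
    modes = [base] + [_gauss(wl, c, 70.0) for c in centers[: rank - 1]]
    coeffs = np.column_stack(
        [rng.uniform(0.85, 1.15, n_patches)]
        + [rng.uniform(-0.12, 0.12, n_patches) for _ in range(rank - 1)]
    )
    spectra = coeffs @ np.stack(modes)
    if spectra.min() < 0.0 or spectra.max() > 1.0:  # pragma: no cover
        raise AssertionError("mode amplitudes escaped the [0, 1] gamut")
    return spectra


@dataclasses.dataclass
class SyntheticCameraModel:
    """Parametric endoscope-camera forward model.

    ``mixing`` maps XYZ/100 to linear RGB (default: the exact inverse of
    the standard sRGB matrix, i.e. a colorimetrically ideal camera);
    ``poly`` holds per-channel coefficients (c0, c1, c2, c3) applied as
    ``c0 + c1 v + c2 v² + c3 v³``; ``dark`` is a per-channel offset added
    after distortion; ``noise_sigma`` is the standard deviation of
    additive Gaussian noise on the linear signal.
    """

    mixing: np.ndarray = dataclasses.field(
        default_factory=lambda: np.linalg.inv(SRGB_TO_XYZ_STANDARD)
    )
    poly: np.ndarray = dataclasses.field(
        default_factory=lambda: np.tile([0.0, 1.0, 0.0, 0.0], (3, 1))
    )
    dark: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(3))
    noise_sigma: float = 0.0
    apply_gamma: bool = True

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.poly = np.asarray(self.poly, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.mixing.shape != (3, 3) or self.poly.shape != (3, 4):
            raise ValueError("mixing must be 3x3 and poly 3x4")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be ≥ 0")


def ideal_camera() -> SyntheticCameraModel:
    """Distortion-free, noise-free camera (exact sRGB inverse mixing)."""
    return SyntheticCameraModel()


def distorted_camera(
    seed: int, cubic_scale: float = 0.08, dark_scale: float = 0.02,
    noise_sigma: float = 0.0,
) -> SyntheticCameraModel:
    """A mildly misbehaving camera: per-channel cubic distortion + dark offset."""
    rng = np.random.default_rng(seed)
    poly = np.tile([0.0, 1.0, 0.0, 0.0], (3, 1))
    poly[:, 2] = rng.uniform(-cubic_scale, cubic_scale, 3)  # quadratic term
    poly[:, 3] = rng.uniform(-cubic_scale, cubic_scale, 3)  # cubic term
    poly[:, 1] = rng.uniform(0.92, 1.05, 3)
    dark = rng.uniform(0.0, dark_scale, 3)
    return SyntheticCameraModel(poly=poly, dark=dark, noise_sigma=noise_sigma)


def forward_capture_array(
    spectra: np.ndarray,
    camera: SyntheticCameraModel,
    illuminant: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Image (n, 401) reflectance spectra through the camera → (n, 3) sRGB."""
    xyz = spectra_to_xyz_array(np.atleast_2d(spectra), illuminant)
    lin = xyz / 100.0 @ camera.mixing.T
    c = camera.poly
    distorted = (
        c[:, 0]
        + c[:, 1] * lin
        + c[:, 2] * lin**2
        + c[:, 3] * lin**3
    )
    signal = distorted + camera.dark
    if camera.noise_sigma > 0:
        if rng is None:
            raise ValueError("a Generator is required when noise_sigma > 0")
        signal = signal + rng.normal(0.0, camera.noise_sigma, signal.shape)
    signal = np.clip(signal, 0.0, 1.0)
    return gamma_encode(signal) if camera.apply_gamma else signal


def forward_capture(
    spectrum: np.ndarray,
    camera: SyntheticCameraModel,
    illuminant: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Single-spectrum convenience wrapper around :func:`forward_capture_array`."""
    return forward_capture_array(np.asarray(spectrum)[None, :], camera, illuminant, rng)[0]


@dataclasses.dataclass
class TissueSpectrumParams:
    """Class-conditional tissue-spectrum parameters.

    Absorption bands follow hemoglobin's geometry — a strong Soret-like
    band near 415 nm and weaker Q-like bands near 540/577 nm; depths are
    free parameters of the fixture, not claimed physiological values.
    Bleeding tissue gets the deep defaults, non-bleeding the shallow ones.
    """

    band_centers_nm: tuple[float, ...] = (415.0, 540.0, 577.0)
    band_widths_nm: tuple[float, ...] = (28.0, 14.0, 12.0)
    # Q-band depths sit near 1/9 of the Soret depth, mirroring hemoglobin's
    # extinction ratio; they are fixture parameters, not physiological claims
    depths_bleeding: tuple[float, ...] = (0.90, 0.25, 0.20)
    depths_nonbleeding: tuple[float, ...] = (0.25, 0.05, 0.04)
    baseline_low: float = 0.25
    baseline_high: float = 0.70
    baseline_knee_nm: float = 600.0
    baseline_slope_nm: float = 50.0
    texture_amplitude: float = 0.25
    texture_scale_px: float = 4.0
    brightness_jitter: float = 0.25
    # deep-penetrating red light reflects subsurface villous structure, a
    # class-independent nuisance; modelled as per-frame red-shoulder jitter
    scatter_jitter: float = 0.25
    scatter_knee_nm: float = 620.0
    scatter_slope_nm: float = 40.0

    def __post_init__(self) -> None:
        for c in self.band_centers_nm:
            if not 380.0 <= c <= 780.0:
                raise ValueError("band centers must lie within 380–780 nm")
        for d in self.depths_bleeding + self.depths_nonbleeding:
            if not 0.0 <= d <= 1.0:
                raise ValueError("band depths must lie in [0, 1]")

    def baseline(self) -> np.ndarray:
        """Mucosa-like baseline reflectance (dim blue rising into red)."""
        wl = datasets.WAVELENGTHS
        return self.baseline_low + (self.baseline_high - self.baseline_low) * expit(
            (wl - self.baseline_knee_nm) / self.baseline_slope_nm
        )

    def class_mean_spectrum(self, bleeding: bool) -> np.ndarray:
        """Mean reflectance of a class at unit texture and brightness."""
        wl = datasets.WAVELENGTHS
        depths = self.depths_bleeding if bleeding else self.depths_nonbleeding
        absorption = np.ones(wl.size)
        for mu, sig, d in zip(self.band_centers_nm, self.band_widths_nm, depths):
            absorption *= 1.0 - d * _gauss(wl, mu, sig)
        return np.clip(self.baseline() * absorption, 0.0, 1.0)


@dataclasses.dataclass
class LabeledFrame:
    """One synthetic endoscope frame with its ground truth."""

    image: np.ndarray  # (H, W, 3) uint8 sRGB
    label: int  # 1 = bleeding, 0 = non-bleeding
    frame_id: str
    patient_id: str
    cube: SpectralCube | None = None  # ground-truth reflectance


@dataclasses.dataclass
class LabeledFrameSet:
    """An ordered collection of labeled frames with unique IDs."""

    frames: list[LabeledFrame]

    def __post_init__(self) -> None:
        ids = [f.frame_id for f in self.frames]
        if len(set(ids)) != len(ids):
            raise ValueError("frame IDs must be unique")
        for f in self.frames:
            if f.label not in (0, 1):
                raise ValueError("labels must be binary (0/1)")

    def __len__(self) -> int:
        return len(self.frames)

    def labels(self) -> np.ndarray:
        return np.array([f.label for f in self.frames], dtype=int)

    def patients(self) -> list[str]:
        return [f.patient_id for f in self.frames]


def _texture_field(
    rng: np.random.Generator, shape: tuple[int, int], scale_px: float, amplitude: float
) -> np.ndarray:
    field = gaussian_filter(rng.standard_normal(shape), sigma=scale_px)
    sd = field.std()
    if sd > 0:
        field = field / sd
    return 1.0 + amplitude * field


def make_tissue_frames(
    n_bleed: int,
    n_nonbleed: int,
    size: tuple[int, int] = (32, 32),
    params: TissueSpectrumParams | None = None,
    camera: SyntheticCameraModel | None = None,
    illuminant: np.ndarray | None = None,
    seed: int = 0,
    frames_per_patient: int = 4,
    keep_cubes: bool = True,
) -> LabeledFrameSet:
    """Generate labeled bleeding / non-bleeding frames with ground-truth cubes.

    Per pixel the class-conditional absorption depths are modulated by a
    smooth texture field; a per-frame brightness jitter emulates exposure
    variation. Frames are grouped into synthetic patients
    (``frames_per_patient`` consecutive frames each, per class) to support
    leakage-free patient-level splits.
    """
    if n_bleed < 0 or n_nonbleed < 0 or n_bleed + n_nonbleed < 1:
        raise ValueError("need at least one frame")
    h, w = size
    if h < 8 or w < 8:
        raise ValueError("frame size must be at least 8×8")
    params = params or TissueSpectrumParams()
    camera = camera or ideal_camera()
    if illuminant is None:
        illuminant = datasets.illuminant("led")
    rng = np.random.default_rng(seed)
    wl = datasets.WAVELENGTHS
    baseline = params.baseline()
    frames: list[LabeledFrame] = []
    counters = {1: 0, 0: 0}
    for label, count in ((1, n_bleed), (0, n_nonbleed)):
        depths = params.depths_bleeding if label else params.depths_nonbleeding
        gausses = [
            _gauss(wl, mu, sig)
            for mu, sig in zip(params.band_centers_nm, params.band_widths_nm)
        ]
        for i in range(count):
            tex = _texture_field(
                rng, (h, w), params.texture_scale_px, params.texture_amplitude
            )
            brightness = 1.0 + params.brightness_jitter * rng.uniform(-1.0, 1.0)
            scatter = 1.0 + params.scatter_jitter * rng.uniform(-1.0, 1.0) * expit(
                (wl - params.scatter_knee_nm) / params.scatter_slope_nm
            )
            absorption = np.ones((h * w, wl.size))
            for g, d in zip(gausses, depths):
                local_d = np.clip(d * tex.ravel(), 0.0, 1.0)
                absorption *= 1.0 - local_d[:, None] * g[None, :]
            spectra = np.clip(
                brightness * (baseline * scatter)[None, :] * absorption, 0.0, 1.0
            )
            noise_rng = rng if camera.noise_sigma > 0 else None
            rgb = forward_capture_array(spectra, camera, illuminant, noise_rng)
            image = np.round(rgb.reshape(h, w, 3) * 255.0).astype(np.uint8)
            cube = (
                SpectralCube(
                    spectra.reshape(h, w, wl.size),
                    metadata={"synthetic": True, "label": label},
                )
                if keep_cubes
                else None
            )
            idx = counters[label]
            counters[label] += 1
            cls = "bleed" if label else "nonbleed"
            frames.append(
                LabeledFrame(
                    image=image,
                    label=label,
                    frame_id=f"{cls}_{idx:03d}",
                    patient_id=f"pt_{cls}_{idx // frames_per_patient:02d}",
                    cube=cube,
                )
            )
    return LabeledFrameSet(frames)
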