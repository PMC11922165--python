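"""Wavelength-band configurations, cube slicing and band-limited rendering.

Seven band configurations are defined, mirroring narrow-band-imaging
practice for gastrointestinal endoscopy: full white-light passthrough, the
red range (540–780 nm), a green range (470–500 nm), their union, a
blue+green+red composite, the blue range alone (405–415 nm, straddling
hemoglobin's Soret absorption), and the classic NBI pair 405–415 ∪
535–545 nm. Slicing a reconstructed cube to a configuration and rendering
it back to RGB simulates what a narrow-band system would have imaged.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from . import datasets
from .colorimetry import SRGB_TO_XYZ_STANDARD, gamma_encode
from .spectral_model import SpectralCube, spectra_to_xyz_array

__all__ = [
    "BandRange",
    "BandConfiguration",
    "seven_configurations",
    "configuration_by_name",
    "CFG5_RED_EXTENDED",
    "slice_cube",
    "render_band_image",
]


@dataclasses.dataclass(frozen=True)
class BandRange:
    """An inclusive wavelength interval [start_nm, end_nm] on the 1 nm grid."""

    start_nm: int
    end_nm: int

    def __post_init__(self) -> None:
        if not (380 <= self.start_nm <= self.end_nm <= 780):
            raise ValueError(
                f"band range [{self.start_nm}, {self.end_nm}] outside 380–780 nm"
            )

    @property
    def n_samples(self) -> int:
        return self.end_nm - self.start_nm + 1


@dataclasses.dataclass(frozen=True)
class BandConfiguration:
    """A named, sorted, pairwise-disjoint set of band ranges.

    An empty range list means full-spectrum (white-light) passthrough.
    """

    name: str
    ranges: tuple[BandRange, ...] = ()

    def __post_init__(self) -> None:
        ranges = tuple(
            sorted(self.ranges, key=lambda r: r.start_nm)
        )
        for a, b in zip(ranges, ranges[1:]):
            if b.start_nm <= a.end_nm:
                raise ValueError(f"overlapping ranges in configuration {self.name!r}")
        object.__setattr__(self, "ranges", ranges)

    @property
    def is_passthrough(self) -> bool:
        return len(self.ranges) == 0

    def mask(self) -> np.ndarray:
        """Boolean mask over the 401-sample grid (all True for passthrough)."""
        wl = datasets.WAVELENGTHS
        if self.is_passthrough:
            return np.ones(wl.size, dtype=bool)
        m = np.zeros(wl.size, dtype=bool)
        for r in self.ranges:
            m |= (wl >= r.start_nm) & (wl <= r.end_nm)
        return m


def _cfg(name: str, *ranges: tuple[int, int]) -> BandConfiguration:
    return BandConfiguration(name, tuple(BandRange(a, b) for a, b in ranges))


#: The variant of the fifth configuration with the red range extended to
#: 780 nm, as stated once in the originating methods prose.
CFG5_RED_EXTENDED = _cfg("cfg5_alt_540_780", (405, 415), (470, 500), (540, 780))


def seven_configurations() -> list[BandConfiguration]:
    """The seven dataset configurations, white-light first."""
    return [
        _cfg("wli"),
        _cfg("cfg2_540_780", (540, 780)),
        _cfg("cfg3_470_500_540_780", (470, 500), (540, 780)),
        _cfg("cfg4_470_500", (470, 500)),
        _cfg("cfg5_405_415_470_500_540_590", (405, 415), (470, 500), (540, 590)),
        _cfg("cfg6_405_415", (405, 415)),
        _cfg("cfg7_405_415_535_545", (405, 415), (535, 545)),
    ]


def configuration_by_name(name: str) -> BandConfiguration:
    """Look up a configuration by name (the seven defaults plus the cfg5 variant)."""
    table = {c.name: c for c in seven_configurations()}
    table[CFG5_RED_EXTENDED.name] = CFG5_RED_EXTENDED
    # short aliases: cfg1..cfg7
    for i, c in enumerate(seven_configurations(), start=1):
        table[f"cfg{i}"] = c
    try:
        return table[name]
    except KeyError:
        raise KeyError(
            f"unknown configuration {name!r}; choose from {sorted(table)}"
        ) from None


def slice_cube(
    cube: SpectralCube, config: BandConfiguration, mode: str = "mask"
) -> SpectralCube:
    """Restrict a cube to a configuration's wavelengths.

    ``mask`` zeroes out-of-range bands, keeping all 401 planes; ``compact``
    keeps only in-range planes (the wavelength grid shrinks accordingly).
    A passthrough configuration returns an identical copy.
    """
    if mode not in {"mask", "compact"}:
        raise ValueError(f"mode must be 'mask' or 'compact', got {mode!r}")
    if cube.wavelengths.size != datasets.N_BANDS:
        raise ValueError("cube must be on the standard 380–780 nm grid")
    meta = dict(cube.metadata, band_config=config.name, slice_mode=mode)
    if config.is_passthrough:
        return SpectralCube(cube.data.copy(), cube.wavelengths.copy(), meta)
    m = config.mask()
    if mode == "mask":
        data = np.where(m[None, None, :], cube.data, 0.0)
        return SpectralCube(data, cube.wavelengths.copy(), meta)
    return SpectralCube(cube.data[:, :, m], cube.wavelengths[m].copy(), meta)


def render_band_image(
    cube: SpectralCube,
    config: BandConfiguration,
    illuminant: np.ndarray,
    cmf: np.ndarray | None = None,
    display_renormalize: bool = False,
    quantize: bool = True,
) -> np.ndarray:
    """Render a band-restricted cube back to an 8-bit sRGB image.

    Per pixel the spectrum is masked to the configuration, integrated to
    XYZ (the luminance normalization uses the FULL illuminant, so narrow
    configurations render dim and tinted, showing true relative
    brightness), mapped to linear RGB by the inverse of the standard
    sRGB matrix, gamma-encoded, clipped and quantized.
    ``display_renormalize`` instead rescales the whole image so its
    brightest pixel (largest XYZ component) sits at full scale, making
    narrow bands visible without altering within-image contrast. With
    ``quantize=False`` the float RGB image in [0, 1] is returned.
    """
    if cube.wavelengths.size != datasets.N_BANDS:
        raise ValueError("cube must be on the standard 380–780 nm grid")
    if cmf is None:
        cmf = datasets.color_matching_functions()
    h, w, _ = cube.data.shape
    spectra = cube.data.reshape(-1, datasets.N_BANDS)
    m = config.mask()
    masked = np.where(m[None, :], spectra, 0.0)
    xyz = spectra_to_xyz_array(masked, illuminant, cmf)
    if display_renormalize and not config.is_passthrough:
        peak = xyz.max()
        if peak > 0.0:
            xyz = xyz * (100.0 / peak)
    lin = xyz / 100.0 @ np.linalg.inv(SRGB_TO_XYZ_STANDARD).T
    srgb = gamma_encode(np.clip(lin, 0.0, 1.0)).reshape(h, w, 3)
    if not quantize:
        return srgb
    return np.round(srgb * 255.0).astype(np.uint8)
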