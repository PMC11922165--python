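"""Packaged spectral tables: observer color-matching functions and illuminants.

All tables live on the canonical visible-light grid, 380-780 nm sampled at
1 nm (401 samples). The CIE 1931 2-degree observer is packaged as a smooth
multi-lobe Gaussian analytic approximation of the standard curves (accurate
to a few percent pointwise, equal-energy chromaticity within 3e-4 of 1/3),
which keeps the package self-contained without redistributing tabulated data.
"""

from __future__ import annotations

import functools
from importlib import resources

import numpy as np

#: Canonical wavelength grid in nanometres.
WAVELENGTHS = np.arange(380, 781, 1.0)
#: Number of spectral samples on the canonical grid.
N_BANDS = 401


def _read_csv(name: str) -> np.ndarray:
    ref = resources.files("specband.data").joinpath(name)
    with ref.open("rb") as fh:
        return np.loadtxt(fh, delimiter=",", skiprows=1)


@functools.lru_cache(maxsize=None)
def color_matching_functions() -> np.ndarray:
    """Return the 401x3 table of x̄(λ), ȳ(λ), z̄(λ) on the canonical grid."""
    table = _read_csv("cie1931_cmf_2deg.csv")
    if table.shape != (N_BANDS, 4):
        raise ValueError(f"corrupt CMF table: shape {table.shape}")
    return table[:, 1:4].copy()


@functools.lru_cache(maxsize=None)
def illuminant(name: str = "e") -> np.ndarray:
    """Return a 401-sample illuminant spectral power distribution.

    Parameters
    ----------
    name:
        ``"e"`` — equal-energy illuminant (flat spectrum);
        ``"led"`` — a smooth white-LED endoscope-lamp model
        (blue pump near 450 nm plus a broad phosphor lobe near 560 nm).
    """
    key = name.lower()
    if key not in {"e", "led"}:
        raise ValueError(f"unknown illuminant {name!r}; choose 'e' or 'led'")
    table = _read_csv(f"illuminant_{key}.csv")
    if table.shape != (N_BANDS, 2):
        raise ValueError(f"corrupt illuminant table: shape {table.shape}")
    return table[:, 1].copy()
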