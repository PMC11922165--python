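"""Minimal ENVI-style I/O for spectral cubes.

Cubes are stored as a plain-text ``.hdr`` header plus a raw band-sequential
(BSQ) 32-bit float binary, the de-facto interchange format for
hyperspectral rasters. Only the subset of the header needed for
self-describing round trips is written.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .spectral_model import SpectralCube

__all__ = ["write_cube", "read_cube"]


def write_cube(cube: SpectralCube, path: str | Path) -> tuple[Path, Path]:
    """Write ``path.hdr`` + ``path.bsq``; returns both paths."""
    base = Path(path)
    if base.suffix in {".hdr", ".bsq"}:
        base = base.with_suffix("")
    hdr, bsq = base.with_suffix(".hdr"), base.with_suffix(".bsq")
    h, w, bands = cube.data.shape
    wl = ", ".join(f"{v:.1f}" for v in cube.wavelengths)
    hdr.write_text(
        "ENVI\n"
        "description = {spectral reflectance cube}\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    # BSQ: band-major
    np.ascontiguousarray(
        np.moveaxis(cube.data, 2, 0).astype("<f4")
    ).tofile(bsq)
    return hdr, bsq


def _parse_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key = None
    buf = ""
    for line in text.splitlines()[1:]:
        if key is None:
            if "=" not in line:
                continue
            k, v = line.split("=", 1)
            key, buf = k.strip(), v.strip()
        else:
            buf += " " + line.strip()
        if buf.startswith("{") and not buf.endswith("}"):
            continue  # multi-line braced value
        fields[key] = buf.strip("{} ")
        key, buf = None, ""
    return fields


def read_cube(path: str | Path) -> SpectralCube:
    """Read a cube written by :func:`write_cube`."""
    base = Path(path)
    if base.suffix in {".hdr", ".bsq"}:
        base = base.with_suffix("")
    hdr, bsq = base.with_suffix(".hdr"), base.with_suffix(".bsq")
    fields = _parse_header(hdr.read_text())
    if fields.get("interleave", "bsq").lower() != "bsq" or fields.get("data type") != "4":
        raise ValueError("only float32 BSQ cubes are supported")
    h = int(fields["lines"])
    w = int(fields["samples"])
    bands = int(fields["bands"])
    wl = np.array([float(v) for v in fields["wavelength"].split(",")])
    if wl.size != bands:
        raise ValueError("wavelength list does not match band count")
    data = np.fromfile(bsq, dtype="<f4")
    if data.size != h * w * bands:
        raise ValueError("binary size does not match header dimensions")
    cube_data = np.moveaxis(data.reshape(bands, h, w), 0, 2).astype(float)
    return SpectralCube(cube_data, wl, {"source": str(bsq)})
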