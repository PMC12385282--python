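"""Cube and spectrum I/O.

Two cube dialects are supported:

* ``envi`` — an ENVI-style pair: a text header (``.hdr``) carrying
  ``samples``/``lines``/``bands``/``wavelength`` and a raw binary file in
  band-interleaved-by-line (BIL) order, the layout line-scan SWIR
  instruments write natively.  Values round-trip within float32 precision.
* ``array+csv`` — a portable fallback: a NumPy ``.npy`` array next to a
  CSV wavelength list; the round trip is value-exact.

Reference spectra are plain two-column (wavelength nm, reflectance) text
files, one per endmember, as produced from pure analytical standards.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .hypercube import Hypercube

__all__ = [
    "read_cube",
    "write_cube",
    "read_reference_spectrum",
    "write_reference_spectrum",
    "export_map_csv",
]

_ENVI_DTYPE = {4: np.float32, 5: np.float64}
_ENVI_CODE = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


class FormatError(ValueError):
    """File does not conform to the declared dialect."""


def write_cube(cube: Hypercube, path: str | Path, format: str = "envi") -> None:
    """Write a cube as ENVI BIL (``path`` + ``path.hdr``) or array+csv."""
    path = Path(path)
    if format == "envi":
        rows, cols, bands = cube.shape
        # BIL: per line, per band, per sample
        bil = np.ascontiguousarray(
            cube.values.astype(np.float32).transpose(0, 2, 1)
        )
        bil.tofile(path)
        wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
        hdr = (
            "ENVI\n"
            f"samples = {cols}\n"
            f"lines = {rows}\n"
            f"bands = {bands}\n"
            "data type = 4\n"
            "interleave = bil\n"
            "byte order = 0\n"
            "wavelength units = Nanometers\n"
            f"wavelength = {{ {wl} }}\n"
        )
        path.with_suffix(path.suffix + ".hdr").write_text(hdr)
    elif format == "array+csv":
        np.save(path.with_suffix(".npy"), cube.values)
        np.savetxt(path.with_suffix(".wavelengths.csv"), cube.wavelengths,
                   delimiter=",", header="wavelength_nm", comments="")
    else:
        raise ValueError(f"unknown cube format {format!r}")


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    # join brace-delimited multi-line values
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def read_cube(path: str | Path, format: str = "envi") -> Hypercube:
    """Read a cube written by :func:`write_cube`."""
    path = Path(path)
    if format == "envi":
        hdr_path = path.with_suffix(path.suffix + ".hdr")
        if not hdr_path.exists():
            hdr_path = path.with_suffix(".hdr")
        if not hdr_path.exists():
            raise FormatError(f"no ENVI header found for {path}")
        fields = _parse_envi_header(hdr_path.read_text())
        try:
            cols = int(fields["samples"])
            rows = int(fields["lines"])
            bands = int(fields["bands"])
            dtype_code = int(fields.get("data type", "4"))
        except KeyError as exc:
            raise FormatError(f"ENVI header missing key: {exc}") from exc
        interleave = fields.get("interleave", "bil").lower()
        if interleave != "bil":
            raise FormatError(f"only BIL interleave supported, got {interleave!r}")
        m = re.search(r"\{([^}]*)\}", fields.get("wavelength", ""))
        if m is None:
            raise FormatError("ENVI header has no wavelength list")
        wavelengths = np.array([float(x) for x in m.group(1).split(",") if x.strip()])
        if len(wavelengths) != bands:
            raise FormatError(
                f"header declares {bands} bands but {len(wavelengths)} wavelengths"
            )
        dtype = _ENVI_DTYPE.get(dtype_code)
        if dtype is None:
            raise FormatError(f"unsupported ENVI data type {dtype_code}")
        flat = np.fromfile(path, dtype=dtype)
        if flat.size != rows * cols * bands:
            raise FormatError(
                f"binary size {flat.size} != lines*bands*samples {rows * cols * bands}"
            )
        values = flat.reshape(rows, bands, cols).transpose(0, 2, 1)
        return Hypercube(values.astype(float), wavelengths, {"source": str(path)})
    if format == "array+csv":
        values = np.load(path.with_suffix(".npy"))
        wavelengths = np.loadtxt(path.with_suffix(".wavelengths.csv"),
                                 delimiter=",", skiprows=1)
        return Hypercube(values, np.atleast_1d(wavelengths), {"source": str(path)})
    raise ValueError(f"unknown cube format {format!r}")


def write_reference_spectrum(path: str | Path, wavelengths: np.ndarray,
                             reflectance: np.ndarray, name: str = "") -> None:
    """Write a two-column (wavelength nm, reflectance) reference spectrum."""
    header = f"reference spectrum: {name}\nwavelength_nm\treflectance" if name \
        else "wavelength_nm\treflectance"
    np.savetxt(Path(path), np.column_stack([wavelengths, reflectance]),
               delimiter="\t", header=header)


def read_reference_spectrum(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column reference spectrum; returns (wavelengths, reflectance)."""
    arr = np.loadtxt(Path(path))
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise FormatError(f"{path}: expected two columns (wavelength, reflectance)")
    return arr[:, 0], arr[:, 1]


def export_map_csv(path: str | Path, map2d: np.ndarray) -> None:
    """Export a 2-D map (e.g. a refolded abundance image) as CSV."""
    np.savetxt(Path(path), np.asarray(map2d, dtype=float), delimiter=",")
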