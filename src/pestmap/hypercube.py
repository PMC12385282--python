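"""Hyperspectral cube containers and the geometric/radiometric primitives.

A :class:`Hypercube` is the raw object every stage of the residue-analysis
pipeline consumes: a ``rows x cols x bands`` stack of reflectance (or raw
detector counts) with a strictly increasing wavelength axis in nanometres.
The module provides flat-field reflectance calibration against white/dark
references, wavelength cropping, ROI masking, and the unfold/refold pair
that turns a cube into the pixels-by-bands data matrix consumed by the
unmixing stage and maps per-pixel results back to image geometry.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Hypercube",
    "DataMatrix",
    "RoiMask",
    "calibrate_reflectance",
    "crop_wavelengths",
    "unfold",
    "refold",
]

logger = logging.getLogger(__name__)

# reflectance outside [0,1] is physically suspicious past this slack
_REFLECTANCE_SLACK = 0.05


class ShapeError(ValueError):
    """Array dimensions incompatible with the requested operation."""


class DegenerateReferenceError(ValueError):
    """White minus dark reference is zero somewhere; calibration undefined."""


class EmptySelectionError(ValueError):
    """A mask or wavelength window selects no pixels/bands."""


@dataclass
class Hypercube:
    """A 3-D reflectance (or raw-count) stack with its wavelength axis.

    Parameters
    ----------
    values : ndarray, shape (rows, cols, bands)
        Non-negative intensities or reflectance.  Values outside [0, 1]
        after calibration are legal (and kept).
    wavelengths : ndarray, shape (bands,)
        Strictly increasing band centres in nm.
    meta : dict
        Free-form provenance (source path, calibration state, ...).
    """

    values: np.ndarray
    wavelengths: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise ShapeError(f"cube must be 3-D, got shape {self.values.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.values.shape[2]:
            raise ShapeError(
                f"wavelength axis length {self.wavelengths.shape} does not match "
                f"band dimension {self.values.shape[2]}"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]


@dataclass
class DataMatrix:
    """Unfolded cube: one row per pixel, one column per band.

    ``pixel_index`` preserves the (row, col) origin of every matrix row so
    that per-pixel results (abundances, residuals) can be refolded into
    maps with :func:`refold`.
    """

    D: np.ndarray
    pixel_index: list[tuple[int, int]]
    wavelengths: np.ndarray
    spatial_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.D.ndim != 2:
            raise ShapeError("D must be 2-D")
        if self.D.shape[0] != len(self.pixel_index):
            raise ShapeError("pixel_index length must equal number of rows")
        if self.D.shape[1] != len(self.wavelengths):
            raise ShapeError("wavelength axis must match number of columns")
        if len(set(self.pixel_index)) != len(self.pixel_index):
            raise ValueError("pixel_index contains duplicate positions")

    @property
    def n_pixels(self) -> int:
        return self.D.shape[0]


@dataclass
class RoiMask:
    """Boolean region-of-interest over the cube's spatial grid."""

    mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ShapeError("mask must be 2-D")
        if not self.mask.any():
            raise EmptySelectionError("ROI mask selects no pixels")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def calibrate_reflectance(raw: Hypercube, white: Hypercube, dark: Hypercube) -> Hypercube:
    """Flat-field reflectance calibration ``(raw - dark) / (white - dark)``.

    The standard white/dark reference correction for line-scan imaging:
    the dark cube removes detector dark current, the white-reference cube
    (a Teflon standard) normalises out the illumination and per-pixel gain.
    Values outside [0, 1] are kept, not clipped — clipping would bias the
    downstream bilinear unmixing; a warning is logged past a small slack.

    Raises
    ------
    ShapeError
        If the three cubes disagree in shape or wavelength axis.
    DegenerateReferenceError
        If ``white - dark`` is zero at any voxel (names an offending band).
    """
    for name, cube in (("white", white), ("dark", dark)):
        if cube.shape != raw.shape:
            raise ShapeError(f"{name} cube shape {cube.shape} != raw shape {raw.shape}")
        if not np.array_equal(cube.wavelengths, raw.wavelengths):
            raise ShapeError(f"{name} cube wavelength axis differs from raw")

    denom = white.values - dark.values
    zero = denom == 0
    if zero.any():
        band = int(np.argwhere(zero)[0, 2])
        raise DegenerateReferenceError(
            f"white - dark is zero at {int(zero.sum())} voxel(s); first offending "
            f"band index {band} ({raw.wavelengths[band]:.1f} nm)"
        )
    refl = (raw.values - dark.values) / denom
    lo, hi = refl.min(), refl.max()
    if lo < -_REFLECTANCE_SLACK or hi > 1 + _REFLECTANCE_SLACK:
        logger.warning(
            "calibrated reflectance outside [%.2f, %.2f]: range [%.3f, %.3f] kept unclipped",
            -_REFLECTANCE_SLACK, 1 + _REFLECTANCE_SLACK, lo, hi,
        )
    meta = dict(raw.meta)
    meta["calibration"] = "reflectance (raw-dark)/(white-dark)"
    return Hypercube(refl, raw.wavelengths.copy(), meta)


def crop_wavelengths(cube: Hypercube, lo: float, hi: float) -> Hypercube:
    """Keep the bands with ``lo <= wavelength <= hi`` (inclusive both ends).

    Idempotent: cropping an already-cropped cube to the same window is a
    no-op.  Raises :class:`EmptySelectionError` if no band falls inside.
    """
    if lo >= hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    keep = (cube.wavelengths >= lo) & (cube.wavelengths <= hi)
    if not keep.any():
        raise EmptySelectionError(f"no bands in [{lo}, {hi}] nm")
    meta = dict(cube.meta)
    meta["crop_nm"] = (float(lo), float(hi))
    return Hypercube(cube.values[:, :, keep], cube.wavelengths[keep], meta)


def unfold(cube: Hypercube, roi: RoiMask | None = None) -> DataMatrix:
    """Unfold a cube into the pixels-by-bands data matrix D.

    Pixels are taken in row-major scan order; with an ROI, only masked
    pixels are kept (still in scan order).  The returned
    :class:`DataMatrix` records each row's (row, col) origin for refolding.
    """
    rows, cols, _ = cube.shape
    if roi is not None:
        if roi.mask.shape != cube.spatial_shape:
            raise ShapeError(
                f"ROI shape {roi.mask.shape} != cube spatial shape {cube.spatial_shape}"
            )
        sel = np.argwhere(roi.mask)  # argwhere is row-major
    else:
        sel = np.argwhere(np.ones((rows, cols), dtype=bool))
    pixel_index = [(int(r), int(c)) for r, c in sel]
    D = cube.values[sel[:, 0], sel[:, 1], :]
    return DataMatrix(D, pixel_index, cube.wavelengths.copy(), cube.spatial_shape)


def refold(
    vector: np.ndarray,
    pixel_index: list[tuple[int, int]],
    spatial_shape: tuple[int, int],
) -> np.ndarray:
    """Place per-pixel values back on the image grid; unselected pixels are NaN.

    The inverse of :func:`unfold` for a single per-pixel quantity (one
    abundance column, one band, a residual norm).  Invariant under any
    consistent permutation of (vector, pixel_index).
    """
    vector = np.asarray(vector, dtype=float)
    if vector.ndim != 1 or len(vector) != len(pixel_index):
        raise ShapeError(
            f"vector length {vector.shape} != pixel_index length {len(pixel_index)}"
        )
    out = np.full(spatial_shape, np.nan)
    idx = np.asarray(pixel_index)
    out[idx[:, 0], idx[:, 1]] = vector
    return out
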