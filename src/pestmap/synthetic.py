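"""Synthetic SWIR scenes and concentration series for end-to-end testing.

No hyperspectral accessions of pesticide-treated leaves are publicly
deposited, so this module generates data with the statistical structure the
analysis assumes: two-endmember bilinear scenes (leaf + surface residue)
with non-negative Gaussian-peak spectra, spatially heterogeneous
non-negative abundance fields, white/dark reference cubes so the
reflectance calibration is exercised end-to-end, and a four-level
concentration series (0, 0.02, 0.04, 0.06 % active ingredient; 15 leaves
per level, two ROIs per leaf = 120 mean spectra) mirroring the study
design it emulates.

The built-in endmembers place their reflectance/absorption features at the
wavelengths reported for perilla leaf (1123, 1170, 1300, 1450, 1652 nm),
chlorfenapyr residue (1141, 1217, 1394, 1558, 1860, 1940 nm) and
azoxystrobin residue (1217, 1394, 1623, 2030 nm); 1450 and 1940 nm are
modelled as absorption dips (water bands), the rest as reflectance peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .hypercube import Hypercube
from .quantification import SpectralDataset

__all__ = [
    "EndmemberSpec",
    "SceneSpec",
    "SceneData",
    "default_wavelength_grid",
    "LEAF_ENDMEMBER",
    "CHLORFENAPYR_ENDMEMBER",
    "AZOXYSTROBIN_ENDMEMBER",
    "make_endmember",
    "make_scene",
    "make_concentration_series",
    "make_reference_spectra",
]

# instrument grid: 894 nm start, 5.876 nm spectral resolution, 274 bands
GRID_START_NM = 894.0
GRID_STEP_NM = 5.876
GRID_BANDS = 274


def default_wavelength_grid() -> np.ndarray:
    """The 274-band SWIR grid (894-2498 nm at 5.876 nm resolution)."""
    return GRID_START_NM + GRID_STEP_NM * np.arange(GRID_BANDS)


@dataclass
class EndmemberSpec:
    """Gaussian-peak parameterisation of one pure-component spectrum.

    ``peaks`` is a list of ``(center_nm, width_nm, amplitude, sign)`` with
    sign ``+1`` for a reflectance peak and ``-1`` for an absorption dip.
    """

    name: str
    peaks: list[tuple[float, float, float, int]]
    baseline: float = 0.3

    def __post_init__(self) -> None:
        for c, w, a, s in self.peaks:
            if w <= 0:
                raise ValueError(f"{self.name}: peak width must be > 0, got {w}")
            if s not in (+1, -1):
                raise ValueError(f"{self.name}: sign must be +1 or -1")


LEAF_ENDMEMBER = EndmemberSpec(
    name="perilla_leaf",
    peaks=[
        (1123.0, 20.0, 0.18, +1),
        (1170.0, 18.0, 0.12, +1),
        (1300.0, 35.0, 0.15, +1),
        (1450.0, 30.0, 0.25, -1),   # water absorption
        (1652.0, 30.0, 0.14, +1),
    ],
    baseline=0.40,
)

CHLORFENAPYR_ENDMEMBER = EndmemberSpec(
    name="chlorfenapyr",
    peaks=[
        (1141.0, 20.0, 0.12, +1),
        (1217.0, 22.0, 0.16, +1),
        (1394.0, 25.0, 0.20, +1),
        (1558.0, 25.0, 0.13, +1),
        (1860.0, 28.0, 0.11, +1),
        (1940.0, 30.0, 0.22, -1),   # water absorption
    ],
    baseline=0.35,
)

AZOXYSTROBIN_ENDMEMBER = EndmemberSpec(
    name="azoxystrobin",
    peaks=[
        (1217.0, 22.0, 0.15, +1),
        (1394.0, 25.0, 0.18, +1),
        (1623.0, 26.0, 0.16, +1),
        (2030.0, 30.0, 0.14, +1),
    ],
    baseline=0.35,
)


def make_endmember(spec: EndmemberSpec, wavelengths: np.ndarray) -> np.ndarray:
    """Evaluate an endmember spectrum on a wavelength grid (floored at 0)."""
    wl = np.asarray(wavelengths, dtype=float)
    s = np.full_like(wl, spec.baseline)
    for center, width, amp, sign in spec.peaks:
        s = s + sign * amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return np.clip(s, 0.0, None)


@dataclass
class SceneSpec:
    """Recipe for one synthetic two-endmember scene."""

    shape: tuple[int, int] = (64, 64)
    endmembers: list[EndmemberSpec] = field(
        default_factory=lambda: [LEAF_ENDMEMBER, CHLORFENAPYR_ENDMEMBER]
    )
    abundance_pattern: str = "smooth"  # smooth | blobs | halves
    noise_sd: float = 0.01            # fraction of the mean signal
    residue_scale: float = 1.0        # multiplies the non-leaf abundances
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.abundance_pattern not in ("smooth", "blobs", "halves"):
            raise ValueError(f"unknown abundance pattern {self.abundance_pattern!r}")


@dataclass
class SceneData:
    """A generated scene with its ground truth factors."""

    raw: Hypercube
    white: Hypercube
    dark: Hypercube
    truth: Hypercube           # noisy reflectance the calibration recovers
    C: np.ndarray              # (n_pixels, k) true abundances, row-major
    S: np.ndarray              # (k, n_bands) true endmember spectra
    wavelengths: np.ndarray


def _abundance_fields(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    rows, cols = spec.shape
    k = len(spec.endmembers)
    fields = np.empty((k, rows, cols))
    for j in range(k):
        if spec.abundance_pattern == "smooth":
            f = gaussian_filter(rng.standard_normal((rows, cols)),
                                sigma=max(rows, cols) / 12)
            f = f - f.min()
            f = 0.1 + 0.5 * f / max(f.max(), 1e-12)
        elif spec.abundance_pattern == "blobs":
            f = np.zeros((rows, cols))
            yy, xx = np.mgrid[0:rows, 0:cols]
            for _ in range(6):
                cy, cx = rng.uniform(0, rows), rng.uniform(0, cols)
                r = rng.uniform(min(rows, cols) / 10, min(rows, cols) / 4)
                f += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * r**2))
            f = 0.05 + f / max(f.max(), 1e-12)
        else:  # halves
            f = np.full((rows, cols), 0.1)
            if j % 2 == 0:
                f[:, : cols // 2] = 1.0
            else:
                f[:, cols // 2:] = 1.0
        fields[j] = f
    fields[1:] *= spec.residue_scale
    return fields


def make_scene(spec: SceneSpec) -> SceneData:
    """Generate raw/white/dark cubes and their bilinear ground truth.

    The noisy truth reflectance is composed back into detector counts as
    ``raw = truth * (white - dark) + dark`` with a smooth illumination
    field and a low dark level, so ``calibrate_reflectance`` recovers the
    truth to float precision.  Bit-reproducible per seed.
    """
    rng = np.random.default_rng(spec.seed)
    wl = default_wavelength_grid()
    rows, cols = spec.shape
    k = len(spec.endmembers)

    S = np.vstack([make_endmember(e, wl) for e in spec.endmembers])
    fields = _abundance_fields(spec, rng)
    C = fields.reshape(k, rows * cols).T  # row-major pixels

    clean = (C @ S).reshape(rows, cols, len(wl))
    noise = rng.standard_normal(clean.shape) * (spec.noise_sd * clean.mean())
    truth_vals = np.clip(clean + noise, 0.0, None)

    # smooth illumination x lamp spectral envelope; dark: low pedestal
    illum = 900.0 * (0.9 + 0.1 * gaussian_filter(
        rng.standard_normal((rows, cols)), sigma=rows / 6, mode="nearest"))
    lamp = 1.0 + 0.3 * np.sin((wl - wl[0]) / (wl[-1] - wl[0]) * np.pi)
    white_vals = illum[:, :, None] * lamp[None, None, :]
    dark_vals = np.full((rows, cols, len(wl)), 40.0) + \
        4.0 * rng.standard_normal((rows, cols, len(wl)))
    raw_vals = truth_vals * (white_vals - dark_vals) + dark_vals

    meta = {"generator": "pestmap.synthetic.make_scene", "seed": spec.seed}
    return SceneData(
        raw=Hypercube(raw_vals, wl, {**meta, "role": "raw"}),
        white=Hypercube(white_vals, wl, {**meta, "role": "white"}),
        dark=Hypercube(dark_vals, wl, {**meta, "role": "dark"}),
        truth=Hypercube(truth_vals, wl, {**meta, "role": "truth"}),
        C=C,
        S=S,
        wavelengths=wl,
    )


def make_concentration_series(
    levels: tuple[float, ...] = (0.0, 0.02, 0.04, 0.06),
    leaves_per_level: int = 15,
    rois_per_leaf: int = 2,
    response_coef: float = 1.0,
    noise_sd: float = 0.01,
    leaf_effect_sd: float = 0.02,
    seed: int = 0,
    crop_nm: tuple[float, float] | None = (918.0, 2058.0),
    leaf: EndmemberSpec = LEAF_ENDMEMBER,
    residue: EndmemberSpec = CHLORFENAPYR_ENDMEMBER,
) -> SpectralDataset:
    """Generate the concentration-series regression table.

    Each ROI's mean spectrum is ``leaf + response_coef * concentration *
    residue``, scaled by a per-leaf multiplicative random effect
    (``leaf_effect_sd``, so both ROIs of one leaf are correlated) plus
    additive per-band Gaussian noise with SD ``noise_sd`` times the mean
    leaf signal.  Defaults give 4 levels x 15 leaves x 2 ROIs = 120 rows
    on the 918-2058 nm working range.
    """
    if len(levels) < 2:
        raise ValueError("need at least 2 concentration levels")
    if leaves_per_level < 1:
        raise ValueError("leaves_per_level must be >= 1")
    rng = np.random.default_rng(seed)
    wl = default_wavelength_grid()
    leaf_s = make_endmember(leaf, wl)
    res_s = make_endmember(residue, wl)
    base_level = float(leaf_s.mean())

    rows, y, groups = [], [], []
    leaf_id = 0
    for conc in levels:
        for _ in range(leaves_per_level):
            leaf_gain = 1.0 + leaf_effect_sd * rng.standard_normal()
            for _ in range(rois_per_leaf):
                spectrum = leaf_gain * (leaf_s + response_coef * conc * res_s)
                spectrum = spectrum + noise_sd * base_level * \
                    rng.standard_normal(len(wl))
                rows.append(np.clip(spectrum, 0.0, None))
                y.append(conc)
                groups.append(leaf_id)
            leaf_id += 1

    X = np.vstack(rows)
    y = np.array(y)
    groups = np.array(groups)
    if crop_nm is not None:
        keep = (wl >= crop_nm[0]) & (wl <= crop_nm[1])
        X, wl = X[:, keep], wl[keep]
    return SpectralDataset(X=X, y=y, wavelengths=wl, groups=groups)


def make_reference_spectra(endmembers: list[EndmemberSpec],
                           wavelengths: np.ndarray, out_dir) -> list:
    """Write one two-column reference-spectrum file per endmember."""
    from pathlib import Path

    from .io import write_reference_spectrum

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for e in endmembers:
        p = out_dir / f"{e.name}.txt"
        write_reference_spectrum(p, wavelengths, make_endmember(e, wavelengths),
                                 name=e.name)
        paths.append(p)
    return paths
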