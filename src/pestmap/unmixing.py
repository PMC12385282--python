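"""Spectral unmixing: SIMPLISMA initialisation and constrained MCR-ALS.

The observed data matrix (pixels x bands) is modelled bilinearly,

    D = C S' + E,

with C the per-pixel abundance (distribution) matrix, S' the matrix of
pure-component spectra and E the unexplained residual.  Multivariate curve
resolution by alternating least squares (MCR-ALS) refines an initial
estimate of S by alternating two conditionally optimal non-negative
least-squares solves — C given S, then S given C — until the lack of fit

    LOF% = 100 * sqrt(sum(E^2) / sum(D^2))

changes by less than a relative tolerance between sweeps.  Because each
half-step is solved exactly (active-set NNLS, not clip-after-solve) the
LOF trace is non-increasing, which is what makes the relative-change
stopping rule meaningful.

Initial spectra come either from pure reference spectra measured on
analytical standards, or from SIMPLISMA, the pure-variable selection
heuristic: the purity of band j is sigma_j / (mu_j + delta) with a noise
offset delta, and successive pure variables are down-weighted by the
determinant of the correlation-around-origin matrix of the already
selected ones so that each new variable adds independent information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._nnls import nnls_multi_rhs
from .hypercube import DataMatrix, Hypercube, RoiMask, EmptySelectionError

__all__ = [
    "MCRConfig",
    "MCRResult",
    "simplisma_init",
    "fit_mcr_als",
    "lack_of_fit",
    "explained_variance",
    "component_proportions",
    "select_residue_regions",
    "extract_mean_spectra",
    "match_components",
    "export_spectra_csv",
    "render_abundance_map",
]

logger = logging.getLogger(__name__)

# LOF (percent) below this is float-level noise; treated as a perfect fit
_LOF_FLOOR = 1e-9


class ConfigError(ValueError):
    pass


class DegenerateDataError(ValueError):
    pass


@dataclass
class MCRConfig:
    """Settings for the alternating least-squares factorisation.

    ``tol`` is the relative change of LOF between consecutive sweeps, in
    percent; iteration stops when it drops below ``tol`` or after
    ``max_iter`` sweeps.  With ``normalize_spectra`` on, every resolved
    spectrum is rescaled to unit maximum after each sweep (the inverse
    scale is absorbed into C), which fixes the bilinear scale ambiguity.
    """

    n_components: int = 2
    init: str = "simplisma"  # or "reference"
    nonneg_c: bool = True
    nonneg_s: bool = True
    tol: float = 0.1
    max_iter: int = 10000
    normalize_spectra: bool = True
    simplisma_offset: float = 3.0  # noise offset, percent of max column mean
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ConfigError("n_components must be >= 1")
        if self.tol <= 0:
            raise ConfigError("tol must be > 0")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")
        if self.init not in ("simplisma", "reference"):
            raise ConfigError(f"unknown init {self.init!r}")


@dataclass
class MCRResult:
    """Resolved factors and diagnostics of one MCR-ALS fit."""

    C: np.ndarray          # (n_pixels, k) abundances
    S: np.ndarray          # (k, n_bands) spectra
    lof_percent: float
    r2_percent: float
    n_iter: int
    converged: bool
    lof_trace: list[float] = field(default_factory=list)

    def component_maps(self, dm: DataMatrix) -> list[np.ndarray]:
        """Refold each abundance column onto the image grid."""
        from .hypercube import refold

        if dm.spatial_shape is None:
            raise ValueError("DataMatrix carries no spatial shape")
        return [
            refold(self.C[:, j], dm.pixel_index, dm.spatial_shape)
            for j in range(self.C.shape[1])
        ]


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, DataMatrix):
        return data.D
    return np.asarray(data, dtype=float)


def simplisma_init(D, k: int, offset_percent: float = 3.0,
                   return_indices: bool = False):
    """Select k pure variables (bands) and derive initial spectra estimates.

    Returns an initial ``(k, n_bands)`` spectra matrix: the abundance
    proxies at the selected pure bands are regressed against D by NNLS.
    With ``return_indices`` the selected band indices are returned too.
    """
    Dm = _as_matrix(D)
    n_pix, n_bands = Dm.shape
    if k > n_bands:
        raise ConfigError(f"k={k} exceeds number of bands {n_bands}")
    mu = Dm.mean(axis=0)
    sigma = Dm.std(axis=0)
    if np.all(sigma == 0):
        raise DegenerateDataError("all columns of D are constant")
    delta = offset_percent / 100.0 * float(mu.max())
    purity0 = sigma / (mu + delta)

    # correlation-around-origin on length-scaled columns
    lam = np.sqrt(mu**2 + (sigma + delta) ** 2)
    lam[lam == 0] = 1.0
    Z = Dm / (np.sqrt(n_pix) * lam)
    Q = Z.T @ Z

    selected: list[int] = []
    for _ in range(k):
        weights = np.empty(n_bands)
        for j in range(n_bands):
            idx = [j] + selected
            weights[j] = np.linalg.det(Q[np.ix_(idx, idx)])
        purity = weights * purity0
        purity[selected] = -np.inf
        selected.append(int(np.argmax(purity)))

    C0 = Dm[:, selected].copy()
    colmax = C0.max(axis=0)
    colmax[colmax == 0] = 1.0
    C0 /= colmax
    S0 = nnls_multi_rhs(C0, Dm)  # (k, n_bands)
    rowmax = S0.max(axis=1, keepdims=True)
    rowmax[rowmax == 0] = 1.0
    S0 = S0 / rowmax
    if return_indices:
        return S0, selected
    return S0


def lack_of_fit(D, model) -> float:
    """Percent lack of fit: ``100 * sqrt(sum(E^2) / sum(D^2))``."""
    Dm = _as_matrix(D)
    M = np.asarray(model, dtype=float)
    if Dm.shape != M.shape:
        raise ValueError(f"shape mismatch {Dm.shape} vs {M.shape}")
    ss_d = float(np.sum(Dm**2))
    if ss_d == 0:
        raise DegenerateDataError("sum of squares of D is zero; LOF undefined")
    ss_e = float(np.sum((Dm - M) ** 2))
    return 100.0 * np.sqrt(ss_e / ss_d)


def explained_variance(D, model) -> float:
    """Percent variance explained: ``100 * (sum(D^2) - sum(E^2)) / sum(D^2)``."""
    Dm = _as_matrix(D)
    M = np.asarray(model, dtype=float)
    if Dm.shape != M.shape:
        raise ValueError(f"shape mismatch {Dm.shape} vs {M.shape}")
    ss_d = float(np.sum(Dm**2))
    if ss_d == 0:
        raise DegenerateDataError("sum of squares of D is zero")
    ss_e = float(np.sum((Dm - M) ** 2))
    return 100.0 * (ss_d - ss_e) / ss_d


def fit_mcr_als(
    D,
    config: MCRConfig | None = None,
    reference_spectra: np.ndarray | None = None,
) -> MCRResult:
    """Run constrained MCR-ALS on the unfolded data matrix.

    Parameters
    ----------
    D : DataMatrix or ndarray (n_pixels, n_bands)
    config : MCRConfig
    reference_spectra : ndarray (k, n_bands), required when
        ``config.init == "reference"``; must live on D's wavelength grid.
    """
    config = config or MCRConfig()
    Dm = _as_matrix(D)
    if not np.all(np.isfinite(Dm)):
        raise DegenerateDataError("D contains non-finite values")
    k = config.n_components

    if config.init == "reference":
        if reference_spectra is None:
            raise ConfigError("reference init requires reference_spectra")
        S = np.asarray(reference_spectra, dtype=float).copy()
        if S.shape != (k, Dm.shape[1]):
            raise ConfigError(
                f"reference spectra shape {S.shape} != ({k}, {Dm.shape[1]})"
            )
    else:
        S = simplisma_init(Dm, k, config.simplisma_offset)

    ridge = 0.0
    lof_trace: list[float] = []
    converged = False
    n_iter = 0
    C = np.zeros((Dm.shape[0], k))
    for sweep in range(1, config.max_iter + 1):
        n_iter = sweep
        # C-update: rows of C solve min ||S' c - d|| (shared design S')
        C = _half_step(S.T, Dm.T, nonneg=config.nonneg_c, ridge=ridge).T
        if np.any(C.sum(axis=0) == 0):
            ridge = 1e-10 * float(np.trace(Dm @ Dm.T)) / max(Dm.shape[0], 1)
            logger.warning("rank-deficient abundance update; enabling ridge %.3g", ridge)
        # S-update: columns of S solve min ||C s - d_band||
        S = _half_step(C, Dm, nonneg=config.nonneg_s, ridge=ridge)
        if config.normalize_spectra:
            rowmax = S.max(axis=1, keepdims=True)
            scale = np.where(rowmax > 0, rowmax, 1.0)
            S = S / scale
            C = C * scale.T
        lof = lack_of_fit(Dm, C @ S)
        lof_trace.append(lof)
        if sweep > 1:
            prev = lof_trace[-2]
            if prev <= _LOF_FLOOR or abs(prev - lof) / prev * 100.0 < config.tol:
                converged = True
                break
        elif lof <= _LOF_FLOOR:
            converged = True
            break

    lof = lof_trace[-1]
    r2 = 100.0 * (1.0 - (lof / 100.0) ** 2)
    return MCRResult(C=C, S=S, lof_percent=lof, r2_percent=r2,
                     n_iter=n_iter, converged=converged, lof_trace=lof_trace)


def _half_step(A: np.ndarray, B: np.ndarray, nonneg: bool, ridge: float) -> np.ndarray:
    """One conditionally optimal solve ``min_X ||A X - B||`` (X >= 0 if nonneg)."""
    if nonneg:
        return nnls_multi_rhs(A, B, ridge=ridge)
    if ridge:
        k = A.shape[1]
        AtA = A.T @ A + ridge * np.eye(k)
        return np.linalg.solve(AtA, A.T @ B)
    return np.linalg.lstsq(A, B, rcond=None)[0]


def component_proportions(C: np.ndarray) -> np.ndarray:
    """Percent of total resolved abundance carried by each component."""
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("C must be non-negative")
    total = C.sum()
    if total == 0:
        raise DegenerateDataError("all-zero abundance matrix")
    return 100.0 * C.sum(axis=0) / total


def select_residue_regions(abundance_map: np.ndarray, top_fraction: float = 0.2,
                           label: str = "residue") -> RoiMask:
    """Mask the ceil(top_fraction * n) pixels with the largest abundance.

    NaN pixels (outside the unfolded selection) are never chosen.  Ties are
    broken by row-major scan order, so the mask is deterministic.
    """
    if not 0 < top_fraction <= 1:
        raise ConfigError(f"top_fraction must be in (0, 1], got {top_fraction}")
    amap = np.asarray(abundance_map, dtype=float)
    flat = amap.ravel()
    finite = np.isfinite(flat)
    if not finite.any():
        raise DegenerateDataError("abundance map has no finite pixels")
    n = int(finite.sum())
    n_keep = int(np.ceil(top_fraction * n))
    vals = np.where(finite, flat, -np.inf)
    order = np.argsort(-vals, kind="stable")  # stable: ties fall in scan order
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:n_keep]] = True
    return RoiMask(mask.reshape(amap.shape), label=label)


def extract_mean_spectra(source, masks: list[RoiMask]) -> np.ndarray:
    """Per-band arithmetic mean spectrum over each ROI mask.

    ``source`` may be a :class:`Hypercube` or a :class:`DataMatrix` whose
    pixel index covers every masked pixel.  Returns (len(masks), n_bands).
    """
    if not masks:
        raise EmptySelectionError("no masks given")
    if isinstance(source, Hypercube):
        out = np.empty((len(masks), source.n_bands))
        for i, roi in enumerate(masks):
            if roi.mask.shape != source.spatial_shape:
                raise ValueError("mask shape does not match cube")
            out[i] = source.values[roi.mask].mean(axis=0)
        return out
    if isinstance(source, DataMatrix):
        pos = {p: i for i, p in enumerate(source.pixel_index)}
        out = np.empty((len(masks), source.D.shape[1]))
        for i, roi in enumerate(masks):
            idx = [pos[(int(r), int(c))] for r, c in np.argwhere(roi.mask)]
            if not idx:
                raise EmptySelectionError(f"mask {roi.label!r} selects no pixels")
            out[i] = source.D[idx].mean(axis=0)
        return out
    raise TypeError("source must be a Hypercube or DataMatrix")


def match_components(S: np.ndarray, references: np.ndarray) -> np.ndarray:
    """Assign each reference spectrum its best-correlated resolved component.

    Greedy maximal Pearson correlation; returns an index array ``perm``
    such that ``S[perm[i]]`` corresponds to ``references[i]``.
    """
    S = np.asarray(S, dtype=float)
    refs = np.asarray(references, dtype=float)
    corr = np.corrcoef(np.vstack([refs, S]))[: len(refs), len(refs):]
    perm = np.full(len(refs), -1)
    used: set[int] = set()
    for i in np.argsort(-np.nanmax(corr, axis=1)):
        order = np.argsort(-corr[i])
        for j in order:
            if int(j) not in used:
                perm[i] = int(j)
                used.add(int(j))
                break
    return perm


def export_spectra_csv(path, wavelengths: np.ndarray, S: np.ndarray,
                       names: list[str] | None = None) -> None:
    """Write resolved spectra as CSV: wavelength column + one column per component."""
    import pandas as pd

    k = S.shape[0]
    names = names or [f"component_{i + 1}" for i in range(k)]
    df = pd.DataFrame({"wavelength_nm": wavelengths})
    for name, row in zip(names, S):
        df[name] = row
    df.to_csv(path, index=False)


def render_abundance_map(path, map2d: np.ndarray, title: str = "") -> None:
    """Render an abundance map as PNG; background (NaN) pixels drawn as 0."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = np.nan_to_num(np.asarray(map2d, dtype=float), nan=0.0)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(img, cmap="viridis")
    fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
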