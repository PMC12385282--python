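"""End-to-end workflows: simulate, detect, quantify.

Each workflow takes a :class:`RunConfig`, runs the corresponding chain of
library calls, and writes every artifact (resolved spectra, abundance
maps, metric tables, the config itself and its hash) into the output
directory, so a run is reproducible from its report alone.  All
randomness flows from the single root seed: stage-level seeds are spawned
deterministically as ``root_seed * 100 + stage_offset``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as hio
from .hypercube import Hypercube, calibrate_reflectance, crop_wavelengths, unfold
from .quantification import (
    SpectralDataset,
    double_cross_validation,
    gpr_factory,
    label_summary,
    plsr_factory,
    relative_improvement,
    split_calibration_test,
    svr_factory,
)
from .synthetic import (
    CHLORFENAPYR_ENDMEMBER,
    LEAF_ENDMEMBER,
    SceneSpec,
    default_wavelength_grid,
    make_concentration_series,
    make_endmember,
    make_reference_spectra,
    make_scene,
)
from .unmixing import (
    MCRConfig,
    component_proportions,
    extract_mean_spectra,
    export_spectra_csv,
    fit_mcr_als,
    render_abundance_map,
    select_residue_regions,
)

__all__ = ["RunConfig", "run_detection", "run_quantification", "run_simulate"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration shared by the pipeline workflows.

    ``workflow`` is one of ``simulate``, ``detect``, ``quantify``.  Paths
    may be None for workflows that generate their own inputs.
    """

    workflow: str = "detect"
    out_dir: str = "pestmap_out"
    seed: int = 0
    # detect inputs: either a calibrated cube, or raw+white+dark
    cube_path: str | None = None
    raw_path: str | None = None
    white_path: str | None = None
    dark_path: str | None = None
    cube_format: str = "envi"
    reference_paths: list[str] = field(default_factory=list)
    crop_nm: tuple[float, float] | None = (918.0, 2058.0)
    # unmixing settings
    n_components: int = 2
    init: str = "simplisma"
    tol: float = 0.1
    max_iter: int = 10000
    top_fraction: float = 0.2
    # quantification settings
    series_path: str | None = None
    cal_fraction: float = 0.70
    inner_folds: int = 5
    n_repeats: int = 1
    kernels: tuple[str, ...] = ("se", "matern32", "matern52", "rq")
    # simulate settings
    scene_shape: tuple[int, int] = (64, 64)
    noise_sd: float = 0.01
    leaves_per_level: int = 15

    def config_hash(self) -> str:
        # out_dir is where results land, not what they are: reruns into a
        # different directory must hash identically
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _prepare_out(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_config.json", "w") as fh:
        json.dump({**asdict(config), "config_hash": config.config_hash()},
                  fh, indent=2, default=str)
    return out


def _stage(name: str):
    """Decorator tagging stage failures with the stage name."""
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"[stage: {name}] {exc}") from exc
        return wrapped
    return deco


def _load_calibrated_cube(config: RunConfig) -> Hypercube:
    if config.cube_path:
        return hio.read_cube(config.cube_path, config.cube_format)
    if not (config.raw_path and config.white_path and config.dark_path):
        raise ValueError("need cube_path or raw/white/dark paths")
    raw = hio.read_cube(config.raw_path, config.cube_format)
    white = hio.read_cube(config.white_path, config.cube_format)
    dark = hio.read_cube(config.dark_path, config.cube_format)
    return calibrate_reflectance(raw, white, dark)


def run_detection(config: RunConfig, cube: Hypercube | None = None,
                  reference_spectra: np.ndarray | None = None) -> dict:
    """Detection workflow: calibrate, crop, unfold, unmix, map, report.

    ``cube`` (already calibrated) and ``reference_spectra`` may be passed
    directly to skip file I/O; otherwise they are read per the config.
    Returns the report dict that is also written to ``detection_report.json``.
    """
    out = _prepare_out(config)
    if cube is None:
        cube = _stage("load")(_load_calibrated_cube)(config)
    if config.crop_nm is not None:
        cube = _stage("crop")(crop_wavelengths)(cube, *config.crop_nm)
    dm = _stage("unfold")(unfold)(cube)

    refs = reference_spectra
    if refs is None and config.reference_paths:
        loaded = []
        for p in config.reference_paths:
            wl, refl = hio.read_reference_spectrum(p)
            if len(wl) != len(cube.wavelengths) or not np.allclose(wl, cube.wavelengths):
                refl = np.interp(cube.wavelengths, wl, refl)
            loaded.append(refl)
        refs = np.vstack(loaded)

    mcr_cfg = MCRConfig(
        n_components=config.n_components,
        init="reference" if refs is not None else config.init,
        tol=config.tol, max_iter=config.max_iter, seed=config.seed,
    )
    result = _stage("mcr-als")(fit_mcr_als)(dm, mcr_cfg, reference_spectra=refs)

    proportions = component_proportions(result.C)
    maps = result.component_maps(dm)
    for j, amap in enumerate(maps):
        hio.export_map_csv(out / f"abundance_component_{j + 1}.csv", amap)
        render_abundance_map(out / f"abundance_component_{j + 1}.png", amap,
                             title=f"component {j + 1}")
    export_spectra_csv(out / "resolved_spectra.csv", cube.wavelengths, result.S)

    report = {
        "workflow": "detect",
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_components": config.n_components,
        "init": mcr_cfg.init,
        "lof_percent": result.lof_percent,
        "r2_percent": result.r2_percent,
        "n_iter": result.n_iter,
        "converged": result.converged,
        "proportions_percent": [float(p) for p in proportions],
    }
    with open(out / "detection_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def run_quantification(config: RunConfig,
                       dataset: SpectralDataset | None = None) -> dict:
    """Quantification workflow: regression table -> nested CV -> LOD.

    The dataset is loaded from ``series_path`` (CSV) or generated
    synthetically when neither is given.  Fits GPR with kernel selection
    plus PLSR and SVR baselines under the same double cross-validation
    protocol, then reports the relative improvement of GPR over the best
    baseline and the ICH detection limit.
    """
    out = _prepare_out(config)
    if dataset is None:
        if config.series_path:
            dataset = SpectralDataset.from_csv(config.series_path)
        else:
            dataset = make_concentration_series(
                leaves_per_level=config.leaves_per_level,
                noise_sd=config.noise_sd, seed=config.seed * 100 + 1)

    cal, test = split_calibration_test(dataset, config.cal_fraction,
                                       seed=config.seed)
    split_stats = {"full": label_summary(dataset), "calibration": label_summary(cal),
                   "test": label_summary(test)}

    reports = {}
    factories = {
        "GPR": gpr_factory(kernel_menu=tuple(config.kernels)),
        "PLSR": plsr_factory(),
        "SVR": svr_factory(),
    }
    for name, factory in factories.items():
        reports[name] = _stage(name)(double_cross_validation)(
            dataset, factory, config.cal_fraction, config.inner_folds,
            config.n_repeats, config.seed)

    best_baseline_rmse = min(reports["PLSR"].rmse_val, reports["SVR"].rmse_val)
    ref_r2 = max(reports["PLSR"].r2_val, reports["SVR"].r2_val)
    improvements = {
        "rmsev_reduction_percent": relative_improvement(
            best_baseline_rmse, reports["GPR"].rmse_val, "lower-better"),
        "r2v_gain_percent": relative_improvement(
            ref_r2, reports["GPR"].r2_val, "higher-better"),
    }

    report = {
        "workflow": "quantify",
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "split": split_stats,
        "models": {name: r.as_dict() for name, r in reports.items()},
        "improvement_vs_best_baseline": improvements,
        "lod_percent": reports["GPR"].lod_percent,
    }
    with open(out / "quantification_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def run_simulate(config: RunConfig) -> dict:
    """Generate one scene (raw/white/dark cubes) and one concentration series."""
    out = _prepare_out(config)
    scene = make_scene(SceneSpec(shape=config.scene_shape,
                                 noise_sd=config.noise_sd,
                                 seed=config.seed * 100 + 1))
    for role in ("raw", "white", "dark"):
        hio.write_cube(getattr(scene, role), out / f"scene_{role}.bil", "envi")
    ref_paths = make_reference_spectra(
        [LEAF_ENDMEMBER, CHLORFENAPYR_ENDMEMBER],
        default_wavelength_grid(), out / "references")

    series = make_concentration_series(
        leaves_per_level=config.leaves_per_level,
        noise_sd=config.noise_sd, seed=config.seed * 100 + 2)
    series.to_csv(out / "concentration_series.csv")

    manifest = {
        "workflow": "simulate",
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "scene": {"shape": list(config.scene_shape), "noise_sd": config.noise_sd,
                  "seed": config.seed * 100 + 1,
                  "files": [f"scene_{r}.bil" for r in ("raw", "white", "dark")]},
        "references": [str(p.name) for p in ref_paths],
        "series": {"file": "concentration_series.csv", "n_rows": len(series),
                   "seed": config.seed * 100 + 2},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
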