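"""Concentration regression from extracted residue spectra.

The regression table is a :class:`SpectralDataset`: one mean reflectance
spectrum per leaf ROI on the 918-2058 nm working range, labelled with the
applied active-ingredient concentration in percent.  Model evaluation
follows a double (nested) cross-validation protocol: an outer group-aware
stratified 70/30 split holds out a test set that never touches model
development, and a 5-fold inner cross-validation on the calibration set
selects the Gaussian-process kernel family (squared exponential, Matern
3/2, Matern 5/2, rational quadratic), the PLSR latent-variable count, or
the SVR hyperparameter grid point.  GP hyperparameters within a family are
set by maximising the marginal likelihood with multiple restarts.

The detection limit follows the ICH 3.3*sigma/slope convention applied to
the calibration predicted-vs-reference regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    RBF,
    ConstantKernel,
    Matern,
    RationalQuadratic,
    WhiteKernel,
)
from sklearn.model_selection import GroupKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = [
    "SpectralDataset",
    "RegressionReport",
    "split_calibration_test",
    "label_summary",
    "gpr_fit",
    "gpr_predict",
    "plsr_fit",
    "svr_fit",
    "double_cross_validation",
    "compute_metrics",
    "limit_of_detection",
    "lod_from_calibration",
    "relative_improvement",
    "KERNEL_FAMILIES",
]


class ConfigError(ValueError):
    pass


@dataclass
class SpectralDataset:
    """n mean spectra x d wavelengths with concentration labels in percent.

    ``groups`` ties the rows extracted from the same leaf together so that
    splits can keep a leaf's ROIs on one side of the fence.
    """

    X: np.ndarray
    y: np.ndarray
    wavelengths: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.groups = np.asarray(self.groups)
        n, d = self.X.shape
        if len(self.y) != n or len(self.groups) != n:
            raise ValueError("y and groups must have one entry per row of X")
        if len(self.wavelengths) != d:
            raise ValueError("wavelengths must match the number of columns")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("dataset contains non-finite values")

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, idx: np.ndarray) -> "SpectralDataset":
        return SpectralDataset(self.X[idx], self.y[idx],
                               self.wavelengths, self.groups[idx])

    def to_csv(self, path) -> None:
        """CSV layout: group id, concentration %, then one column per band."""
        df = pd.DataFrame(self.X, columns=[f"{w:.3f}" for w in self.wavelengths])
        df.insert(0, "concentration_pct", self.y)
        df.insert(0, "group", self.groups)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectralDataset":
        df = pd.read_csv(path)
        wavelengths = np.array([float(c) for c in df.columns[2:]])
        return cls(df.iloc[:, 2:].to_numpy(float), df["concentration_pct"].to_numpy(float),
                   wavelengths, df["group"].to_numpy())


@dataclass
class RegressionReport:
    """Calibration/validation metrics of one fitted model."""

    model_name: str
    r2_cal: float
    rmse_cal: float
    r2_val: float
    rmse_val: float
    predictions_cal: np.ndarray
    predictions_val: np.ndarray
    chosen_kernel: str | None = None
    chosen_params: dict = field(default_factory=dict)
    lod_percent: float | None = None

    def as_dict(self) -> dict:
        return {
            "model": self.model_name,
            "r2_cal": self.r2_cal,
            "rmse_cal": self.rmse_cal,
            "r2_val": self.r2_val,
            "rmse_val": self.rmse_val,
            "chosen_kernel": self.chosen_kernel,
            "chosen_params": {k: (v if isinstance(v, (int, float, str)) else str(v))
                              for k, v in self.chosen_params.items()},
            "lod_percent": self.lod_percent,
        }


def label_summary(ds: SpectralDataset) -> dict:
    """Mean/min/max/SD of the concentration labels (the split-balance report)."""
    return {
        "n": len(ds),
        "mean": float(np.mean(ds.y)),
        "min": float(np.min(ds.y)),
        "max": float(np.max(ds.y)),
        "sd": float(np.std(ds.y, ddof=1)) if len(ds) > 1 else 0.0,
    }


def _symmetric_priority(n_levels: int) -> list[int]:
    # outermost levels first, pairing low with high, so that allocating
    # leftover calibration slots keeps the label mean balanced
    order, lo, hi = [], 0, n_levels - 1
    while lo <= hi:
        order.append(lo)
        if hi != lo:
            order.append(hi)
        lo, hi = lo + 1, hi - 1
    return order


def split_calibration_test(
    ds: SpectralDataset, cal_fraction: float = 0.70, seed: int = 0
) -> tuple[SpectralDataset, SpectralDataset]:
    """Group-aware stratified random split into calibration and test sets.

    Whole leaves (groups), not rows, are allocated within each
    concentration level, so both ROIs of a leaf land on the same side.
    Per-level calibration counts follow a largest-remainder rule that
    hands leftover slots to the outer levels pairwise (lowest with
    highest), keeping the label mean of both subsets at the full-set mean
    for a balanced design.
    """
    if not 0 < cal_fraction < 1:
        raise ConfigError(f"cal_fraction must be in (0,1), got {cal_fraction}")
    rng = np.random.default_rng(seed)
    levels = np.unique(ds.y)
    level_groups = []
    for lev in levels:
        g = np.unique(ds.groups[ds.y == lev])
        if len(g) < 2:
            raise ConfigError(f"concentration level {lev} has fewer than 2 groups")
        level_groups.append(g)

    total_groups = sum(len(g) for g in level_groups)
    total_cal = int(round(cal_fraction * total_groups))
    base = [int(np.floor(cal_fraction * len(g))) for g in level_groups]
    leftover = total_cal - sum(base)
    remainders = [cal_fraction * len(g) - b for g, b in zip(level_groups, base)]
    priority = sorted(
        range(len(levels)),
        key=lambda i: (-remainders[i], _symmetric_priority(len(levels)).index(i)),
    )
    n_cal = list(base)
    for i in priority[:leftover]:
        n_cal[i] += 1

    cal_groups: set = set()
    for g, n in zip(level_groups, n_cal):
        perm = rng.permutation(len(g))
        cal_groups.update(g[perm[:n]].tolist())

    in_cal = np.array([grp in cal_groups for grp in ds.groups])
    return ds.subset(np.where(in_cal)[0]), ds.subset(np.where(~in_cal)[0])


# ---------------------------------------------------------------------------
# models

KERNEL_FAMILIES = ("se", "matern32", "matern52", "rq")


def _make_kernel(family: str):
    bounds = (1e-3, 1e4)
    const = ConstantKernel(1.0, bounds)
    if family == "se":
        core = RBF(length_scale=10.0, length_scale_bounds=bounds)
    elif family == "matern32":
        core = Matern(length_scale=10.0, length_scale_bounds=bounds, nu=1.5)
    elif family == "matern52":
        core = Matern(length_scale=10.0, length_scale_bounds=bounds, nu=2.5)
    elif family == "rq":
        core = RationalQuadratic(length_scale=10.0, alpha=1.0,
                                 length_scale_bounds=bounds,
                                 alpha_bounds=(1e-3, 1e3))
    else:
        raise ConfigError(f"unknown kernel family {family!r}")
    noise = WhiteKernel(noise_level=1e-4, noise_level_bounds=(1e-12, 1e2))
    return const * core + noise


@dataclass
class FittedModel:
    """A fitted regressor with enough context to predict and report."""

    name: str
    pipeline: Pipeline
    chosen_kernel: str | None = None
    chosen_params: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.pipeline.predict(X)).ravel()

    def predict_with_std(self, X: np.ndarray):
        scaler = self.pipeline.named_steps.get("scale")
        reg = self.pipeline.named_steps["model"]
        if not isinstance(reg, GaussianProcessRegressor):
            raise TypeError("predictive variance only available for GPR")
        Xt = scaler.transform(X) if scaler is not None else X
        mean, std = reg.predict(Xt, return_std=True)
        return np.asarray(mean).ravel(), np.asarray(std).ravel()


def _inner_folds_indices(cal: SpectralDataset, inner_folds: int):
    n_groups = len(np.unique(cal.groups))
    if n_groups < inner_folds:
        raise ConfigError(
            f"need at least {inner_folds} calibration groups, got {n_groups}"
        )
    gkf = GroupKFold(n_splits=inner_folds)
    return list(gkf.split(cal.X, cal.y, groups=cal.groups))


def _cv_rmse(builder, cal: SpectralDataset, folds) -> float:
    errs = []
    for tr, va in folds:
        model = builder()
        model.fit(cal.X[tr], cal.y[tr])
        pred = np.asarray(model.predict(cal.X[va])).ravel()
        errs.append(np.sqrt(np.mean((pred - cal.y[va]) ** 2)))
    return float(np.mean(errs))


def gpr_fit(
    cal: SpectralDataset,
    kernel_menu: tuple[str, ...] = KERNEL_FAMILIES,
    inner_folds: int = 5,
    seed: int = 0,
    n_restarts: int = 5,
    standardize: bool = True,
) -> FittedModel:
    """Fit a GP regressor, selecting the kernel family by inner-fold CV.

    Within a family, hyperparameters (length scale, signal variance, noise
    variance, and alpha for the rational quadratic) maximise the marginal
    log-likelihood with ``n_restarts`` random restarts.  The family with
    the lowest mean RMSE over the group-aware inner folds wins; ties go to
    the simpler family in menu order.  The concentration target is centred
    and scaled internally (zero-mean GP prior plus fitted constant shift).
    """
    folds = _inner_folds_indices(cal, inner_folds)

    def builder(family: str, restarts: int):
        def build():
            steps = []
            if standardize:
                steps.append(("scale", StandardScaler()))
            steps.append(("model", GaussianProcessRegressor(
                kernel=_make_kernel(family),
                normalize_y=True,
                n_restarts_optimizer=restarts,
                random_state=seed,
                alpha=1e-10,
            )))
            return Pipeline(steps)
        return build

    scores = {}
    for family in kernel_menu:
        # restarts trimmed inside the folds; the winning family is refit
        # on the full calibration set with the full restart budget
        scores[family] = _cv_rmse(builder(family, max(1, n_restarts // 2)),
                                  cal, folds)
    best = min(kernel_menu, key=lambda f: (round(scores[f], 12), kernel_menu.index(f)))

    pipe = builder(best, n_restarts)()
    pipe.fit(cal.X, cal.y)
    gp = pipe.named_steps["model"]
    return FittedModel(
        name="GPR",
        pipeline=pipe,
        chosen_kernel=best,
        chosen_params={"kernel": str(gp.kernel_), "cv_rmse": scores[best],
                       "log_marginal_likelihood": float(
                           gp.log_marginal_likelihood(gp.kernel_.theta))},
    )


def gpr_predict(model: FittedModel, X: np.ndarray):
    """Posterior predictive mean and standard deviation of a fitted GPR."""
    d = model.pipeline.named_steps["model"].X_train_.shape[1]
    if X.shape[1] != d:
        raise ValueError(f"query has {X.shape[1]} bands, model trained on {d}")
    return model.predict_with_std(X)


def plsr_fit(cal: SpectralDataset, max_components: int = 15,
             inner_folds: int = 5) -> FittedModel:
    """PLS regression with the latent-variable count chosen by inner CV."""
    rank = int(min(cal.X.shape[0] - 1, cal.X.shape[1]))
    max_components = min(max_components, rank)
    if max_components < 1:
        raise ConfigError("calibration set too small for PLSR")
    folds = _inner_folds_indices(cal, inner_folds)
    best_nc, best_rmse = 1, np.inf
    for nc in range(1, max_components + 1):
        # fold train sets shrink the feasible component count further
        if nc >= min(len(tr) for tr, _ in folds):
            break
        rmse = _cv_rmse(lambda nc=nc: PLSRegression(n_components=nc, scale=False),
                        cal, folds)
        if rmse < best_rmse - 1e-12:
            best_rmse, best_nc = rmse, nc
    pipe = Pipeline([("model", PLSRegression(n_components=best_nc, scale=False))])
    pipe.fit(cal.X, cal.y)
    return FittedModel(name="PLSR", pipeline=pipe,
                       chosen_params={"n_components": best_nc, "cv_rmse": best_rmse})


def svr_fit(cal: SpectralDataset, grid: dict | None = None,
            inner_folds: int = 5) -> FittedModel:
    """RBF support-vector regression with C/gamma/epsilon chosen by inner CV."""
    grid = grid or {
        "C": np.logspace(-2, 3, 6),
        "gamma": np.logspace(-4, 1, 6),
        "epsilon": [1e-4, 1e-3, 1e-2],
    }
    folds = _inner_folds_indices(cal, inner_folds)
    best, best_rmse = None, np.inf
    for C in grid["C"]:
        for gamma in grid["gamma"]:
            for eps in grid["epsilon"]:
                rmse = _cv_rmse(
                    lambda C=C, gamma=gamma, eps=eps: Pipeline([
                        ("scale", StandardScaler()),
                        ("model", SVR(kernel="rbf", C=C, gamma=gamma, epsilon=eps)),
                    ]),
                    cal, folds)
                if rmse < best_rmse - 1e-12:
                    best_rmse = rmse
                    best = {"C": float(C), "gamma": float(gamma), "epsilon": float(eps)}
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("model", SVR(kernel="rbf", **best)),
    ])
    pipe.fit(cal.X, cal.y)
    return FittedModel(name="SVR", pipeline=pipe,
                       chosen_params={**best, "cv_rmse": best_rmse})


# ---------------------------------------------------------------------------
# metrics and protocol


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """Coefficient of determination and root mean square error."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    if len(y_true) < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance in y_true; R2 undefined")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    return r2, rmse


def limit_of_detection(residual_sd: float, slope: float) -> float:
    """ICH detection limit ``3.3 * residual_sd / slope`` (percent in, percent out)."""
    if slope == 0:
        raise ValueError("zero calibration slope; LOD undefined")
    if residual_sd < 0:
        raise ValueError("residual_sd must be >= 0")
    return 3.3 * residual_sd / slope


def lod_from_calibration(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """LOD from the predicted-vs-reference ordinary regression of a calibration.

    Fits ``y_pred = a + S * y_true`` by least squares; the residual
    standard deviation (n-2 denominator) and slope S feed 3.3*rho/S.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if len(y_true) < 3:
        raise ValueError("need at least 3 calibration points")
    slope, intercept = np.polyfit(y_true, y_pred, 1)
    resid = y_pred - (intercept + slope * y_true)
    rho = float(np.sqrt(np.sum(resid**2) / (len(y_true) - 2)))
    return limit_of_detection(rho, float(slope))


def relative_improvement(metric_ref: float, metric_new: float,
                         direction: str = "lower-better") -> float:
    """Percent improvement of ``metric_new`` over ``metric_ref``.

    ``lower-better`` (errors): 100*(ref - new)/ref; ``higher-better``
    (R2-like): 100*(new - ref)/ref.
    """
    if metric_ref == 0:
        raise ValueError("reference metric is zero; relative change undefined")
    if direction == "lower-better":
        return 100.0 * (metric_ref - metric_new) / metric_ref
    if direction == "higher-better":
        return 100.0 * (metric_new - metric_ref) / metric_ref
    raise ConfigError(f"unknown direction {direction!r}")


def evaluate_model(model: FittedModel, cal: SpectralDataset,
                   test: SpectralDataset, with_lod: bool = True) -> RegressionReport:
    """Fill a report with calibration and held-out metrics (and LOD)."""
    pred_cal = model.predict(cal.X)
    pred_val = model.predict(test.X)
    r2c, rmsec = compute_metrics(cal.y, pred_cal)
    r2v, rmsev = compute_metrics(test.y, pred_val)
    lod = lod_from_calibration(cal.y, pred_cal) if with_lod else None
    return RegressionReport(
        model_name=model.name, r2_cal=r2c, rmse_cal=rmsec,
        r2_val=r2v, rmse_val=rmsev,
        predictions_cal=pred_cal, predictions_val=pred_val,
        chosen_kernel=model.chosen_kernel, chosen_params=model.chosen_params,
        lod_percent=lod,
    )


def double_cross_validation(
    ds: SpectralDataset,
    model_factory,
    cal_fraction: float = 0.70,
    inner_folds: int = 5,
    n_repeats: int = 1,
    seed: int = 0,
) -> RegressionReport:
    """Nested evaluation: outer 70/30 group split, inner k-fold selection.

    ``model_factory(cal, inner_folds, seed)`` must return a fitted
    :class:`FittedModel`.  With ``n_repeats > 1`` the outer split is
    redrawn with distinct seeds and the metrics averaged; the returned
    predictions are those of the last repeat.
    """
    reports = []
    for rep in range(n_repeats):
        cal, test = split_calibration_test(ds, cal_fraction, seed=seed + rep)
        model = model_factory(cal, inner_folds, seed + rep)
        reports.append(evaluate_model(model, cal, test))
    last = reports[-1]
    return RegressionReport(
        model_name=last.model_name,
        r2_cal=float(np.mean([r.r2_cal for r in reports])),
        rmse_cal=float(np.mean([r.rmse_cal for r in reports])),
        r2_val=float(np.mean([r.r2_val for r in reports])),
        rmse_val=float(np.mean([r.rmse_val for r in reports])),
        predictions_cal=last.predictions_cal,
        predictions_val=last.predictions_val,
        chosen_kernel=last.chosen_kernel,
        chosen_params=last.chosen_params,
        lod_percent=float(np.mean([r.lod_percent for r in reports])),
    )


def gpr_factory(kernel_menu=KERNEL_FAMILIES, n_restarts: int = 5,
                standardize: bool = True):
    """Model factory for :func:`double_cross_validation` running GPR."""
    def factory(cal, inner_folds, seed):
        return gpr_fit(cal, kernel_menu, inner_folds, seed,
                       n_restarts=n_restarts, standardize=standardize)
    return factory


def plsr_factory(max_components: int = 15):
    def factory(cal, inner_folds, seed):
        return plsr_fit(cal, max_components, inner_folds)
    return factory


def svr_factory(grid: dict | None = None):
    def factory(cal, inner_folds, seed):
        return svr_fit(cal, grid, inner_folds)
    return factory
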