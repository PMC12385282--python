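"""Estimate residue concentration from extracted spectra.

Builds the 120-spectrum concentration series (4 levels x 15 leaves x
2 ROIs), evaluates Gaussian-process regression against PLSR and SVR
baselines under double cross-validation (group-aware 70/30 outer split,
5-fold inner model selection), and reports the held-out R2/RMSE, the
relative improvement of GPR over the best baseline, and the ICH limit of
detection (3.3 * residual SD / slope of the calibration regression).
All concentrations are in percent active ingredient.
"""

from pestmap.quantification import (
    double_cross_validation,
    gpr_factory,
    plsr_factory,
    relative_improvement,
    svr_factory,
)
from pestmap.synthetic import make_concentration_series

ds = make_concentration_series(noise_sd=0.01, seed=11)
print(f"dataset: {len(ds)} spectra, {len(ds.wavelengths)} bands "
      f"({ds.wavelengths[0]:.0f}-{ds.wavelengths[-1]:.0f} nm)")

reports = {}
for name, factory in [("GPR", gpr_factory()), ("PLSR", plsr_factory()),
                      ("SVR", svr_factory())]:
    rep = double_cross_validation(ds, factory, cal_fraction=0.70,
                                  inner_folds=5, seed=11)
    reports[name] = rep
    kernel = f" (kernel: {rep.chosen_kernel})" if rep.chosen_kernel else ""
    print(f"{name:5s} R2v={rep.r2_val:.4f}  RMSEV={rep.rmse_val:.5f} %"
          f"  LOD={rep.lod_percent:.5f} %{kernel}")

best_rmse = min(reports["PLSR"].rmse_val, reports["SVR"].rmse_val)
best_r2 = max(reports["PLSR"].r2_val, reports["SVR"].r2_val)
print(f"GPR reduces RMSEV by "
      f"{relative_improvement(best_rmse, reports['GPR'].rmse_val):.2f} % "
      f"and changes R2v by "
      f"{relative_improvement(best_r2, reports['GPR'].r2_val, 'higher-better'):.2f} % "
      f"vs the best baseline")
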