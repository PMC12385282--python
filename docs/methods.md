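# Methods

## The measurement model

A line-scan SWIR instrument records a hypercube of detector counts over a
274-band grid starting at 894 nm with 5.876 nm resolution (so the last
band sits near 2498 nm). Counts are converted to reflectance with the
standard flat-field correction `R = (I_raw − I_dark)/(I_white − I_dark)`,
which cancels any common positive gain in illumination and detector
response. Reflectance outside [0, 1] is kept, not clipped: clipping would
bias the bilinear factorisation that follows, and out-of-range values are
informative about calibration drift (a warning is logged beyond ±0.05).
Analysis uses the 918–2058 nm window (194 bands of the default grid),
inclusive at both ends; no smoothing or other preprocessing is applied
after calibration.

## Unmixing

The unfolded matrix `D` (pixels × bands, row-major scan order) is
factorised as `D = C Sᵀ + E` with non-negativity on both factors.
Choices that matter:

- **Exact NNLS half-steps.** Each alternating update solves its
  constrained least-squares subproblem exactly (active-set solution, not
  clip-after-solve). Both half-steps share one design matrix across all
  right-hand sides, so the active set is found by enumerating the 2^k
  candidate supports, vectorised over pixels/bands; this is algebraically
  identical to per-row active-set NNLS and keeps a 64×64×274 fit under a
  second. Exactness is what guarantees the non-increasing LOF trace that
  the stopping rule relies on. Rank-deficient subproblems fall back to a
  tiny ridge (1e−10 · trace) with a logged warning.
- **Convergence** is declared when the relative change of LOF between
  consecutive sweeps falls below `tol` (default 0.1 %), or after
  `max_iter` (default 10 000) sweeps. LOF below 1e−9 % is float-level
  noise and is treated as a perfect fit.
- **Scale ambiguity** is fixed by rescaling each resolved spectrum to
  unit maximum after every sweep, absorbing the inverse scale into `C`.
  Component proportions (percent of total abundance per component) are
  computed under this convention; any other normalisation changes them,
  which is why reported proportions are convention-dependent quantities.
- **Initialisation.** Reference mode starts from measured pure spectra
  (interpolated onto the cube grid if needed). SIMPLISMA mode selects
  pure bands by purity `σ_j/(μ_j + δ)` with noise offset
  `δ = 3 %·max(μ)` (standard 1–5 % range), deflating successive
  selections by the determinant of the correlation-around-origin matrix
  of already-selected bands; initial spectra are the NNLS regression of
  `D` on the abundance proxies at the selected bands.
- **Component identity** (which factor is "residue") is assigned by
  maximal Pearson correlation with the reference or generating spectrum.
- **Residue ROIs** take the top 20 % of pixels by residue abundance
  (configurable), ties broken by scan order so masks are deterministic.

### Model order

The two-component model is the physically motivated choice (leaf +
residue). The quantitative signal that more components add nothing is
that LOF stops improving beyond k = 2; the tests assert exactly that. An
overcomplete factorisation of (near-)rank-2 data is degenerate: collinear
components can share abundance freely, so the *proportion* carried by an
extra component is not a reliable model-order diagnostic on synthetic
scenes, and no such threshold is asserted here.

## Quantification

The regression table holds one mean spectrum per leaf ROI with the
applied concentration in percent active ingredient (levels 0, 0.02, 0.04,
0.06 %).

- **Split protocol.** The outer 70/30 split is group-aware (both ROIs of
  a leaf stay together — a deliberate strengthening against leakage) and
  stratified by level with a largest-remainder rule that hands leftover
  calibration slots to the outer levels pairwise, keeping the label mean
  of both subsets at 0.030 % for the balanced design (84/36 rows).
- **GPR.** Spectra are standardised per band with calibration statistics
  only; the target is centred/scaled internally, reconciling the
  zero-mean GP prior with nonzero concentrations. Within each kernel
  family (SE, Matérn 3/2, Matérn 5/2, RQ, each times a signal variance
  plus a white-noise term), hyperparameters maximise the marginal
  likelihood with 5 restarts (the likelihood is multimodal; restarts are
  halved inside the inner folds and the winning family is refit with the
  full budget). The family with the lowest mean RMSE over 5 group-aware
  inner folds wins; ties go to the simpler family (SE < Matérn < RQ).
- **Baselines.** PLSR (mean-centred, 1–15 latent variables capped at
  rank) and RBF-SVR (standardised; grid C ∈ [1e−2, 1e3],
  γ ∈ [1e−4, 1e1], ε ∈ {1e−4, 1e−3, 1e−2}) are tuned by the same inner
  folds.
- **Metrics** are `R² = 1 − SS_res/SS_tot` and RMSE on the outer test
  predictions; with `n_repeats > 1` the outer split is redrawn and
  metrics averaged (default is the single split, matching a single
  reported test set).
- **LOD** = 3.3·ρ/S with ρ the residual SD (n−2 denominator) and S the
  slope of the ordinary regression of calibration predictions on
  reference values (the ICH reading). Because a GP with a small fitted
  noise term nearly interpolates its calibration set, its
  calibration-residual LOD on clean synthetic data is close to zero;
  LOD values are only meaningful up to the realism of the calibration
  residuals. No percent-to-ppm conversion is implemented: it requires a
  mass basis (spray volume, leaf mass) the model does not carry.

## Synthetic data

The generator emulates the study design: two endmembers built from
signed Gaussian bands (widths 15–40 nm) at the characteristic
wavelengths of perilla leaf (1123, 1170, 1300, 1450, 1652 nm; the
1450 nm water band as an absorption dip) and chlorfenapyr residue (1141,
1217, 1394, 1558, 1860 nm peaks, 1940 nm dip), with an azoxystrobin
variant (1217, 1394, 1623, 2030 nm); smooth/blob/half-field non-negative
abundance maps; white cubes with a smooth illumination field times a lamp
envelope and low-level dark cubes, composed so calibration recovers the
truth exactly; additive Gaussian noise with SD a fraction (default 1 %)
of the mean signal. The concentration series is
`leaf + c·residue` per ROI with a per-leaf multiplicative random effect
(SD 2 %, correlating the two ROIs of a leaf; disabled where an exact
linear oracle is wanted) plus band-wise noise, 15 leaves per level and
2 ROIs per leaf giving 120 rows. Everything is bit-reproducible per seed.

What the generator does *not* emulate: scattering and moisture-driven
baseline effects, droplet-drying spatial patterns, instrument striping,
and — importantly — any nonlinearity of the concentration response. On
an exactly linear series the linear PLSR baseline is the correctly
specified model and typically edges out GPR; the advantage of GPR
reported on real leaves plausibly stems from nonlinear matrix effects a
linear generator cannot produce. Passing tests therefore demonstrate the
correctness of the machinery and calibration-level performance bounds,
not that GPR dominates linear baselines on arbitrary data.

## Level comparison

Mann–Whitney U between consecutive concentration levels, two-sided,
midrank tie handling; exact null when min(n) ≤ 8 without ties, otherwise
the tie-corrected normal approximation with continuity correction. No
multiplicity correction is applied (per-pair α = 0.05 is reported
as-is). Pixels are treated as exchangeable; spatial autocorrelation
within a leaf makes the nominal p-values liberal, so borderline
significance should not be over-read.

## Problem sizes

Simulation-backed checks use 64×64×274 scenes (4096 pixels) and the
120-spectrum series, ten seeds each — sizes at which the full chain runs
in seconds per fit on one CPU while leaving the statistical structure of
the larger study intact.
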