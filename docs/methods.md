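# Methods

This note documents the models, the numerical choices, and what the
synthetic study conditions do and do not establish about real data.

## Bioclimatic variables

Eleven variables are derived from 36 monthly normals (12 × tmin, 12 ×
tmax, 12 × precipitation) on a fixed 365-day calendar with month lengths
[31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]:

| variable | definition | units |
|---|---|---|
| DD5 | Σ_days max(0, T_d − 5) | degree-days |
| DD0 | Σ_days max(0, −T_d) | degree-days |
| MWMT / MCMT | warmest / coldest monthly mean | °C |
| TD | MWMT − MCMT (continentality) | °C |
| MAT | month-length-weighted annual mean | °C |
| MAP / MSP / MWP | annual / Apr–Sep / Nov–Feb precipitation | mm |
| PAS | precipitation of months with tmean ≤ 0 °C | mm |
| NFFD | days with interpolated tmin > 0 °C | days |

Daily temperatures T_d are defined by piecewise-linear interpolation
between month-midpoint values, wrapping December to January.  This
closed definition replaces the regression-based degree-day
approximations common in forestry climate tools: it is exactly
reproducible and is anchored in the test suite to an independent
brute-force daily oracle (agreement to 10⁻⁶).  Design choices made
where conventions vary: TD uses warmest-minus-coldest month (not fixed
July/January); MWP wraps Nov–Feb within the climatological year; PAS
uses a 0 °C monthly-mean threshold; MWP is in mm (the "°C" sometimes
seen on winter-precipitation axis labels is treated as a typo).  No
leap years, no radiation or soil-water variables.

## Delta-method palaeo overlay

Coarse anomaly grids (12 additive ΔT layers in °C, 12 multiplicative
precipitation factors > 0) are regridded to the baseline geometry by
bilinear interpolation of cell-centre values (with linear extension
beyond the outermost centres, so constant and planar fields are exact),
then applied as `tmin+ΔT`, `tmax+ΔT`, `precip×factor`.  Multiplicative
precipitation is standard delta-method practice and preserves
non-negativity; an additive mode (clamped at 0) exists for sensitivity
runs.  One ΔT is applied to both tmin and tmax.  An optional 0/1 ice
mask forces cells to nodata before prediction, treating ice-covered
land as "no habitat information" rather than probability zero.
Whether the original workflow interpolated anomalies bilinearly or used
nearest-cell assignment is not documented; bilinear was adopted.

## Habitat model

A bagged ensemble of CART classification trees (scikit-learn learners,
explicit bootstrap loop).  Probabilities are **vote fractions** — the
share of trees classifying a cell as present — and each record's
out-of-bag (OOB) vote fraction (over the trees whose bootstrap sample
excluded it) provides internal validation, scored by AUC.

Defaults and why:

* `n_trees = 500` — vote fractions stabilise well below this; cheap.
* `max_features = "sqrt"` — classical random-subspace decorrelation.
* `min_samples_leaf = 10` — with probabilistic (Bernoulli) labels,
  fully-grown trees chase label noise; a modest leaf floor makes the
  vote fraction track the generating probability far more faithfully
  (rank correlation with the true niche rises from ≈ 0.87 to ≈ 0.95 in
  the recovery simulations) while leaving separable problems at
  OOB AUC 1.0.
* covariate set: DD5, MWMT, TD, MAP, MSP, MWP (six low-collinearity
  variables); the full 11-variable set is available per call.
* class weighting: none by default; a balanced-bootstrap option exists
  for absence-heavy data.

AUC is the Mann–Whitney pair statistic with mid-rank ties, computed via
ranks; it is invariant under strictly increasing transforms of the
scores.  Hindcast validation extracts the period surface at each fossil
record's cell, drops and counts records outside the grid or on nodata
(e.g. ice-masked) cells, and reports per-period and pooled
(concatenated) AUC — the pooling convention of the historical analyses
is not documented, so both are reported.

## Stability maps

Stability = `p_now × p_LGM` cellwise; by construction it is bounded by
`min(p_now, p_LGM)` and monotone in both inputs.  Classification
thresholds (moderate ≥ 0.25, high ≥ 0.5) are conventions — no published
definition of "moderate or high probability of persistence" exists —
and are exposed as parameters and recorded in the output.

## Trial model and REML

The phenotype model is the randomised-complete-block decomposition
given in the README; all terms after μ are independent mean-zero
Gaussian random effects.  For single-site traits the site and
provenance × site terms drop and block-within-site becomes block.
Fitted separately per region and trait, the residual component is the
within-population variance estimate.

Estimation details:

* REML (matching mixed-model software defaults), with the variance
  ratios γ_k = σ²_k/σ²_e profiled against the residual.  The profiled
  criterion is evaluated through the Woodbury identity on the q × q
  random-effects crossproduct matrix (q ≈ 300 for a one-region,
  five-site fit), giving O(q³) per evaluation.
* Non-negativity is enforced by L-BFGS-B bounds; estimates within
  10⁻¹⁰ of the boundary are reported as exactly 0.  A second start
  guards against stalls on flat likelihoods.
* The response is centred before forming crossproducts — a fixed-effect
  shift that REML is invariant to — to avoid catastrophic cancellation
  in y'Py when trait means are large (e.g. day-of-year phenology).
* Standard errors come from the observed information (finite-difference
  Hessian of the REML log-likelihood in the variance parameterisation),
  the analogue of the COVTEST output of SAS PROC MIXED; SEs are
  reported as undefined (NaN) for components estimated on the zero
  boundary.
* Random terms with a single level, or whose grouping duplicates an
  already-retained term (e.g. provenance × block when there is one
  block), are dropped from the model rather than made singular.
  Designs without within-plot replication are rejected: the residual
  would not be identifiable.
* On balanced designs with interior estimates, these REML estimates
  coincide with the classical ANOVA method-of-moments estimators
  (asserted against a closed-form oracle in the tests), and on
  unbalanced data they match R's lme4 to ~10⁻³ relative (independent
  cross-check in the test suite).

Provenance-mean ordination uses PCA of the correlation matrix (SVD of
the standardized provenance-mean matrix; orthonormal loadings; sign
fixed so each component's largest-magnitude loading is positive).
Under the balanced design, provenance means are least-squares means.

## Synthetic study conditions

The generator defaults define the simulated trial and landscape:

* **Trial**: 43 provenances in six regions (BC Northeast 6, Northern AB
  7, AB Foothills 7, Central AB 8, Saskatchewan 7, Minnesota 8 — the
  published design does not give the split), 5 sites × 6 blocks ×
  5-tree plots → 6,450 height records; phenology at one site → 1,290
  records.  Generating residual variances per region and trait are the
  published within-population components (height 0.61–0.94; bud break
  8.4–13.1; leaf senescence 5.2–10.3); the non-residual components are
  fixed at realistic magnitudes (height: σ²_P 0.15, σ²_S 0.5, σ²_P×S
  0.05, σ²_B(S) 0.10, σ²_P×B(S) 0.10; phenology: σ²_P 6, σ²_B 3,
  σ²_P×B 3 days²) since they are not published.  The height scale of
  0.61–0.94 after nine seasons implies the original heights were
  transformed before fitting; components here are reported on the input
  scale, whatever it is.
* **Climate**: a 40 × 50-cell, 0.5° grid with a 0.35 °C/row southward
  lapse around −4 °C mean, 16 °C seasonal amplitude, 8 °C diurnal
  range, one static elevation-like noise field (white noise smoothed
  over 3 cells, 1.5 °C SD), and a log-normal spatial precipitation
  field (CV 0.2) over a summer-peaked monthly profile.
* **Anomalies**: period means ΔT = −8/−5/−3/−1 °C and precipitation
  factors 0.70/0.80/0.90/0.95 for 21k/14k/11k/6k BP, with N(0, 1 °C)
  and log-normal (σ = 0.05) cell/month noise on a 4× coarser grid.
  These magnitudes are plausible mid/high-latitude values; the original
  climate-model anomaly fields are not published.
* **Occurrences** are sampled uniformly over non-nodata cells with
  replacement (plot density is a free parameter, not a published
  quantity); **fossil records** flip thresholded occupancy (threshold
  0.5) with the specified false-positive/false-negative rates.

What passing tests show — and don't.  The synthetic landscape has
smooth gradients, exogenous noise, no spatial sampling bias, no
observer error in occurrences, and fossil noise that is independent
across records.  Recovery of the niche, calibrated AUCs, and unbiased
variance components under these conditions validate the *machinery*;
they do not reproduce the published real-data results (OOB AUC 0.91 on
>600,000 plots; AUC 0.67 against 9,568 fossil records; continental
refugium maps), which require undeposited data and are explicitly out
of scope.

## Problem sizes and numerics

Default test and acceptance runs use the 40 × 50 synthetic grid, 5,000
training occurrences, 300–500 trees, 400 fossil records per period, and
100–200 REML replicates per recovery experiment; these sizes were
chosen so every distributional check has narrow Monte-Carlo error while
a full run stays comfortably on a laptop.  Replicate seeds are drawn
from a single seeded generator; every generator and fit is
deterministic given its seed.  Known limitations: no topographic
microclimate, no sea-level or ice-sheet reconstruction beyond the
optional mask, Wald-type variance SEs are asymptotic and poorly
calibrated for components with few levels (e.g. 5 sites), and the PCA
assumes complete provenance × variable matrices.
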