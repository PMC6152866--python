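# Methods

## Model and assumptions

`occumap` fits the single-season (static) occupancy–detection model.
Site presence is a latent Bernoulli state `z_i ~ Bernoulli(ψ_i)`;
conditional on presence, each survey occasion yields a detection
`y_ij ~ Bernoulli(z_i ρ_ij)`. Both probabilities take logit links:
occupancy on site covariates (linear and optional quadratic terms on
the standardised scale), detection on the sampling method — an
observation-level factor, coded as one intercept per method rather
than a reference-cell contrast, so per-method detectability is read
directly off the coefficients — plus optional site-level covariates
shared across methods (by default time since fire, fire frequency and
terrain ruggedness, chosen because fire history and terrain plausibly
affect sightability).

Assumptions inherited from the model class: closure of the occupancy
state across the survey period (or random movement in and out, which
re-interprets ψ as probability of use); independence of detections
across occasions given `z_i`; no unmodelled detection heterogeneity.
Detection covariates are site-level constants broadcast to occasions —
per-occasion covariates such as weather are not represented.

The site likelihood marginalises the latent state:

    L_i = ψ_i ∏_{j∈obs(i)} ρ_ij^{y_ij}(1−ρ_ij)^{1−y_ij}
          + (1−ψ_i)·1[all observed y_ij = 0]

Missing occasions are excluded from the product, which makes ragged
designs (3 vs 4 trap nights; method subsets per site) exact rather
than imputed. Sites with no observed occasions are dropped with a
warning. A site surveyed on a single occasion leaves ψ and ρ
identified only through their product; the likelihood is flat along
ψρ = constant, and the test suite asserts this explicitly.

## Estimation and numerics

Maximum likelihood on the unconstrained logit-scale coefficients with
L-BFGS-B and analytic gradients (objective tolerance 1e-10, gradient
tolerance 1e-6), from 5 jittered starts by default (Gaussian jitter,
sd 0.5, seeded); the best optimum is kept. Starting values: the ψ
intercept from the logit of naive occupancy (fraction of sites with
≥1 detection, clipped to [0.05, 0.95]); method intercepts from the
logit of per-method detection frequency among detected sites; all
slopes at zero. Linear predictors are clipped at |η| = 35 before the
inverse logit, past which probabilities are numerically 0/1.

Standard errors come from the inverse observed information (numeric
central-difference Hessian of the analytic gradient). A condition
number above 1e10, a non-finite Hessian, or negative variances mark
the fit with `boundary_flag` instead of failing; the flag is also set
when every fitted ψ (or every fitted ρ) is within 1e-4 of 0 or 1 —
the classic symptom of too few detections.

A brute-force likelihood (explicit summation over `z_i ∈ {0,1}` per
site, plain loops, no shared code with the vectorised path) serves as
the oracle in tests; the two agree to ~1e-14 on random instances.

## Detection histories

Raw events carry (site, species, method, occasion, sub-event,
detected). Collapsing scores an occasion 1 if any event within it
detected the species, 0 if surveyed without detection, missing if not
surveyed; the `daily` rule is the occasion unit for traps and
searches, `weekly` for cameras (occasion indices arrive pre-binned —
calendar parsing is out of scope). Sub-events exist to exercise the
any-detection rule (e.g. three 10-minute bird surveys per day);
default designs use one. Per-method matrices are appended column-wise
over the union of sites, missing where a site lacks a method, with
method order lexicographic by default and overridable so the factor
level order is reproducible. Sites trapped 3 of 4 nights get a missing
fourth occasion rather than a shortened row.

## Covariate preparation

Screening: pairwise Spearman |ρ| > 0.7 (strict) discards the
lower-priority member of each offending pair, iterating until no
retained pair exceeds the threshold; priority is a user-supplied list
defaulting to column order, which reproduces ad-hoc published choices
(e.g. dropping a minimum-temperature layer correlated with rainfall)
by configuration. Standardisation uses sample sd (n−1); constants are
stored and reapplied verbatim at prediction time. Quadratic terms are
computed on the standardised scale and require their linear term
(marginality — the enumeration stays interpretable); fire extent and
fire patchiness refuse quadratics by default, since those indices are
already aggregate neighbourhood summaries. Raster coarsening uses
block means over finite cells (all-missing blocks stay missing).

## Model selection

Candidates are all subsets of the screened occupancy covariates
(optionally with quadratics) crossed with all subsets of the detection
covariates; the method factor is always present for multi-method
species and never counted as a covariate term. The complexity cap is
`floor(n_detection_sites / 10)` covariate terms, counting each linear
or quadratic term as one, summed over both model parts (the
alternative ψ-only count is a config switch). Non-converged fits are
excluded; models are ranked by AIC = −2logL + 2k with ties broken by
fewer parameters then enumeration order; the retained set is ΔAIC
strictly below 6. Selection walks that set in rank order, rejecting
boundary-flagged fits, goodness-of-fit failures (any statistic with
p ≤ α, default 0.05), and vetoes from pluggable screen predicates —
the hook where expert map validation would sit; the default accepts
everything, since expert judgment is not reproducible. If the set is
exhausted, the species falls back to the constant model (method factor
retained); species below 10 detection sites are capped at zero terms
and therefore fit as nulls, flagged in the summary. The pipeline
refuses dredges beyond `max_models` (default 10 000) candidate
specifications per species; full-study dredges of a dozen covariates
with quadratics are possible but should be configured deliberately.

## Goodness-of-fit

Parametric bootstrap, B = 1000 by default: simulate a dataset from the
fitted model on the same design and missingness pattern, refit the
same specification (warm-started at the generating coefficients),
compute the statistics on the simulated data against its own refit,
and report p = (1 + #{t_sim ≥ t_obs}) / (B + 1) — never exactly zero
at finite B. All three statistics share one replicate stream.
Replicates whose refit fails are redrawn; above 10% redraws the result
is flagged unstable.

The bootstrapped statistics (SSE, Freeman–Tukey, Pearson) are computed
on detection-history frequencies: sites are cohorted by missingness
pattern, observed counts of each distinct history are compared with
their expected counts under the fitted model, and a remainder cell
absorbs never-observed histories so expectations sum to the cohort
size. This construction was chosen after the obvious alternative —
the same statistics on cell-level fitted values ψ̂ρ̂ — proved nearly
ancillary for Bernoulli detections: the likelihood equations pin the
detection totals those statistics aggregate (for a constant model the
cell-level Pearson statistic is *identically* the number of cells),
so their bootstrap p-values collapse around 0.5 and carry no
lack-of-fit information. The cell-level statistics remain available
(`gof_statistics`) as descriptive discrepancies. The
history-frequency p-values are uniform under a correctly specified
model (KS p ≈ 0.6–0.9 in the calibration study), slightly
conservative at small cohort counts.

## Mapping

Prediction standardises each raster cell with the fitting-time
constants, then applies the inverse-logit linear predictor; any cell
missing a required covariate is missing in the output. The
environmental-domain mask keeps cells where every selected covariate
lies within the closed [min, max] observed at the monitoring sites —
min/max is the reproducible default, with an optional quantile trim
for a stricter domain; the published analyses' exact truncation
thresholds are judgement calls we do not guess. Restricted-range
species are handled by a buffered region mask (Euclidean distance
transform on cell centres for gridded regions, point-in-polygon for
shapely geometries; 5 km is the conventional buffer) applied both to
the sites used for fitting and to the predicted surface. Richness is
the cellwise sum of predicted ψ across non-null species — a relative
index (summed occupancy probability), not an expected species count;
cells missing in some species contribute zero there and a coverage
grid records how many species contributed. Null-model species are
excluded from richness but their flat surfaces are still written.

Rasters are in-memory `GridStack` objects serialized as ESRI ASCII
grids (plain-text, GDAL/QGIS-readable) with a JSON sidecar for layer
names and scaling constants; masks and surfaces use the same format
with NaN as nodata.

## Synthetic data

The generator emulates the statistical structure of a multi-method
regional monitoring study: ~300 sites on a smooth covariate landscape;
13 covariates named after the climatic/topographic/fire set typical of
such studies, with two pairs correlated above the 0.7 screening
threshold (rainfall–minimum temperature at 0.85, fire
frequency–proportion burnt at 0.8) so the screening stage fires; 3–4
daily occasions for trap/search methods and 5 weekly camera occasions;
and species panels spanning mean occupancy ~0.01–0.8 and per-occasion
detectability ~0.01–0.9, matching the spread reported for tropical
savanna vertebrates. Landscapes are independent Gaussian white-noise
fields smoothed with a 3-cell Gaussian kernel (smoothness makes
domain-mask tests meaningful), rescaled to unit variance and mixed
through the Cholesky factor of the target correlation, so cellwise
cross-covariate correlation is exact in distribution while neighbouring
cells remain similar.

What the generator does **not** emulate: real fire-scar dynamics or
climatologies (only Gaussian surrogates), spatial autocorrelation in
occupancy beyond what covariates induce, detection heterogeneity
between individuals or observers, and non-closure. Passing tests
therefore demonstrate correctness of the estimator and pipeline under
the model's own assumptions, not robustness to their violation.

## Validation studies and problem sizes

`occumap.calibration` holds the simulation studies that
`scripts/acceptance.py` and the acceptance tests run; sizes were
chosen to estimate each property precisely while keeping a full run
around one minute on one CPU:

- likelihood vs brute-force enumeration: 100 random instances, ≤5
  sites, ≤9 occasions, 2 methods (agreement ~1e-14, tolerance 1e-10);
- constant-model MLE vs 0.001-resolution grid search on a fixed 5-site
  toy dataset (tolerance 0.005 per coordinate);
- Wald coverage: 200 datasets of 300 sites, K=4, two methods, ψ ~
  intercept + 1 covariate at interior values; coverage within
  [0.90, 0.98] per coefficient, |bias of mean ψ̂| < 0.02;
- AIC retention: 100 datasets of 500 sites, |β| = 1, 4 candidate
  covariates; generating model in the ΔAIC < 6 set ≥ 85% of runs;
- GoF calibration: 50 outer replicates, B = 100, 100 sites;
  KS-uniformity of p-values at α = 0.01;
- richness convergence: 20 replicates, 40×40 landscape, 3 species,
  sampling effort 100 → 300 → 1000 sites; mean absolute cell error
  decreases monotonically.

## Known limitations

Single-season only (no colonisation/extinction dynamics); no
abundance-induced heterogeneity (Royle–Nichols) or observer effects;
no multimodel averaging — a single best model is selected; richness
maps ignore the variance of each species' surface; AUC-style
discrimination metrics are deliberately absent because non-detections
are not confirmed absences under imperfect detection.
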