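# Methods

This note documents the models, numerical choices, and synthetic-data
conditions behind `omihet`, and what the test suite does and does not
establish about real data.

## Decay model and fitting

A TCSPC pixel histogram over 256 bins (default bin width 0.039 ns, ~10 ns
window) is modeled as an IRF-convolved two-exponential decay plus a constant
background C. The IRF is Gaussian with configurable FWHM (default 0.25 ns)
and peak at 10% of the window — a standard, analytically controllable stand-in
for a measured instrument response. Simulation and fitting share the same
discrete convolution on the bin grid (time origin at bin 0, no color-shift
parameter), so fit-quality tests isolate estimator error from discretization
error. Decay photons are scaled so the expected in-window sum equals the
requested photon budget; observed counts are Poisson draws.

Fitting is variable projection: for any (τ₁, τ₂) the amplitudes and C enter
linearly and are solved by weighted non-negative least squares, so the outer
optimizer (`scipy.optimize.least_squares`, trust-region reflective) searches
only two dimensions. Bounds keep the components identifiable: τ₁ ∈ [0.05,
1.5] ns, τ₂ ∈ [0.8, 10] ns, amplitudes and C ≥ 0. Initialization is (0.3,
2.5) ns for NAD(P)H and (0.3, 2.0) ns for FAD; deterministic perturbations
(×0.5, ×1.5, ×2.0) are tried only if a start fails, keeping the fit
deterministic for identical input.

Weights: the first pass uses Neyman weights 1/max(count, 1). Pure Neyman
weighting overweights downward count fluctuations and at a 5,000-photon
budget biased τₘ low by ~5% (median |error| 5.1% over 200 Monte-Carlo
draws). Two further passes therefore refresh the weights from the fitted
model (Pearson weighting); this removes the bias (−0.1%) and brings the
median |τₘ error| to ~2.4%. The reduced χ² uses n − 5 degrees of freedom.
Pixels under 500 photons (after 3×3 spatial binning, which mirrors the
standard practice of summing the 8 surrounding pixels) are marked invalid —
two-exponential fits below that budget are ill-conditioned.

## Per-cell quantification and the OMI index

Segmentation is deliberately simple: Gaussian smoothing (σ = 2 px), global
Otsu threshold, removal of objects under `min_area`, and marker-based
watershed on the distance transform to split touching cells. Lumens and dark
nuclei fall below the global threshold and are never part of a label. Hollow
vs. solid morphology is consumed as metadata, never computed.

The per-cell redox ratio is the ratio of the cell's mean NAD(P)H to mean FAD
intensity (ratio of means, robust to dim-pixel ratio noise), not the mean of
pixel ratios. Each of the three endpoints — redox ratio, NAD(P)H τₘ, FAD τₘ
— is divided by the mean over control cells of the same patient and
timepoint and then has 1 subtracted, making all three addends unitless
fractional deviations before the (1, 1, −1) combination; without that
scaling the combination would add a unitless ratio to nanosecond lifetimes.
Control cells therefore average to OMI index 0 (machine precision) within
every stratum, and a normalized redox ratio of 1.

## Mixture modeling and the wH-index

Subpopulation models are 1-D Gaussian mixtures with g ∈ {1, 2, 3}, selected
by AIC with k = 3g − 1 free parameters. The EM implementation is owned by
the package and fully deterministic: component means start at the g sample
quantiles (2i+1)/2g, weights start uniform, and all components start at the
overall sample variance — a deliberately broad initialization in the style
of widespread mixture-fitting software. Convergence stops when the relative
log-likelihood change falls below 1e−3 (at most 100 iterations); component
variances have a hard floor of 1e−6 × sample variance (1e−12 for constant
samples, which short-circuit to a degenerate g = 1 model).

Two of these choices matter and were made deliberately. First, aggressive
multi-start optimization is counterproductive here: the mixture likelihood
of a plain unimodal sample contains spurious overlap-split optima whose gain
exceeds the AIC penalty, and the harder the EM optimizes, the more often
AIC selects g ≥ 2 on data with no real subpopulations (a single broad
deterministic start selects g = 1 on N(0,1) samples of n = 500 in ~96–99%
of seeds; ten k-means++ restarts drove that below 85%). Second, early
stopping acts as a mild regularizer against those same splits while leaving
well-separated mixtures — which converge in a few iterations — untouched
(4σ-separated two-component recovery: 100/100 seeds, mixing proportions
within 0.1).

The wH-index is evaluated on the selected model:
`Σᵢ (1 − pᵢ ln(pᵢ+1)) (σᵢ + dᵢ)`, with dᵢ = |μᵢ − m| and m the median of the
fitted mixture (root of the mixture CDF at 1/2 by bisection, not the sample
median — the index is defined on the model). For g = 1 this reduces to
(1 − ln 2)·σ ≈ 0.3069 σ; the index is translation-invariant and scales
linearly with the data scale.

Companion descriptors: quadratic entropy on 20 equal-width bins with
range-normalized distances (bounded in [0, 1]); the KS statistic against a
normal with the sample's mean and SD (a descriptive normality distance, not
a test); outlier percentage by Tukey 1.5·IQR fences. All are 0 on constant
input.

**Bootstrap.** `bootstrap_wh` draws n_boot = 1,000 resamples and re-fits the
mixture in each. By default g is selected once on the full sample and held
fixed across resamples: bootstrap resampling duplicates points, and AIC read
on such lumpy resamples systematically inflates g, making the wH
distribution jump between model classes (bootstrap means 30–230% away from
the point estimate) rather than reflect sampling noise. With fixed g the
bootstrap mean tracks the point estimate to well under 1% on unimodal
samples. Re-selection per resample remains available (`reselect_g=True`) for
propagating model-choice uncertainty explicitly.

## Response statistics

Glass's Δ = (mean(control) − mean(treated)) / SD(control, ddof = 1);
positive Δ means the treated mean decreased, the response direction for the
OMI index. The Wilcoxon rank-sum p-value uses exact enumeration when both
groups have n ≤ 10 without ties and the tie- and continuity-corrected normal
approximation otherwise. The classifier calls `predicted_responder` iff
Δ ≥ 0.75 (inclusive) and the point wH-index change is negative; exactly
equal wH values return `indeterminate`. No multiple-testing correction is
applied by default (raw rank-sum p-values are reported); Benjamini–Hochberg
is available as an option.

Variance partitioning regresses an endpoint on group indicators by OLS and
reports 100 × adjusted R², restricted to control cells at each patient's
first timepoint (organoid grouping within a patient; patient grouping across
patients). Adjusted R² can be slightly negative under the null and is
reported raw, with a floored companion column for plotting.

## Synthetic data: what it emulates, what it does not

The cohort generator draws cells within organoids within patients with
additive Gaussian variance components per endpoint; treatment arms get their
own organoids (treated and control organoids are physically distinct
cultures). Treatment shifts are expressed in control-SD units
(√(var_organoid + var_cell)); treated arms may instead be mixtures of
subpopulations, each with a per-endpoint shift and a cell-noise SD
multiplier, and an arm-level organoid-SD multiplier models treatments that
homogenize the response across organoids. Endpoints are drawn independently
(an optional joint distribution is out of scope; no joint distribution is
established for these endpoints).

Default conditions: variance components give organoid-level intraclass
correlation ≈ 0.23, inside the 16–36% organoid-level fraction reported for
patient organoid cohorts; planted-response cohorts use 6 organoids × 40
cells per arm (treatment groups pool cells from at least five imaged
organoids). The FLIM simulator defaults to 5,000 photons per binned pixel —
chosen for fit stability, not measured fidelity to any instrument — and
disc/annulus cell geometry, which exercises segmentation and hollow/solid
contrast without a morphology engine.

Passing tests on these data establish estimator correctness (round-trip
recovery, oracle equivalence, determinism) under the stated noise model.
They do not establish robustness to optical effects the simulator omits:
depth-dependent scattering, point-spread blur, autofluorescence from
non-cellular material, segmentation errors on irregular morphologies, or
correlated endpoint noise.

## Pipeline

`run-all` executes simulate → fit-flim → segment → quantify → heterogeneity
→ respond → report, each stage writing versioned outputs and log counts;
stages are individually invokable and fail with the stage name and offending
path. The bundled synthetic fixture is two patients × 3 organoids × 2 arms
with 32×32-pixel, 3-cell images — sized so a full run fits comfortably in an
interactive session; every CSV carries the config hash and seed in a `#`
header line, and reruns with the same seed reproduce CSVs byte for byte.
Figures (effect-size heatmap with Δ ≥ 0.75 asterisks, overlaid normalized
density curves annotated with g) always have CSV twins containing exactly
the plotted numbers.

## Known limitations

- The two-exponential model is assumed exact; no model-selection against
  mono- or tri-exponential decays per pixel.
- The classifier threshold Δ = 0.75 is a proposed cutoff from a small
  cohort, not a validated decision boundary; treat calls as a screening
  signal.
- AIC's false-split rate on unimodal groups (~2–4% at n = 240–500) puts a
  ceiling on responder-classification accuracy, since one spurious g ≥ 2
  selection inflates the treated wH discontinuously.
- Cells are not tracked across timepoints; each timepoint images separate
  representative organoids.
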