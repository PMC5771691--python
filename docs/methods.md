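# Methods

## The growth–degeneration model

Regional brain area is modelled as `dA/dt = (G − D)·A`, a piecewise
exponential with a growth coefficient *G* and a degeneration coefficient *D*
(both mo⁻¹) that are constant within each phase of the age grid
{0, 1, 2, 6, 23} months.  The data are cross-sectional group means: each age
point comes from a different set of animals, so the model is fit to the mean
trajectory, not to longitudinal curves, and the package deliberately reports
point coefficients without confidence intervals.

**Discretization.**  The continuous model admits several discrete
identifications of the net coefficient `k = G − D` from two anchors
(A₀, t₀), (A₁, t₁).  The package default is the end-anchored rule
`k = (ΔA/Δt)/A₁`, i.e. the interval's mean rate referred to the area at the
interval's end; this is the convention under which the packaged reference
summaries reproduce the study's coefficient table (the logarithmic
alternative `k = ln(A₁/A₀)/Δt` differs by up to ~70% in the fast first-month
phase and is available via `convention="log"`).  Forward simulation inverts
whichever rule was used: `A₁ = A₀/(1 − kΔt)` for the end-anchored rule
(requiring `kΔt < 1`), `A₁ = A₀·e^{kΔt}` for the logarithmic rule, so
simulate→fit is an exact round trip.

**Identification.**  *G* and *D* are not separately identifiable from a net
rate, so structural assumptions pin one of them per phase: in controls
degeneration is negligible before `growth_phase_end` (default 6 mo) and
growth negligible after it.  The two counterfactuals then ask whether the
mutant's trajectory can be explained by one mechanism alone:

* *undergrowth-only* holds *D* at control levels during growth phases and
  solves for *G*; after the growth-phase end the shared structural
  assumption `G = 0` applies and *D* is refit to the mutant data.  (Holding
  *D* at the control value there instead would force a negative *G*; the
  refit convention is the one under which the reference summaries reproduce
  the published decline-phase cells, where both counterfactual columns
  coincide.)
* *degeneration-only* holds *G* at control levels in every phase and solves
  for *D*.

Both variants preserve the interval's net coefficient exactly
(`G − D = k`), so they repartition — never change — the fitted kinetics.
Negative fitted coefficients are reported verbatim and flagged
`feasible = False`; infeasibility is the scientific conclusion (a mechanism
that cannot explain the data), not an error state.

**Atrophy percentages.**  `percent_decrease` reports
`100·(mean_ref − mean_test)/mean_ref`.  The default uncertainty is
`100·SEM_test/mean_ref` — the convention that matches the published "± x%"
annotations — with first-order (delta-method) propagation of both SEMs as an
option.

## Summary-statistic inference

All tests run from (mean, SEM, n) cells or raw vectors interchangeably; the
group SD is reconstructed as `SEM·√n` and every statistic used (pooled *t*,
*F* ratios, studentized range, clustered-age OLS slopes) is a function of
per-group means, SDs and counts only, so the two routes agree to machine
precision whenever the raw data realize the summaries.  Where an explicit
data vector is required (the two-way Type III fit) a deterministic
standardized ramp with the exact sample mean and SD stands in; the resulting
ANOVA is exact, not approximate.

Choices:

* pooled-variance Student *t* (df = n₁+n₂−2) is the default, Welch a flag;
* one-way ANOVA uses the classical between/within decomposition; Tukey HSD
  p-values come from scipy's studentized-range distribution with the
  Tukey–Kramer harmonic-mean correction for unbalanced pairs;
* two-way ANOVA uses classical cell-means formulas in balanced designs and
  Type III sums of squares with sum-to-zero contrasts (via statsmodels OLS)
  when unbalanced, matching the conventions of the common commercial ANOVA
  packages; variance shares are `100·SS_term/SS_total` including the
  residual, and sum to 100;
* slope comparison fits OLS per group and tests
  `t = (b₁−b₂)/√(SE₁²+SE₂²)` on the summed residual df.  With two age
  clusters the slope depends only on cluster means and counts, so it is
  exact from summaries; the SE additionally uses the reconstructed
  within-cluster SDs.
* p-values are reported at full precision; the report layer bins them as
  `*` ≤ 0.05, `**` ≤ 0.01, `***` ≤ 0.001, `****` ≤ 0.0001.

## Morphometry

Operators work in 0-based (row, col) pixel coordinates with an explicit
`pixel_size_um`.

* **Purkinje-cell linear density**: somata within a capture distance
  (default 1.5× the soma radius, default radius 10 µm) of the layer polyline,
  divided by the physical path length, reported per 100 µm.
* **Signal-area fraction**: percent of pixels above a threshold.  The
  default rule is background mean + k·SD (k = 3); when no background mask is
  supplied the sub-Otsu pixels serve as the background sample — a
  reproducible stand-in for manual thresholding against a dark background,
  which is not otherwise specifiable.  Otsu and fixed thresholds are
  options.
* **Tiled cell counts**: square fields (default 228 µm side) as half-open
  rectangles, so a centroid on a shared edge is counted exactly once;
  per-field counts and the summed total are reported.  The field geometry is
  configurable because published field descriptions of the form "N-µm²
  regions" are ambiguous at face value (a 228 µm² region is a ~15 µm square
  that could not hold the reported counts); the package reads them as
  squares with the stated side length.
* **Puncta sizing**: 8-connected components (configurable) of the
  thresholded puncta channel, restricted to components overlapping a cell
  mask, with a minimum-size filter (default 2 px); areas are pixel counts ×
  `pixel_size_um²`, reported per cell and overall.  Regions with no
  mask-positive cells return an empty result with a warning rather than a
  number.

## Synthetic data

The cohort generator draws per-animal areas as `A_true(age) × noise` around
trajectories advanced by the same discrete rule the fitter inverts.  Default
conditions mirror the study's structure: the {0, 1, 2, 6, 23} mo age grid,
coefficients at the fitted study scale, multiplicative normal noise with
CV 5% (the published SEM/mean ratios for gross areas are mostly 1–8%), and
8 animals per age point; a mean-one lognormal noise option guarantees
positivity.  All randomness derives from one integer seed through numpy's
SeedSequence/PCG64, with substreams spawned per group in sorted key order;
outputs carry the seed and a spec hash.

Image scenes are idealized: disk somata along a sinusoidal folium-like path
with jittered spacing and Bernoulli dropout; stain coverage painted by
thresholding a smoothed random field at the exact target quantile; Poisson
cell fields; gamma-distributed puncta drawn as non-overlapping disks (with a
2-px halo so components never merge and a one-step radius correction for
rasterization).  Ground truth lists the surviving objects and as-drawn
areas.  The scenes contain no staining gradients, sectioning artifacts,
overlapping somata or detection noise, so passing recovery tests validates
the *operators'* bookkeeping and calibration — not detection performance on
real histology, which is out of scope.

## Numerical and degenerate-input conventions

* Zero pooled variance: equal means give t = 0, p = 1; unequal means give
  p = 0 with an explicit warning rather than a division error.
* Single-animal cells: SEM recorded as 0 and flagged; summary-mode ANOVA
  rejects n = 1 groups (within-group variance undefined).
* The discrete simulator refuses `kΔt ≥ 1` (singular inversion); the fitter
  refuses intervals straddling the growth-phase boundary, non-increasing
  ages, and non-positive end areas.
* Table output uses 6 significant digits by default (configurable); JSON
  keeps native floats.

## Problem sizes

The test-suite calibration runs use 200 Monte-Carlo cohorts (CV 5%, n = 8
per age) for coefficient-recovery bias, 2000 null replicates for type-I
calibration of the t test and one-way ANOVA, and single 512²–1024² px scenes
for morphometry recovery — sizes at which the checks are statistically
informative while the whole suite runs in well under a minute.

## Known limitations

* Coefficients computed from *printed* (rounded) group means differ from
  those computed from raw data in cells formed as small differences of
  near-equal numbers; the package propagates input-rounding intervals in its
  acceptance tests rather than pretending to more precision than the inputs
  carry.
* No continuous-time maximum-likelihood fit to animal-level data and no
  uncertainty on *G*/*D*: the estimand is the group-mean trajectory.
* Morphometry consumes ground-truth objects or simple thresholded synthetic
  images; it does not segment real stains.
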