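# Methods

## Exposure model

The package implements the standard chronic oral-ingestion model for a
single contaminant: estimated daily intake `EDI = C_f·C_d/B_w`
(mg/kg/day) and hazard quotient `HQ = EDI/RfD`. It assumes drinking
water is the only exposure route, intake and body weight are constant
within a group, and toxicity is adequately summarised by the oral
reference dose (1.6 mg/kg/day for nitrate). Carcinogenic endpoints,
dermal/inhalation routes and multi-contaminant hazard indices are out
of scope.

The four built-in groups (infant 0.08 L/day / 10 kg, children 0.85 / 15,
teenager 2 / 50, adults 2.5 / 78, RfD 1.6 throughout) are the
parameterisation under which the packaged survey's hazard table was
produced; they can be overridden per run.

Exceedance is strict (`HQ > 1`); a quotient exactly at 1 is reported as
at the acceptable limit, not above it.

## The packaged survey and its errata

The reference dataset is a survey of 66 rural groundwater wells with
nitrate between 6 and 49 mg/L (mean 15.10, sample SD 6.15). The
package reproduces all 264 EDI and 264 HQ cells of the published
per-sample table at the printed 4 decimal places. Two conventions
matter:

* **Rounding.** All computation is in full double precision; only
  comparisons against printed values round. The published table rounds
  ties *half-up* (0.31875 → 0.3188), the spreadsheet convention, so the
  package provides `round_half_up` and uses it for printed-value
  comparisons; Python's built-in banker's rounding would miss five
  cells that land exactly on a tie.
* **The summary rows.** The published Mean and SD rows are identical
  (e.g. both "6.15" for concentration). Recomputation shows the SD row
  is genuine — the sample SDs of concentration (6.148) and of HQ per
  group (0.0307, 0.2177, 0.1537, 0.1232) match it exactly — while the
  Mean row is a duplicated copy of the SD row. The correct means are
  15.097 mg/L for concentration and 0.0755 / 0.5347 / 0.3774 / 0.3024
  for the group HQs. Tests assert the recomputed values and exclude the
  corrupted printed row.

SD is the sample standard deviation (n−1) throughout; a single
observation reports SD 0.

## Monte-Carlo engine

Plain independent Monte-Carlo (no Latin-hypercube or quasi-random
sequences, no input correlation): each of `C_f`, `C_d`, `B_w` is given a
`DistributionSpec` — point, normal, lognormal (parameterised on the log
scale), uniform, triangular, or empirical resampling — and
`n_iterations` triples (default 10,000) are pushed through the exposure
model. Defaults make only the concentration stochastic, fitted to the
sample data, because it is the only input with measurements behind it;
intake and weight stay at their nominal values unless the user supplies
distributions.

Numerical and procedural choices:

* **Fitting.** Candidates are fitted by maximum likelihood
  (`scipy.stats`); the winner has the smallest Kolmogorov–Smirnov
  statistic, ties broken by log-likelihood. On the packaged survey the
  lognormal (mu 2.6519, sigma 0.3436 on the log scale; K-S 0.117) beats
  the normal (K-S 0.165), as expected for right-skewed concentration
  data. Constant data collapse to a point mass; if every fit is
  degenerate the empirical distribution is used with a warning.
* **Quantiles.** Linear interpolation between order statistics (the
  "type 7" rule shared by numpy, R and spreadsheets).
* **Physical support.** Draws with negative concentration or
  non-positive intake/weight are rejected and redrawn; the count is
  reported and capped at 10× the iteration count, after which the run
  errors rather than silently biasing. Explicit truncation bounds are
  honoured the same way.
* **Degenerate output.** When every draw is identical (all inputs point
  masses) the mean and SD are reported as the common value and exactly
  0, so the probabilistic result collapses bitwise onto the
  deterministic one rather than carrying ~1e-16 accumulation noise.
* **Sensitivity.** Contribution to variance is the squared Spearman
  rank correlation of each stochastic input with HQ, normalised to sum
  to 1 — the rank-based measure spreadsheet risk tools report, robust
  to the multiplicative model. Point-mass inputs are excluded; an
  all-point-mass configuration yields an empty mapping.
* **Reproducibility.** All randomness flows through
  `numpy.random.default_rng(seed)`; identical configuration implies
  bit-identical results.

The published probabilistic summary for this survey prints means around
0.01–0.017 and P90s around 0.3 for all groups, which is internally
inconsistent with its own per-sample table (children HQ routinely
exceeds 0.4). The package therefore reproduces the *structure* of that
deterministic-vs-probabilistic report (mean, SD, P90, exceedance
probability per group) but validates its numbers against closed forms —
e.g. the lognormal P90 `exp(mu + 1.2816·sigma)·C_d/(B_w·RfD)` — and
against the deterministic collapse, not against those printed values.

## IDW interpolation

Prediction at a target point is the weighted mean of well values with
weights `d^-p` (power p = 2 by default, configurable), optionally
restricted to the k nearest wells and/or a search radius. Because the
weights are positive and normalised, predictions are convex
combinations of the data: bounded by the observed min/max, exact at
well locations (a target within 1e-9 degrees of a well returns that
well's value, ties among coincident wells averaged), and converging to
nearest-neighbour as p grows. Distance ratios are normalised by the
per-target minimum distance before exponentiation so that very large
powers neither overflow nor underflow.

Distances are planar Euclidean in degree space (adequate at single
well-field extents; an equirectangular option scales longitude by
cos(mean latitude)). Wells sharing a location are averaged before
interpolation, with a warning; wells without coordinates are excluded,
with a warning. Cell values are computed at cell centres; rasters are
stored and written north-to-south (ESRI ASCII convention). Kriging is
deliberately not implemented.

The survey publishes no well coordinates, so no published raster can be
reproduced numerically; the spatial module is validated by its
mathematical properties and by recovery of known synthetic trend
surfaces.

## Synthetic generator

`generate_wells` scatters wells uniformly in a bounding box (default:
an approximate 0.5°×0.5° box around 27.2° N, 60.7° E, the surveyed
region). Concentrations come either from a distribution — default the
lognormal fitted to the packaged survey, frozen as
`FIXTURE_LOGNORMAL = lognormal(2.65186, 0.34362)` — or, in
`trend_plus_noise` mode, from a bilinear surface on bbox-normalised
coordinates plus Gaussian noise, floored at zero. The generator
emulates the survey's right-skewed 6–49 mg/L concentration scale and a
spatially smooth field sampled at scattered points; it does *not*
emulate hydrogeology (flow, transport, anisotropy), clustered sampling
designs, censored/non-detect values, or measurement error, so passing
tests demonstrate correctness of the computational pipeline rather
than realism of any particular aquifer.

## Problem sizes

The test suite runs the full 66-well table reproduction, Monte-Carlo
checks at 10³–10⁵ iterations (closed-form P90 within 3 Monte-Carlo
standard errors; convergence across two decades of n), sensitivity
checks at up to 3×10⁴ draws, and IDW grids up to 25×25 cells; the whole
suite completes in a few seconds.

## Known limitations

* Single contaminant, ingestion only, no hazard-index aggregation.
* Inputs are sampled independently; correlated exposure inputs are not
  supported.
* IDW in geographic degrees is a small-extent approximation; no true
  map projections.
* The distribution-fitting step considers a fixed candidate list and
  unweighted maximum likelihood; no censoring support.
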