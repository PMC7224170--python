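# Methods

This note documents the models, estimators, and numerical choices behind the
package, and what the synthetic-data tests do and do not establish.

## Data model

One record is one polity in one century: nine real-valued Complexity
Characteristics (CCs) in the fixed order `PolPop, PolTerr, CapPop, levels,
gvrnmt, infrastr, writing, texts, money`, plus NGA, polity, signed integer
calendar year (century resolution; −3600 means 3600 BCE), and an Old/New
World flag. The loader rejects missing or non-finite CC cells — upstream
imputation is assumed complete — as well as duplicate (polity, century) keys
and non-integer years. CSV round-trips are exact: values are written with 17
significant digits and read with pandas' `round_trip` float parser.

## PCA

The PCA is of the correlation matrix: each CC is z-scored (sample sd, n−1
denominator) before eigendecomposition, since the CCs are on
incommensurable scales. Scores are projections onto unit eigenvectors, so
score variances equal eigenvalues (PC1 variance ≈ λ₁), which is what gives
the familiar score magnitudes (thresholds near −2.5/−0.5 on the published
table). Loadings are eigenvectors scaled by √λ, i.e. CC–component
correlations, and `loadings @ loadings.T` reconstructs the correlation
matrix to 1e−9. Eigenvector signs are fixed deterministically after the
decomposition: PC1 so that all CCs load positively, PC2 so that writing,
texts, and money load positively, every later component so its
largest-magnitude loading is positive. Exact eigenvalue ties would fall back
to the same rule; they do not occur on real-valued data.

The sinusoid demonstration uses the covariance (non-standardised)
decomposition instead: standardising two variables always yields a 50/50
variance split, which would erase the point the toy makes (PC1 ≈ x carries
~97% of the variance, computed in closed form from var(x) = (t_max−t_min)²/12
and var(sin 2t) ≈ 1/2, while y = sin(2x) exactly).

## Window profile and hinge fit

Window centers lie on the absolute multiples-of-`step` grid (default step
0.5, width 1.0), clipped to the data range, with half-open membership
[c − w/2, c + w/2); with step = width/2 every record falls in exactly two
windows. A `data`-anchored grid is available because the published window
counts could have been produced either way. The standard error is the
sample sd over √n, reported as 0 for singletons; windows below `min_count`
are dropped.

The PC2 decomposition uses raw eigenvector components so that
`info_part + scale_part` equals the PC2 score to machine precision; the
√λ₂-scaled convention is a flag (`scale_convention="loading"`) and differs
only by that constant factor. Window-level curves average record-level
parts, which by linearity makes the window totals identical to the mean-PC2
profile.

Hinge detection fits the continuous basis {1, x, (x−k₁)₊, (x−k₂)₊} by
weighted least squares (weights = window counts by default; inverse squared
SE or none as options) at every admissible knot pair on a 0.05-spaced grid
and keeps the minimum-RSS pair; ties break toward the smaller knots, making
the estimator deterministic. The grid is finer than the one-decimal
precision at which threshold locations are meaningful.

## Trajectories

Trajectories connect temporally consecutive records within an NGA (the
regional view; a per-polity mode exists). Observation gaps must be positive
multiples of 100 years and are filled by linear interpolation at century
spacing, never extrapolating beyond the observed span. Century segments are
assigned to the zone (left of the Scale Threshold / between / right of the
Information Threshold) of their midpoint PC1, boundary ties to the left, and
summarised per zone and hemisphere as mean displacement per century and PC2
dispersion. Occupancy — the fraction of bounding-grid cells ever visited —
quantifies how little of the possible morphospace is used.

## Gaussian mixtures and the bootstrap

EM is implemented in-package (1-D and multivariate, full or diagonal
covariance) because the analysis needs two things library fits do not
expose: per-record likelihood weights (`Σᵢ wᵢ log f(xᵢ)`, BIC with
n = Σwᵢ) and a per-iteration monotonicity guarantee that is asserted in
tests. scikit-learn's `GaussianMixture` serves as an independent
cross-check oracle in the test suite, never as the implementation.
Initialisation is a quantile split of the sorted data plus seeded random
restarts; components are ordered by mean; a variance floor of 1e−6 of the
data variance marks near-singular components as degenerate.

The two-cluster test is a parametric bootstrap of `2(logL₂ − logL₁)`: null
replicates of size n are simulated from the fitted single Gaussian and
p = (1 + #{null ≥ observed})/(B + 1). Observed data and replicates are fit
by the *identical* protocol — quantile split plus one random start, relative
tolerance 1e−5, at most 200 EM steps — which keeps the comparison
exchangeable. The protocol tolerance is looser than `fit_gmm`'s 1e−8
default deliberately: near-degenerate spike solutions make the fully
converged 2-component likelihood drift for thousands of iterations, so the
statistic is defined by the fitting protocol, as is standard for bootstrap
tests. All replicate fits run through one batched EM, which keeps a
199-fit bootstrap under a second and the 200-replicate type-I calibration
around ninety seconds. The package-wide convention for a positive
two-cluster verdict is p ≤ 0.01 at B = 99.

`is_bimodal` counts local maxima of the fitted 2-component density and
requires the secondary peak to reach 10% of the primary's height, so skew,
heavy tails, or a thin shelf component do not count as a second cluster.

## Markov transition model

Transitions are counted over within-unit record pairs exactly one century
apart (pairs separated by longer gaps are excluded — matrix-root inference
is deliberately avoided); zero-count rows become identity rows, and Laplace
smoothing is off by default so hand-counted examples are exact. Entry bins
and times come from each unit's first record, durations from observed
spans; simulation draws entry time and duration independently. Default 15
equal-width bins over the observed PC1 range balance resolution against
sparse counts at a few hundred records.

The **entry-heterogeneity experiment** uses a stylised homogeneous
development chain: slow escape from the low entry bins, rapid transit
through the middle, and a mean-reverting top band whose birth–death rates
are linear in position, giving a smooth binomial-shaped quasi-stationary
law (a geometric-tailed band would make even the control arm leptokurtic
and non-Gaussian). Records are pooled from a trailing observation window at
the horizon: with entry times staggered across three hundred centuries the
window mixes run ages — young runs still near their low entry states, old
runs in the top band — and the pooled values earn a two-cluster verdict;
with a common entry time every run has the same age and the verdict is
negative. Pooling *whole histories* instead would include every run's early
transit regardless of entry time, which is why the window matters: entry
time can only act through the age mixture. The spec-level
`simulate_ensemble` default still pools all records (`record_window=None`).

The **saturation experiment** truncates the chain at a bound and makes the
bound bin absorbing (or reflecting): with upward drift and absorption the
pooled upper mode sits exactly at the bound, which is the premise the
saturation explanation must satisfy; a reflected symmetric walk, whose
stationary law is uniform, is the no-boundary-mode control.

## Undersampling corrections

Within-region interpolation reuses the trajectory interpolator and flags
added records. Density weights are 1/(number of same-NGA records within
`radius` of the record's PC1, inclusive), normalised to sum to n; default
radius 0.5, half the window width. Records at a region's PC1 extremes have
half-empty neighbourhoods and would receive outsize weights on that
geometry alone, so normalised weights are winsorised at 5 by default (the
cap can be disabled, and is disabled in the exact hand-computed tests).

`weighted_bimodality` bootstraps the whole observation design: null
replicates are drawn from the weighted single-Gaussian fit, thinned by the
selection function the weights imply (acceptance ∝ 1/weight at that PC1
position), given interpolated weights, and refit. With uniform weights this
reduces exactly to the unweighted bootstrap.

**Limitation (found empirically, documented deliberately):** a
single-sample procedure cannot distinguish "the gap is a sampling artifact"
from "the gap is real". The design-calibrated bootstrap above conditions on
the selection explanation and is therefore conservative for genuinely
clustered data; conversely an uncalibrated weighted LRT rejects any
non-Gaussian reweighted sample at large n (the 1-vs-2 test is at bottom a
Gaussianity test). The two synthetic controls are therefore read with
complementary instruments: the manufactured-gap control flips from p ≤ 0.01
to p > 0.01 under weighting, while the genuine-cluster control is judged by
the weighted fit retaining two separated density modes. Both controls use a
few hundred records, the regime where reweighting can genuinely restore a
thinned unimodal law below detectability while real clusters stay blatant.

## Synthetic panel generator

Each NGA enters the record at a staggered century drawn from the entry
range, lives 10–40 centuries, and follows a latent development state s with
positive drift 0.25/century and step noise 0.08. CCs respond to s through
fixed per-CC slopes: scale CCs grow at full rate below θ₁ = 3, at
`scale_mid` = 0.3 of it between θ₁ and θ₂ = 6, and at full rate again
above; information CCs are nearly flat below θ₁ (factor `info_lag` = 0.1),
grow steeply between the thresholds (rate 1.6), and plateau above (0.25).
New World NGAs (fraction 0.2, matching six of thirty regions in the real
sample) keep the suppressed information rate throughout and their latent
drift stalls to 15% once s reaches θ₁ — without information capacity there
is little further growth in scale — which confines them to a loose
left-hand cluster. Independent Gaussian observation noise (sd 0.25, about a
tenth of a CC's range) is added per cell. These defaults were chosen once
as a realistic emulation of the panel's structure.

Ground truth ships with every dataset: latent paths, phase labels, and the
generating thresholds, which `GroundTruth.pc1_thresholds` maps onto the
fitted PC1 axis by projecting the noise-free Old-World CC vector at θ₁ and
θ₂ through the fitted model. Full-pipeline recovery of both thresholds is
within ±0.25 PC1 units across seeds at the defaults (asserted at ±0.5).

What the generator does *not* emulate: correlated observation noise across
CCs, polity collapses and within-NGA discontinuities, non-century
resolution, the real panel's missing-century patterns, or any calibration
to the published loadings. Passing tests therefore establish that the
estimators recover the structure they target under a faithful but idealised
mechanism — not that the real data satisfy that mechanism.

## Problem sizes

Defaults used throughout the tests and the acceptance script: a 30-NGA
panel (~700–800 records), 1000-point sinusoid, n = 414 mixture-recovery
samples, 200 chain runs for transition-matrix recovery, 120 runs for the
artifact experiment, B = 99 bootstrap replicates in tests (999 in the
analysis scripts), and 200 seeded replicates of n = 200 for the type-I
calibration. These sizes were chosen as the smallest at which the checked
effects are stable across seeds.
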