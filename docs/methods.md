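# Methods

This note records the models implemented in `seasens`, the defaults that
matter, what the synthetic-data generator does and does not emulate, and the
design choices made where the design was genuinely open.

## Survey data model

An effort unit is a *segment*: a boat recording period (strip half-width
300 m, exact perpendicular distances) or an ~1 km aerial leg (distance
bands, default edges 44/163/282/426 m with the first band starting at the
aircraft's blind-strip inner edge). Each segment carries a midpoint in a
single projected planar CRS (metres), covered area in km², season
(April–September = summer, October–March = winter), distance-to-coast
`cdist` (km, from the midpoint), depth (positive metres below sea level,
nearest-raster-cell lookup) and the set of species its survey recorded.
Surveys that recorded only some species (e.g. auk-only boat surveys)
contribute effort only to analyses of those species, preventing spurious
zeros from deflating other species' densities.

Points that fall on land return `cdist = 0` with a warning rather than an
error; survey positions occasionally digitise just onshore and a hard
failure would be worse than a flagged zero. Depth lookup is nearest-cell
rather than a footprint mean: segments are small relative to the raster and
the simpler rule is directly testable.

## Detection

Candidate key functions are half-normal and hazard-rate only — no
cosine/polynomial adjustment terms — selected by exact minimum AIC with ties
going to the fewer-parameter model. Exact distances maximise the
conditional likelihood f(x) = g(x)/∫₀ʷg; banded counts the multinomial with
cell probabilities ∫band g/∫₀ʷ g. Optimisation is Nelder–Mead on log σ
(and log(b−1), keeping the hazard shoulder integrable) from three starts to
guard against hazard-rate local optima; integrals use 64-point
Gauss–Legendre quadrature (both key functions are smooth, and this agrees
with adaptive quadrature to ~10⁻¹⁰ while being an order of magnitude
faster). The CV of p̄ comes from the observed information via the delta
method; a seeded nonparametric bootstrap is available as a cross-check and
agrees within a few percent.

Pools with n < 50 return an explicit insufficient-sample result. Flying
birds on strip transects are counted with p = 1; sea state ships as a data
column but is not a detection covariate.

A property worth knowing: with two candidate forms and exact min-AIC
selection, the wrong (extra-parameter) form wins in roughly 15% of
replicates when the half-normal is true at n = 500 — the classic 2-units-
per-parameter behaviour of AIC, not an optimiser artefact; inspected
hazard-rate wins occur on draws whose distance histogram is genuinely
shoulder-shaped. The unit suite freezes the simulation-measured rate
(88/100 at its fixed seeds).

## Density surface model

The GAM is authored here rather than wrapped: penalized IRLS with log link,
offset log(covered area), tensor-product P-spline for s(x, y) (cubic
B-splines, second-order difference penalty per direction, ~30 total basis
functions after a sum-to-zero constraint) and a 1-D P-spline for s(cdist)
(k = 10). Smoothing parameters maximise the Laplace REML score via the
generalized Fellner–Schall update with step damping; an optional (default
on) null-space "double" penalty per term lets REML shrink a whole smooth
out of the model, which is how term selection happens. The NB size θ is
profiled by a bounded Brent search on the REML score; the Tweedie
alternative fixes the power at p = 1.5 and estimates the scale by Pearson.
Coordinates are centred internally, so fits are invariant under translation
of (x, y).

On identical data (constant-truth simulation, 200 segments) this
implementation and `mgcv::gam(..., method="REML", family=nb())` agree to
within ~2% on fitted θ, effective degrees of freedom and the predicted
surface; the test suite keeps a 1-D Poisson comparison against mgcv as a
permanent oracle.

Boundary handling deliberately does not reimplement soap-film smoothing,
whose published use needed a retry-and-fall-back loop around knot placement.
The same intent — no smoothing of density across land — is carried by (i)
predicting only on the sea mask, (ii) cdist as a covariate, and (iii)
flagging as extrapolated any cell outside the convex hull of surveyed
midpoints or outside the fitted cdist range. On a peninsula scenario this
marks the far side of a land barrier as unreliable rather than confidently
interpolating across it.

Per-cell CVs use the Bayesian reading of the penalized fit: draw
β* ~ N(β̂, (X'WX + S_λ)⁻¹), form sd/mean of the per-draw densities (500
draws by default), and combine with the detection CV as
√(CV_gam² + cv_p²). Residual spatial autocorrelation is ignored, as is
conventional for these models, so the CVs are lower bounds on the true
uncertainty. Species with a detection fit but data too sparse for a GAM
fall back to coverage-normalised relative density: Σn̂ in a cell over
Σ covered area, with zero-effort cells missing rather than zero.

Covariate screening: VIF per covariate with greedy pruning — while any VIF
exceeds 5 (configurable; the conventional cut), drop the offending covariate
with the lowest single-term explanatory power. This reproduces the
preference for cdist over depth when the two are confounded.

## Sensitivity scoring

The ten factor scores and the banding rules for the four conservation
factors are implemented exactly as specified in the source scoring scheme
(population share, survival, threat status, directive status). Indices are
computed in exact rational arithmetic (`fractions.Fraction`) so that
intermediates like 22.5 are true halves and the half-to-even rounding is
exercised deterministically — float arithmetic would turn 0.5 × 5/3 × 9
into 7.500000000000001 and silently bypass the tie rule.

Risk-class thresholds are not part of the published tables; the defaults
(collision ≥850/410/190/50, displacement ≥20/9/6) sit inside the gaps
between adjacent printed scores so that every published class label
reproduces, and are exposed in configuration. Displacement is structurally
capped at "High" (category 4).

## Mapping

Sitting and flying densities add per cell, with CVs combined under
independence. Platform fusion per cell: drop candidates with CV > 0.5;
take the maximum density if its CV < 0.3, else the lowest-CV candidate;
no survivors → missing. Per-risk maps weight ln(d + 1) by the raw index
scores; the overall map by the categorical value max(collision_cat,
displacement_cat) — a configuration switch allows categorical per-risk maps
as well, since either convention is defensible. Missing species-cells
contribute 0 to the sum; only cells where *no* species had usable data are
flagged `data_ok = False`, and those emit exactly 0 so that zeros in the
output mark data gaps, not measured absence. Fused CVs are carried for
reporting but not recombined after fusion, since no fused-CV definition
exists for the max/lowest-CV selection rule. Seasonal layers written
together share a min/max in metadata so maps render on one scale.

## Synthetic data

The generator emulates: parallel-transect designs for both platforms,
inhomogeneous-Poisson bird placement from a truth surface (exponential
coastal gradient plus Gaussian hotspots, clipped at zero), known detection
thinning, band-binning for aerial data, strip-count flying birds for boat
data, and optionally partial survey coverage. All randomness flows from
one seed through named substreams, so identical configuration gives
byte-identical CSVs.

It does not emulate: bird movement or responsive movement to the platform,
cluster (flock) sizes (groups are size 1 by default; a geometric-size option
exists but ignores size-biased detection), double-observer designs, or
observer-level heterogeneity. Passing tests therefore demonstrate that the
estimators recover what the model assumes, not that those assumptions hold
for any particular field dataset.

The bundled "hotspot scenario" used in the recovery tests is one region of
30 km × 30 km with a straight western coastline, background 8 birds/km²,
coastal gradient e^(−0.04·cdist), one hotspot (+15 birds/km² peak, 6 km
radius), boat transects 1.8 km apart covering the western ~77% of the area,
~260 segments — sized so a full survey-to-map run takes a few seconds while
leaving a genuinely unsurveyed area for the confidence comparison.
Two-region behaviour (a small region modelled separately shows higher CVs)
is reproduced qualitatively in the synthetic two-region test, not
numerically.

## Numerical details and edge cases

- Degenerate detection input (all distances equal) raises a flagged
  non-convergence error rather than returning σ → 0.
- All-zero DSM responses fit cleanly to a ~0 surface.
- Singular posterior covariances are ridge-stabilised with a warning before
  Cholesky draws.
- Fewer unique covariate locations than basis functions shrink the basis
  with a warning.
- Prediction at covariate values beyond the spline support clamps to the
  support edge and is flagged extrapolated; fitting can be given a wider
  domain (e.g. the full grid extent) up front.
- Grid cells are row-major from the lower-left with cell-centre coordinates;
  coastal cells carry their sea-area fraction (≤ 9 km²) as the offset area.

## Known limitations

- CVs exclude spatial autocorrelation and model-selection uncertainty (the
  detection-form choice in particular), so downstream users should read
  them as optimistic.
- The coverage-normalised fallback has no smoothing and inherits raw
  sampling noise per cell.
- The within-sea (land-avoiding) distance metric for the 2-D smooth is not
  implemented; the sea-mask + cdist substitute covers the tested scenarios.
- No geodetic computation: all inputs must already be in one planar CRS.
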