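# Methods

This note documents the models, algorithms and defaults behind the package,
what the synthetic scenes do and do not emulate, and the numerical choices
made where the design was genuinely open.

## Synthetic SMLM scenes

Each scene is a field (default 20 × 20 µm, × 800 nm axially in 3D) holding
`n_agglomerates` nanomaterial clusters plus a homogeneous Poisson background
of unbound label.

**Agglomerate sizes.**  Diameters are lognormal, parameterized by the
arithmetic mean and standard deviation (σ² = ln(1 + (sd/mean)²),
µ = ln(mean) − σ²/2).  The lognormal was chosen over a normal because the
per-coating presets have coefficients of variation up to ~0.42
(uncoated: 765.5 ± 258.2 nm; F127: 1494.0 ± 282.2 nm; PVP: 354 ± 66.48 nm;
AA4040: 6676 ± 2819 nm) and diameters must stay positive.  Centres are
uniform over the sub-region where the whole object fits; an optional
`min_separation` (default off) supports well-separated recovery studies.

**Fluorophores and blinking.**  Each cluster holds 100 fluorophores by
default; each fluorophore's channel is Bernoulli with the cluster's
channel-1 fraction, its position uniform in the cluster ball (or in the
core/secondary-layer region of its channel in shell mode), and its
localization count Geometric(1/`mean_blinks`) with support starting at 1 —
the single-parameter memoryless re-activation model standard in SMLM
simulation (default mean 5).  Every localization is jittered by isotropic
Gaussian precision noise (defaults σ_xy = 20 nm, σ_z = 50 nm, typical
dSTORM values), stamped with a uniform frame in [1, 20 000] and an
Exponential(1000) photon count.  No dark-state kinetics, photobleaching or
frame-correlated blinking is modelled: the downstream analysis never uses
frame structure, so adding it would not exercise any code path.

**Core–shell mode.**  Channel 1 is confined to a core ball (default
diameter 350 nm) and channel 2 to the spherical layer between the core and
the outer diameter (default 600 nm), emulating a tightly bound initial
corona inside a looser exchanged layer.  In shell mode the drawn lognormal
diameter is recorded as the nominal agglomerate size in the ground truth
while the emission geometry uses the configured shell diameters.

**Background.**  Default 0.5 µm⁻² (µm⁻³ in 3D) of uniform localizations
with a fair-coin channel, standing in for the diffuse no-nanomaterial serum
controls.  Background levels in the real controls are not published; this
value gives control scenes that the density filter empties almost entirely,
which is the qualitative behavior the filter is designed for.

**What passing tests show.**  Scenes are idealized: clusters are isotropic,
blinking is uncorrelated, precision is Gaussian and stationary, and there is
no drift, no fiducial error and no multi-emitter fitting artifact.  Recovery
results on these scenes validate the analysis chain's correctness, not its
robustness to reconstruction pathologies.

## Density filter

Keep a localization iff at least `min_neighbors` (default 15) *other*
same-channel localizations lie within `radius` (default 200 nm).  The count
excludes the point itself — "15 molecules within a 200 nm radius" is read as
15 other molecules; both parameters are configurable.  Channels are always
filtered (and clustered) independently.

## DBSCAN and the min-points sweep

DBSCAN semantics are deterministic and documented: a point is core iff its
closed eps-neighborhood (self included) holds ≥ `min_pts` points; clusters
are connected components of the eps-graph over core points; a border point
joins the cluster of its smallest-index core neighbor; ids are renumbered by
ascending minimum member index.  The core partition is order-independent;
the smallest-index rules make the full labeling reproducible.

`eps` is **not** part of the published chain and has no obvious default; we
use 200 nm — the only length scale attached to molecular clustering (the
density-filter radius) — and surface it prominently so nobody relies on it
unknowingly.

The sweep runs DBSCAN at every `min_pts` in 3…100 (grid values below
dimensionality + 1 are dropped with a warning) and keeps the labeling with
the maximal variance-ratio score

  score = [B/(k−1)] / [W/(n−k)]

over non-noise points, where B is the size-weighted between-centroid and W
the within-cluster sum of squares.  This Calinski–Harabasz-type ratio is the
standard operationalization of "inter-cluster variance" validation; k < 2
scores −∞, perfect separation (W = 0) scores +∞, ties break toward the
smallest `min_pts`.  Since the neighbor structure is independent of
`min_pts`, the sweep computes it once and re-labels only when the core set
changes, making the 98-point grid cheap.

**Reliability floor.**  A sweep whose best score falls below a configurable
floor is flagged "no reliable clustering".  The default floor (5 × 10⁴) was
calibrated on background-only control scenes: they score −∞ in almost every
seed, the rare spurious pair of tiny clusters stays below ~1.4 × 10⁴, while
genuine agglomerate scenes score above ~4 × 10⁵ — the floor sits in that gap
with better than 3× margin on both sides.  The flag is advisory; different
geometries may need a different floor.

## Alpha-shape geometry

A cluster's concave hull is the union of Delaunay simplices with
circumradius ≤ α; measures are summed simplex areas/volumes reported in µm²
or µm³ (densities in µm⁻² / µm⁻³, equivalent diameters in nm).  α → ∞
recovers the convex hull exactly.

**Critical ("auto") alpha.**  Auto selects the smallest circumradius in the
triangulation's spectrum at which (a) every input point is a vertex of a
retained simplex, (b) the retained simplices form one facet-connected
region, and (c) the complex has Euler characteristic 1.  Condition (a)
alone — the "encloses all points" default of common alpha-shape tools —
leaves spurious interior holes on uniformly sampled clusters (on 1000
uniform points in a 500 nm disk it underestimates the area by ~35 %); adding
(b) and (c) removes holes while preserving genuine concavity (in 2D the
three conditions are exactly simple connectivity; in 3D, χ = 1 is a
practical proxy for the absence of tunnels and voids).  With this
definition the disk density is recovered within ~5–9 %, and a concave
"C"-shaped fixture keeps less than half its convex-hull area.  The
selection runs as a single incremental pass (union-find over facet
adjacency plus face counting) in the circumradius ordering.

Clusters with fewer than d + 1 points, or degenerate (collinear/coplanar)
ones, are reported with their localization count only, flagged
`valid_geometry = False`, and excluded from per-image medians — assigning
them measure 0 would inject infinite densities into the medians.

## Two-color composition and radial profiles

Channels are clustered independently; cross-channel cluster pairs whose
centroids lie within `match_radius` (default 250 nm, the scale of the
shell-mode outer radius) are merged greedily by ascending distance into
corona objects.  Centroid matching was preferred to hull-overlap tests for
determinism and speed.  An object's channel-1 fraction f = n₁/(n₁+n₂)
classifies it: *initial* if f ≥ purity (default 0.9), *exchanged* if
f ≤ 1 − purity, else *mixed*; the boundary falls to the pure class.
Unmatched clusters become single-channel objects.  Classes partition the
objects by construction.

Radial profiles measure radii from the core-channel centroid and divide
per-shell counts by the annulus/shell measure.  The core diameter estimate
is 2·r₉₀; for uniform-in-ball points it converges to 2R·0.9^(1/d) (≈ 338 nm
for a 350 nm core in 3D), so it is a mild underestimate by construction —
documented rather than corrected, since the correction would assume the
uniform-ball model.  Objects with fewer than 10 core-channel points carry
no estimate.

## Confocal scenes and quantification

Scenes are channel-first float images (cell, corona, reflectance, lysosome;
default 384 × 384 px at 100 nm/px).  Cells are filled disks; reflectance
spots are non-overlapping disks inside cells; the corona channel carries
signal only on spots, scaled by a per-time-point retention factor; lysosome
disks are translated until their pixel-counted overlap with each spot
matches the configured co-localization fraction (analytic lens-area initial
guess, then a sub-pixel grid search; infeasible targets raise).  Gaussian
and optional Poisson noise are applied last; ground-truth masks are
returned pre-noise.

Segmentation uses Otsu thresholds throughout (cell channel + hole filling;
reflectance ∩ cell interior, 8-connected labeling, minimum spot size 4 px):
the published workflow lives in vendor software and is not reproducible
from text, so a parameter-free method keeps the pipeline deterministic; the
threshold function is pluggable.  Blank channels yield empty masks with a
flag.  Co-localization is a binary-mask area fraction (Manders-M1-like), not
an intensity correlation — matching percentage-style co-localization
reporting; an object-count fraction would be a reasonable alternative and is
noted, not implemented.

Spot metrics report the mean corona intensity on spot pixels and a
background-subtracted variant (minus the median corona intensity over
cell-interior off-spot pixels).  The subtraction implements the
background-vs-corona discrimination that restricting measurement to
reflectance spots is meant to achieve; percent-change normalization uses the
subtracted series, so a scene with retention trajectory r_t reproduces the
configured cumulative decrease exactly in the noise-free limit.

**Per-coating presets.**  Cumulative corona-intensity decreases 43.18 %
(uncoated), 61.01 % (PVP), 4.75 % (F127), 0.56 % (AA4040), realized as a
geometric retention trajectory r_i = (1 − D)^(i/(T−1)) over the fixation
times 0, 2, 6, 18, 24 h; lysosome overlap targets 0.40 / 0.42 / 0.583 /
0.601; spot radii derived from the coating's mean internalized agglomerate
diameter (large-agglomerate coatings fit fewer spots per cell).  Spot
rasterization quantizes radii to whole pixels, so the recovered equivalent
diameters track the presets only to the pixel scale (e.g. PVP's 354 nm
agglomerates render at the 3-px minimum radius).

Percent change is Δ%ₜ = 100·(vₜ − vₜ₋₁)/vₜ₋₁ with cumulative decrease
100·(v₀ − v_T)/v₀; the log transform ln(vₜ/vₜ₋₁) = ln(1 + Δ%/100) is
returned alongside and withheld (with an explanatory flag) when a value is
non-positive.  The two-way ANOVA is the classical balanced fixed-effects
decomposition with the interaction tested against the within-cell mean
square; only complete balanced designs with ≥ 2 replicates per cell are
supported, and a zero-variance table is reported as such rather than as
F = 0.

## Pipeline and determinism

`run_pipeline` executes the configured arms from one `RunConfig`, writing
every intermediate artifact (CSV/TSV/JSON) and a manifest with the package
version, seed and a SHA-256 configuration hash.  All randomness flows from
`numpy.random.default_rng` seeded from the run seed (confocal replicates
via `SeedSequence.spawn`), and numeric output uses full repr precision, so
a rerun with the same config and seed reproduces all artifacts byte for
byte.  A failing stage aborts with its name while preserving partial
outputs.

## Problem sizes

Defaults were chosen so a full study runs interactively: SMLM scenes of a
few thousand localizations (clusters of ~500 localizations each), 100-run
recovery studies, confocal time courses of 5 time points × 2–3 replicates
at 384² px.  All sizes scale through the configuration objects.

## Known limitations

* The sweep's score floor, the default eps, and the auto-alpha definition
  are declared package choices, not published values; alternatives are one
  parameter away.
* 3D auto-alpha hulls underestimate ball volumes by ~15 % at n ≈ 2000
  (boundary concavity at the sample scale); 2D recovery is within ~10 %.
* The confocal generator renders one optical section, not a stack, and its
  noise model (Gaussian + optional Poisson) ignores detector gain structure.
* Composition classification assumes comparable detection efficiency in the
  two channels; real fluorophore pairs blink and fit differently, which
  would bias the channel fraction f.
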