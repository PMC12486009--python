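# Methods

This note documents the models, conventions and design choices behind
`trapfair`: what each exposure measure computes, what the synthetic county
does and does not emulate, and the numerical decisions that matter for
reproducing results.

## Exposure measures

All geometry lives in a single projected planar frame in meters; distances
are 2-D Euclidean.  No geodesic computation is performed anywhere, so inputs
in longitude/latitude degrees are rejected (a bounding box fitting inside
±180° × ±90° triggers a hard error instructing projection).

**EJScreen-style traffic proximity.**  The EPA indicator is described in
public documentation as a distance-weighted traffic sum near a point; we
adopt the inverse-distance form Σᵢ AADTᵢ / max(dᵢ, floor) over arterial
segments (principal + minor arterial by default) whose nearest point lies
within `ej_radius` of the unit's polygon centroid.  Conventions:

* `ej_radius` = 500 m; `min_distance_floor` = 1 m bounds the weight when a
  road passes through the centroid.
* A qualifying segment contributes its *full* AADT — proximity is a
  point-distance concept, so no length clipping is applied here.
* The centroid is that of the reporting unit itself at each level.  Public
  EJScreen values are pre-computed from census *block* centroids and
  aggregated upward; with parcel-free synthetic blocks unavailable, the
  reporting-unit centroid is the self-consistent choice, and it reproduces
  the qualitative centroid-aggregation artifact the audit is designed to
  detect.

**AADT density.**  Σᵢ AADTᵢ · ℓᵢⱼ / Aⱼ with ℓᵢⱼ the exact geometric
intersection length of segment i with unit j.  All road classes contribute:
the density is defined as a total-traffic length-weighted sum normalized by
area.  Clipping conserves length across a level's tiling (tested to 1e-6
relative).

**Parcel traffic proximity (reference).**  Each residential parcel is scored
by the sum (default; median available via `parcel_segment_reducer`) of
*truck* AADT over arterial segments within `parcel_radius` = 400 m of the
parcel point.  The unit value is the weighted median of parcel scores with
household-size weights — the smallest score s whose cumulative weight
reaches half the total.  A fraction-of-parcels-near-roads variant
(`parcel_statistic="fraction_near"`) is exposed behind the same interface
because the two readings of "fraction of residential parcels nearby arterial
roadways" versus "median truck traffic near parcels" are genuinely different
statistics; the median-of-truck-AADT form is the default.

**Zero-exposure convention.**  Units with no qualifying roads or no
residential parcels receive exposure 0, not missing: decile transforms
require complete vectors, and dropping units would silently change every
downstream statistic.  `n_parcels_used` records the parcel count per unit so
sensitivity analyses can exclude empty units explicitly.

## Decile transform and agreement statistics

Values are ranked within one geographic level (average ranks under ties) and
binned by ceil(10·rank/n).  This rank-based construction is invariant under
strictly increasing transforms and well defined under heavy ties, which
value-quantile cuts are not; ties were the deciding concern because the
zero-exposure convention can produce many tied zeros.  Deciles are computed
within each level separately — each level's units are ranked among
themselves.

Agreement of a candidate with the parcel reference uses: the fraction of
units within one decile ("good agreement"); unweighted Cohen's κ (the
chance-corrected exact-match rate; a linear-weighted variant would credit
near misses, but unweighted is the conservative default), with κ ≡ 1 when
both raters are constant and identical (p_e = 1 makes the usual formula
0/0); and Kendall's τ-b, the tie-corrected variant, because decile vectors
are heavily tied.  A fully tied vector makes the τ-b denominator vanish; the
function returns NaN with a warning rather than failing, so degenerate
geographies (e.g. zero roads) complete the pipeline.

## Fairness audit

The error of a candidate measure in a unit is its decile minus the parcel
reference decile (an integer in [−9, 9]); the decile scale is the only one
on which the three measures are commensurable.  Errors are regressed on each
covariate by OLS with intercept and classical homoskedastic 95% CIs — no
robust or spatial errors, no multiple-testing adjustment across the 12
(level × measure × covariate) cells; the audit reports unadjusted per-cell
inference.  Covariates are z-scored by default so slopes are decile-error
per covariate standard deviation and comparable across covariates
(`standardize=False` gives raw-scale slopes).  Kendall's τ-b between error
and covariate is reported alongside.

Monte-Carlo checks (seeded, in the test suite and acceptance script) verify
calibration at the analysis scale of n = 222 tract-like units: near-95% CI
coverage under null and injected slopes, unbiased slope recovery to ±0.03,
and sign recovery.

## Synthetic county generator

The generator emulates the *statistical structure* the analysis needs, not
street-level realism:

* **Nested partitions.** ZCTAs are vertical strips, sliced horizontally into
  tracts, each sliced vertically into block groups, with balanced child
  counts: every unit lies in exactly one parent and each level tiles the
  county exactly.  Real ZCTAs do not truly nest in tracts; exact nesting is
  a harmless simplification because each level is analysed independently.
  With one `tracts_per_side_factor` f, tract and ZCTA counts are derived
  (⌈n_bg/f⌉ and ⌈⌈n_bg/f⌉/f⌉), so the default 697 block groups with f = 3
  give 233 tracts and 78 ZCTAs — the block-group count is exact and the
  coarser counts are structurally close to a mixed urban/suburban county's.
* **Roads.** ~10% are long "highway" chords crossing the county (principal
  arterial); the rest are local chords with log-normal lengths (median
  800 m), classed 75% minor arterial / 25% other so the arterial filter is
  exercised and some units have zero nearby arterials.  AADT is log-normal
  (`aadt_log_mean` 10.8, `aadt_log_sd` 1.0, i.e. median ≈ 49,000
  vehicles/day with a heavy tail); truck AADT is AADT times a per-segment
  fraction drawn around `truck_fraction_mean` = 0.1, clamped to [0, 1].
* **Parcels.** A mixture of `parcel_cluster_count` isotropic Gaussian
  clusters (sd `parcel_cluster_sd`), truncated to the county by resampling;
  household sizes are Poisson(`household_size_mean` = 2.4); 90% of parcels
  are residential.
* **Demographics.** Per-unit fraction non-Hispanic Black (Beta(1.5, 5)
  marginal, right-skewed) and a deprivation index (uniform 0–1 score) are
  drawn from a Gaussian copula against the unit's road-length density, with
  latent correlation ρ = 2·sin(π·r/6) so the *Spearman* correlation with
  density is approximately the requested `demographic_road_correlation` r.
  This copula is synthetic-only machinery — a controllable injection knob,
  not a model of real demographic joint distributions.

Defaults describe a county of 33 × 33 km (≈ 1,089 km²) with 697 block
groups, 2,098 road segments and 20,000 parcels — the scale of a mixed
urban/suburban county — and run the full three-level pipeline in roughly
10 s.  Tests and the acceptance script's determinism/round-trip checks use
reduced counties (36–90 block groups, 60–400 segments, 400–4,000 parcels),
which exercise every code path at a fraction of the cost; the calibration
simulations run at the tract count n = 222 they are statements about.

What passing tests on synthetic counties do **not** show: realism of street
topology or routed distances, block-weighted EJScreen aggregation from true
census blocks, spatial autocorrelation of demographics beyond the injected
road-density correlation, or any claim about a particular real county's
numbers.

## Numerical and degenerate-input choices

* Spatial queries go through an STR-tree; candidate segment indices are
  always visited in ascending order so per-unit calls and the batched table
  computation produce bit-identical floating-point sums.
* GeoJSON is written with `repr`-quality floats and demographics CSVs are
  read with round-trip float parsing, so the file-based pipeline reproduces
  in-memory results exactly.
* Weighted median: smallest value whose cumulative weight reaches half the
  total (lower median under unit weights); all-zero weights fall back to
  unit weights.
* Ties in ranks use average ranks everywhere (deciles, Spearman checks).
* Degenerate inputs: zero-area polygons raise geometry errors at
  construction; empty road lists yield zero exposure; units without parcels
  yield zero with `n_parcels_used = 0`; a fully tied decile vector yields
  κ = 1 (if both raters identical) and τ = NaN with a warning; mixed-level
  unit lists and length mismatches raise input errors naming the problem.
* `inject_decile_distortion` integerizes the injected shift by stochastic
  rounding, so the expected decile error equals the target slope exactly
  before clipping to [1, 10]; with noise sd 0.75 the clipping attenuation at
  n = 222 stays within the ±0.03 recovery tolerance.

## Known limitations

* ZCTA-level analyses on small synthetic counties have few units; regression
  CIs there are wide and the audit is underpowered by construction (as it is
  on real ZCTA data).
* The deprivation index is generated at every level independently; in real
  data it is a tract-level product and coarser levels would require
  area-weighted re-aggregation (the reader applies this convention when
  supplying real files).
* EJScreen values computed here are recomputed from roads, not the EPA's
  pre-calculated block-weighted product; comparisons with published EJScreen
  extracts should expect level shifts.
* No spatial-autocorrelation-aware inference; slopes are descriptive
  associations, not causal estimates.
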