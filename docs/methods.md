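# Methods

## The problem and the models

Community care facilities serve elderly residents who reach them on foot,
so the service a community actually enjoys depends on where beds are
relative to where elderly people live. The package measures that service
with per-community accessibility scores in beds per person, under two
model families that share one computational skeleton.

Write *D_k* for the elderly population of demand unit *k*, *S_j* for the
bed count of facility *j*, *d_kj* for the straight-line distance between
the unit's demand point and the facility, and *w(d)* for a distance-weight
kernel. The generic two-step computation is

    R_j = S_j / Σ_k D_k · w(d_kj)        (supply–demand ratio)
    A_i = Σ_j R_j · w(d_ij)              (accessibility score)

* **2SFCA** is the indicator kernel *w(d) = 1{d ≤ d₀}*: step 1 divides each
  facility's beds among everyone within walking radius *d₀*; step 2 credits
  each community with the ratios of the facilities it can reach. Facilities
  and demand interact across administrative boundaries — only distance
  matters.
* **The two-step gravity model** is the power kernel
  *w(d) = max(d, d_min)^(−β)*: the same two searches, with demand and
  supply attenuated continuously by distance instead of cut off.
* **The plain potential model** drops the ratio step entirely:
  *A_i = Σ_j S_j · w(d_ij)*, the classical potential of supply masses.

Setting β = 0 makes the two-step gravity model identical to 2SFCA with an
infinite radius, and replacing the power kernel with the indicator kernel
reproduces 2SFCA exactly; both identities are exercised as tests.

### Assumptions

* Coordinates are planar meters in a projected CRS. At the sub-district
  scale (a few kilometers) straight-line distance stands in for network
  distance; the package performs no geodetic math and no routing.
* The demand point of a polygonal community is its area-weighted centroid,
  substituting for the unknown centroid of the elderly population.
* Bed counts are the sole supply measure; in the gravity models the
  facility "mass" M_j is likewise the bed count, the only supply quantity
  in the data model.
* The catchment boundary is inclusive (d ≤ d₀).

## Parameters

| parameter | units | default | rationale |
|---|---|---|---|
| `d0` (catchment radius) | m | 600 (500 alternative) | observed walking range of elderly pedestrians; 500 m is the conservative variant, and running both radii is part of the standard protocol |
| `beta` (friction coefficient) | — | 1 | the conventional value for walking-scale analyses; 2 makes scores too dispersed to compare |
| `min_distance` | m | 1 | floors distances before exponentiation so a facility coincident with a demand point cannot divide by zero; 1 m is far below any real separation |
| `variant` | — | `two_step` | the procedure described for the gravity run performs two searches and attenuates the supply–demand ratio, which the plain potential lacks; both variants are available |
| `threshold` | beds/person | 0.035 | planning benchmark of 35 beds per 1000 elderly |
| `breaks` (band fractions) | — | 0.10, 0.27, 0.45 | cumulative rank fractions separating the four priority bands |
| `k` (map levels) | — | 6 | equal-interval choropleth convention (5 for the gravity map) |

## Numerical and procedural choices

* **Degenerate catchments.** A facility whose catchment contains no
  positive population gets R_j = 0 — unreachable supply is unusable supply —
  with a warning naming the facility. This choice (rather than an error or
  an infinity) preserves the conservation identity
  Σ_i D_i·A_i = Σ_{served j} S_j exactly, which the tests verify on 200
  random regions for both kernel families.
* **Zero-population communities** participate as score recipients but
  contribute no demand.
* **Equal-interval levels**: width (max−min)/k, level
  floor((s−min)/width)+1 capped at k; an all-equal score vector gets level
  1 everywhere. Levels bin raw scores; no averaging or smoothing is applied
  first.
* **Percentile bands**: units ranked by descending score, ties broken by
  ascending id for determinism; cutoffs are ceilings of the cumulative
  fractions (n = 49 gives band sizes 5/9/9/26). A score of exactly 0 is
  always assigned the bottom band regardless of rank — "top 10%" is
  meaningless for a community with no access at all, and zero scores
  trigger the priority logic.
* **Priority classes**: analyst exclusion → `not_considered`; else zero in
  all runs → `highest`; else combined (best) band 1 → `not_considered`;
  else bands 2/3/4 → `very_low`/`low`/`high`. The band→class map is an
  overridable reconstruction of the narrative rule, not a published
  algorithm. Exclusions are always explicit input.
* **Report rounding**: percentages round to the nearest integer percent,
  half away from zero; raw values are retained alongside.
* **Zero counts under the gravity models.** Power kernels are strictly
  positive, so exact zero scores are impossible while any facility has
  beds; published zero counts under such a model can only be display
  rounding. The package reports raw values and leaves any display
  threshold to the caller.

## The synthetic generator

Real inputs of such a study — community polygons with elderly head counts
from a district government, facility bed records from a planning bureau —
are administrative data that cannot be redistributed. `synthetic.generate_region`
draws regions with the same structure: 49 communities and 32 facilities in
a 4 km × 4 km extent, populations uniform on 200–2000 persons, beds uniform
on 10–80. Those defaults put the aggregate beds-per-person ratio in
[0.001, 0.05] with near certainty (Monte-Carlo-checked), bracketing the
0.002–0.011 mean-score scale characteristic of under-provisioned inner
districts. Facility placement is uniform or clustered near communities;
a configurable fraction of facilities can carry zero beds. Demand
geometries are small squares centered on the demand points — community
polygons only ever enter the math through their centroids, so the squares
exist to exercise the centroid path, not to mimic cadastral shapes.
Attribute distributions are uniform because no distributional information
is available; everything is reproducible from the seed.

What passing tests on these regions show: the algebraic laws
(conservation, homogeneity, kernel equivalences, monotonicity) and the
pipeline's end-to-end behavior hold on data of realistic size and scale.
What they do not show: anything about real street geometry, spatially
correlated demand, or the actual distribution of beds in any city — the
generator has no road network, no density gradient and no correlation
between community size and facility placement.

A fixed collinear fixture (three communities of 100 persons at x = 0, 500,
1000 m; facilities of 10 and 35 beds at x = 250 and 1000 m) provides fully
hand-derivable values: at d₀ = 600 m the ratios are [0.05, 0.175], the
scores [0.05, 0.225, 0.175], and the population-weighted score total is the
45 beds supplied.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run the study-scale
configuration (49 × 32) throughout: conservation on 200 random regions,
oracle (triple-loop) comparisons up to 50 × 50, and a 1000-draw Monte-Carlo
check of the generator's aggregate ratio. These sizes match the setting the
method targets; nothing is scaled down from it.

## Known limitations

* Straight-line distances only; no travel-time or network routing.
* Geometric centroids, not population-weighted centroids.
* No distance decay inside the 2SFCA catchment (that is the enhanced-2SFCA
  family, deliberately out of scope), and no Gaussian/exponential kernels.
* β is taken as given, never calibrated from observed flows.
* Optimal siting of new facilities is not automated; the package ranks
  communities, the planner places facilities.
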