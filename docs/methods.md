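# Methods

`vallescape` implements a spatially explicit ecosystem-service (ES)
capacity/flow assessment and landscape-pattern analysis for the 31 "valli
da pesca" — diked, privately managed sub-basins at the edge of the Venice
lagoon — together with a synthetic scenario generator that stands in for
the private management records and classified imagery such an assessment
consumes. This note documents the models, the parameters that matter, the
generator's assumptions, and the numerical conventions.

## The assessment model

Nine ESs in three CICES categories are quantified per unit, each as a
*capacity* (the ecosystem's potential to deliver the service) and a *flow*
(the amount actually reaching society):

| category | service | capacity indicator | flow indicator |
|---|---|---|---|
| regulating | climate regulation | carbon sequestration, gC m⁻² y⁻¹ | ≡ capacity |
| regulating | water purification | % of N load removed by denitrification | ≡ capacity |
| regulating | lifecycle support | attractiveness index [0–1] | normalized fry + waterbird sum [0–2] |
| provisioning | aquaculture | potential fish biomass, kg ha⁻¹ y⁻¹ | mean fish catch, kg ha⁻¹ y⁻¹ |
| provisioning | waterfowl hunting | IDW huntable-bird density, n ha⁻¹ y⁻¹ | hunting-register catch, n ha⁻¹ y⁻¹ |
| provisioning | wild food | Salicornia biomass + Limonium honey, kg ha⁻¹ y⁻¹ | harvested mass, kg ha⁻¹ y⁻¹ |
| cultural | tourism | attractiveness index [0–1] | tourists, n y⁻¹ |
| cultural | cognitive development | attractiveness index [0–1] | excursionists, n y⁻¹ |
| cultural | birdwatching | attractiveness index [0–1] | birdwatchers, n y⁻¹ |

**Climate regulation** sums habitat area × literature rate over reed
stands, vegetated saltmarshes, and seagrass meadows, incrementing the
seagrass rate by the deposition from micro-calcareous epiphytic seaweeds,
and divides by unit area. Capacity and flow are equivalent for this
service (sequestration happens where and when it benefits society), and
likewise for **water purification**, reported as the percent of the
nitrogen areal load removed by denitrification in the brackish basins.
The rate constants are not unit-specific measurements; they ship as a
fully overridable `RateTable` (reed 250, vegetated saltmarsh 150, seagrass
120 + 30 epiphyte gC m⁻² y⁻¹; N-removal fraction 0.40; Salicornia 0.2 kg
m⁻² y⁻¹; honey 0.5 g m⁻² y⁻¹) — mid-range values for northern-Adriatic
transitional waters.

**Attractiveness indices** (lifecycle support, tourism, cognitive
development, birdwatching capacities) are weighted per-pixel sums of
factor layers, min–max rescaled to [0, 1] over the *whole unit set* so
that the scale is shared across units. The factor sets follow the
declared interests of the respective user groups (e.g. birdwatching:
pedestrian paths, saltmarsh presence, nesting areas, probability of
observing birds); the weights are placeholders standing in for survey
rankings and are configurable.

**Record-based flows** are arithmetic means of yearly values over the
study window (default 2010–2020). Missing years are excluded from the
mean, never zero-filled; a unit with no usable records is flagged NaN and
excluded pairwise downstream. Cultural flows are absolute visitor counts
(n y⁻¹), not per-hectare.

**Hunting capacity** interpolates waterbird census points with inverse
distance weighting (power 2 by default); the surface reproduces point
values exactly at their pixels, and the unit capacity is the surface mean.
**Wild-food capacity** combines Salicornia patches — detected by closed
range-filtering the across-years mean NDVI of a red/NIR stack — with the
sea-lavender honey yield of Limonium-covered saltmarsh, merged by mass
after g→kg conversion.

## Aggregation and normalization

Raw indicators are incommensurable, so each is min–max normalized to
[0, 1] across the 31-unit comparison set; a category aggregate is the
plain (unweighted) sum of its three normalized components, hence in
[0, 3]. Capacity and flow are normalized *independently*, each by its own
min/max — this is what permits a unit's normalized flow to exceed its
normalized capacity, and the per-category **capacity–flow difference**
(capacity − flow) is therefore allowed to be negative, flagging
exploitation beyond the unit's relative potential. A constant indicator
vector normalizes to all zeros (with a warning): absence of between-unit
contrast carries no signal; 0.5 would invent one. Multi-year flows are
averaged first and normalized after.

## Landscape indicators

Eight per-unit indicators describe the land-cover pattern over the 4-class
legend (terrestrial land, saltmarsh, brackish water, freshwater): five
area ratios (water/total, land/total, saltmarsh/total,
freshwater/brackish, land/saltmarsh), the saltmarsh perimeter/area ratio
in km km⁻², and Shannon's landscape diversity H = −Σ pᵢ ln pᵢ and evenness
E = H/ln S. Conventions: natural logs (log₂ available); richness S counts
classes actually present, with E ≡ 0 for a one-class landscape;
zero-denominator ratios are NaN, excluded pairwise, never 0. Perimeters
are raster edge counts — an exposed edge faces another class, nodata, or
the grid boundary (the embankment of a valle is a real boundary) — with
4-connectivity labeling by default (8 by flag). At 25 m resolution a
single saltmarsh pixel has perimeter/area 100 m / 625 m² = 160 km km⁻².

## Group statistics

Comparisons of each indicator across the five management groups (F fish
production, M multiple ESs, H hunting, R recreational, N not managed) are
routed: Shapiro–Wilk on the pooled within-group residuals (the quantity
whose normality ANOVA actually assumes — configurable to per-group
testing) and Bartlett's homoscedasticity test, both at α = 0.05; if both
pass, one-way ANOVA with exploratory Tukey HSD, otherwise Kruskal–Wallis
H on ranks with Dunn's post-hoc test. The Dunn z statistics share the
pooled tie-corrected ranking with the H statistic. The default Dunn
p-value adjustment is "none" (Holm, Bonferroni, Benjamini–Hochberg by
flag, recorded in output metadata). Pairwise results condense into
per-group annotations: for each group, the set of other groups it differs
from at the 95 % confidence level. Trade-offs between the six category
aggregates are screened with a Spearman correlogram (average ranks for
ties, pairwise-complete exclusion, ≥ 4 complete units required per pair).
All tests are two-sided.

## The synthetic scenario generator

The real inputs — classified very-high-resolution imagery, managers'
records, hunting registers, visitor counts — are private. The generator
emulates their statistical structure, conditioned on management group, and
its defaults *are* the study conditions the rest of the package is tested
under.

**Landscapes** are built by quantile-thresholding smoothed Gaussian random
fields: a base field (smoothing length 4 px) splits water from non-water
at the unit's sampled water proportion; a second field splits freshwater
from brackish within water; a third carves saltmarsh out of non-water,
and its smoothing length is the *edge-roughness* control (1 px for groups
M and H — rough, dendritic marsh edges; 3 px elsewhere). Target
proportions are drawn per unit from a Dirichlet around group means
(concentration 300, i.e. a standard deviation of roughly two percentage
points on the water share), and thresholding realizes them to pixel
accuracy. Group means encode the qualitative pattern of the study system:
F water-dominated (water share 0.85), R land-dominated (water 0.35), N
with no freshwater pools at all, M/H intermediate with the largest
saltmarsh shares. An earlier design sketch used multi-class region
growing; quantile-thresholded fields were chosen instead because they hit
the drawn proportions exactly, expose a single roughness parameter, and
are trivially seed-deterministic.

**Records** are truncated-normal yearly draws (cv 0.10) around group
means. Structural absences are enforced, not sampled: N units have no
seeding, catch, or hunting records; the closed-access groups F and H have
zero tourists, excursionists, and birdwatchers. Per-unit level factors
(sd 0.05) are *shared between capacity and flow* within a service family —
the potential-biomass surface and the fish-catch mean scale together, the
census-point values and the hunting catch together, and wild-food harvest
scales with the unit's realized saltmarsh share. This encodes the
mechanism the system actually exhibits (managers calibrate effort to
their unit's potential) and keeps flow aligned with capacity between
units, so that the only units whose provisioning flow exceeds capacity
are the two designated by the `flow_exceeds_capacity_units` flag (legend
ids 22 and 26 by default), whose fish-catch mean is set to twice their
potential-biomass capacity.

**Everything is a pure function of (config, seed)**: per-unit, per-stage
generators are spawned from the master seed through `numpy.SeedSequence`,
so any piece regenerates identically in isolation (the records stage
re-draws the landscape stage's Dirichlet proportions from the same stream
to couple harvests to composition).

What the generator does *not* emulate: real geography and unit shapes
(units are square grids sized from placeholder areas — the true areas of
the private estates are not public), spatial autocorrelation between
neighbouring units, temporal trends or autocorrelation within record
series, imagery artifacts, and classification error. Passing tests
therefore demonstrate that the assessment machinery recovers the patterns
the generator encodes at realistic sample sizes and noise levels — not
that it would recover them from real imagery and registers.

## Numerical choices and problem sizes

* Default pixel size 25 m, matching the derived-raster resolution of the
  assessment this package operationalizes; a 500-ha unit is a ~89×89 grid.
* NDVI intervals are closed on both ends; 0/0 reflectance pixels are
  nodata. Coincident census points with conflicting values are averaged
  with a warning.
* Kruskal–Wallis uses the tie-corrected statistic with a χ²(k−1) p-value;
  all-identical samples are rejected as degenerate rather than returning
  an undefined H.
* The test suite calibrates the engine on 10,000 3-group null simulations
  (rejection rate at α = 0.05 must fall in [0.04, 0.06]) and checks the
  qualitative pattern contracts over 50 generated scenarios; the
  acceptance script uses 25 replicate scenarios for its frequency
  estimates. These sizes keep a full run in tens of seconds while leaving
  the Monte-Carlo error well below the contract margins.
* Pipeline outputs carry `# seed=… config_hash=… version=…` headers and no
  timestamps, so identical (config, seed) runs are byte-identical.

## Known limitations

* Literature rates and survey weights are defaults, not estimates; any
  quantitative conclusion about a real valle requires site-specific
  values.
* The huntable-bird interpolator is plain IDW; no anisotropy, no search
  radius by default, no kriging variance.
* Normalization is defined over the 31-unit set; adding or removing units
  changes every normalized value (inherent to min–max scaling).
* The classification rule maps declared maximized-ES sets to groups; it
  does not infer groups from the records themselves.
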