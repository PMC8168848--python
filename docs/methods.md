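# Methods

## Assessment model

An elicitation table has one row per species × assessor. Confidence that
taxonomic revision is needed is ordinal with four levels (none <
probably not < highly probable < definite); only the top two levels
enter any analysis, which keeps the estimate of hidden diversity
conservative. The predicted outcome of a revision is exactly one of
increase / decrease / species complex (or unrecorded). Research needs
(fieldwork, genetics, morphology, analysis & manuscript) and
conservation benefits (enables assessment, highly localized,
threatening process, high threat probability) are binary, 1 = yes.
A blank conservation or research cell is coerced to 0 — no claimed
benefit, no claimed outstanding step — with a logged warning; a blank
confidence cell is rejected outright because no conservative default
exists for it. `c_enables_assessment` is the one derived default: when
absent or blank it is 1 exactly for predicted increases, since
describing a candidate species is what makes its formal assessment
possible; an explicit cell value always wins.

Species identity is an exact string match after whitespace collapsing,
case-insensitively. No synonym reconciliation against external
registries is attempted.

### Conflict resolution

When assessors disagree on revision need, the disagreement falls into
three categories with deterministic resolutions: (1) morphological
variation contradicted by genetic data → no revision; (2) a
geographically isolated candidate with no genetic data → highly
probable (outcome taken from the record asserting revision); (3) the
candidate was already described → no revision. Research and
conservation flags are merged by field-wise maximum across the records
asserting revision: any assessor flagging a need or benefit keeps it.
Resolution is idempotent — running it on an already-resolved table is
the identity — and concordant duplicates collapse to a single record
under the same field-wise-maximum merge.

## ROI scoring

`ROI = benefit_sum × tax / cost_sum` with `benefit_sum = Σ c1..c4`,
`cost_sum = Σ r1..r4 ≥ 1`, and tax weights 0 / 0.2 / 0.8 / 1.0. A
species with all research steps complete but a revision still pending
is treated as an inconsistent record (error), not as infinite ROI:
analysis and manuscript preparation are always outstanding for an
unfinished revision. ROI is bounded in [0, 4], non-decreasing in each
benefit flag and the tax weight, non-increasing in each cost flag, and
equivariant under uniform scaling of the weight table — properties the
test suite verifies by exhaustive enumeration of all 2⁴ × 2⁴ flag
combinations × 3 weights against an independently coded formula.

The priority rule is `ROI ≥ threshold` with threshold 1.0: the
inclusive comparison is deliberate (a species whose benefits exactly
balance its costs at full certainty is a priority), and the threshold
is configurable. The default scoring cohort is confidence ∈ {highly
probable, definite} AND outcome = increase; a permissive mode admits
any species with a positive tax weight. Ranking ties break
lexicographically by species id for reproducibility.

## Spatial aggregation

Grids are square, in an equal-area metric CRS (default EPSG:3577,
Australian Albers), with the origin snapped down to an integer multiple
of the cell size from the CRS origin so that grids built from different
extents align cell-for-cell. Cells are half-open squares; the extent is
covered by ceiling division. Default cell size is 25 km; island
subgrids (e.g. Lord Howe and Norfolk groups) reuse the same operations
at 1 km on named bounding boxes with ranges clipped to the box.

Occupancy: under the default ANY_INTERSECTION rule a species claims a
cell iff its polygon intersects the cell with strictly positive area —
touching a boundary does not count. A CENTROID rule (cell center inside
the polygon) is available, since published gridding rules are often
unstated. Per-cell layers: richness (species count), sum of scores,
weighted mean (sum / count, NaN where no scored species occurs — a cell
with no species has no mean, and 0 would be a meaningful score), and
the element-wise square root of the mean, which preserves ordering and
damps the influence of a few extreme cells.

Numerical choices: shapely computes intersections; the positive-area
test uses `area > 0` exactly (boundary contacts yield zero-area
geometries). Invalid polygons are repaired with `make_valid` and a
warning; irreparable or empty geometry is an error. No reprojection is
performed — inputs must already be in the grid CRS — and geographic
(degree-unit) CRS identifiers are rejected by a denylist of common
codes rather than true unit introspection, a documented limitation of
operating without a CRS database. Raster output is plain-text: ESRI
ASCII grid and long-format CSV.

## Synthetic data

The generator emulates the statistical composition of a
continent-scale squamate elicitation, so the pipeline is testable
end-to-end without any download. Defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_species | 1,034 | species pool |
| p_assessed | 0.841 | fraction of the pool the panel can assess |
| p_confidence | (.5259, .1500, .2100, .1141) | confidence mix; top two sum to the 32.4% revision rate |
| p_outcome_given_revision | (.800, .041, .159) | increase / decrease / complex |
| p_research | (.50, .46, .70, .97) | per-step need probabilities |
| p_conservation | (.241, .120, .064) | localized / threatening process / high threat |
| p_conflict | 0.031 | discordant-duplicate rate, category mix 21:5:1 |
| range area | lognormal(10.8, 1.6) km² | heavy-tailed; straddles the 20,000 km² threshold |

Where the source statistics constrain only sums, single values were
fixed once: the highly-probable : definite split (≈65:35) is not
published; the outcome mix is normalized over the 270 species with
printed outcomes. `p_research` is derived in closed form from the 26.4%
backlog identity P(f=0)·P(g=0)·P(m ∨ a) = 0.264 with analysis almost
always outstanding (0.97). A single independent-Bernoulli vector cannot
simultaneously match the snake-specific analysis-only share (9/49 ≈
18%, which would roughly double the implied priority rate); the backlog
and priority-count calibration was kept, so group-specific research
combination counts are indicative only.

Randomness uses one root seed with a named substream per component
(assessed, confidence, outcome, research, conservation, conflict,
geometry): adding a component never perturbs the others' draws, and
identical (seed, config) pairs are byte-identical on disk. Revision-
needed species are guaranteed ≥ 1 outstanding step (analysis forced on
when all four draws are 0), so every generated increase passes the
scorer's preconditions.

Conflicted species are chosen *after* final records are drawn, from
species whose final state is a fixed point of the resolution rule
(categories 1/3 on final no-revision species, category 2 on final
highly-probable increases), and are emitted as two discordant rows.
Resolving the generated table therefore reproduces the configured
marginal rates exactly, which is what the parameter-recovery tests
check with exact central 99% binomial intervals at n ≥ 2,000.

Ranges are convex blobs: a uniformly placed point buffered to a
lognormally drawn target area (the buffer radius is corrected for the
128-gon's area deficit, and centers are inset by the radius where the
extent allows, so unconstrained areas match their targets), clipped to
the extent. Species flagged highly localized are forced below
20,000 km² by rejection sampling. What this does **not** emulate:
range-shape realism, spatial richness gradients, biome structure, or
assessor-level reliability differences — so passing spatial tests
demonstrates correct overlay arithmetic, not geographic realism, and
parameter-recovery tests demonstrate calibration of marginals, not of
joint structure (research steps and conservation flags are independent
within species, which real elicitations will not be).

## Problem sizes

Unit and property tests run on grids ≤ 20 × 20 with ≤ 50 species
(brute-force oracle territory) and generated tables of 200–2,000
species; the end-to-end recovery check uses 5,000 species. The
acceptance script runs the worked example and one synthetic elicitation
at the 1,034-species study scale; both finish in seconds.

## Known limitations

* The published row-level assessment table is not redistributable with
  the package; the reproduction test for its headline numbers runs only
  when the user vendors `data/s1_assessments.csv` (see README).
* "Conservation concern" is operationalized as threatening-process OR
  high-threat-probability; the stricter high-threat-only variant is a
  parameter, as the published counts do not pin the rule down.
* Percentage reporting rounds half-up to one decimal; counts are exact
  and percentages always recompute from counts.
* No monetary costing, no uncertainty intervals on ROI, no coastline
  clipping, and no map styling.
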