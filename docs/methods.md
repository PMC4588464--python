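# Methods

This note documents the models, rules and numerical choices behind
`bizscape`, the assumptions they rest on, and what validation against
synthetic registries does and does not establish.

## The registry model

A registry is a set of annual January snapshots of business
establishments. Each establishment carries a stable nine-digit DUNS
identifier, a company and optional trade name, and per-year fields: an
eight-digit SIC code (possibly missing in some active years), sales
volume, employee count, and a flag marking values imputed upstream. A
delivery arrives as partially overlapping tab-delimited files — a wide
establishment file (one row per business, with the most recent name and
address), a long moves file, a first-address file, and per-source geocode
files. Because file naming varies across deliveries, `nets_io` recognizes
files by required-column signature, with an explicit override map for
pathological cases. The dialect implemented here is a logical
reconstruction of the documented content of such deliveries, not a
bit-exact parser for any proprietary layout.

## Address reconciliation

The delivery records a location in up to four roles: `first`,
`most_recent`, and an origin/destination pair per *significant move* — a
relocation in which both the street address and the five-digit zip
changed between years. Expected equivalences (first = origin of move 1;
destination of move k = origin of move k + 1; destination of the last
move = most recent) are checked on a normalized form — uppercased,
punctuation stripped, whitespace collapsed, street suffixes expanded from
an editable table (`data/street_suffixes.csv`) — and logged when
violated, with the moves file treated as authoritative. The
significant-move predicate itself is evaluated on normalized strings:
the raw strings routinely differ in ways ("St." vs "STREET") that do not
constitute a move.

One location-role is assigned to each business-year: the first-address
role until the year before move 1, then the destination of move k from
the move year itself until the year before move k + 1. Taking the move
year at the destination reflects January snapshots (a move recorded for
year y was observed already completed in January of y); the convention is
switchable (`destination_from_move_year=False`).

The first address has no delivery-supplied geocode of its own; when no
provider candidate exists for it either, the candidates of its expected
equivalent (origin of move 1 for movers, most recent address for
non-movers) stand in for it.

## Geocoding

Geocoding engines are modeled as pluggable candidate providers; each
(business, role) has a list of `GeocodeCandidate`s with a source, WGS84
coordinates and a precision level from the scale point > block face >
street segment > block group > tract centroid > zip. Merging keeps the
single candidate of highest source priority — gold-standard local engine
> commercial point service > commercial street-segment service >
delivery-supplied — with a deterministic tie-break (source name, then
coordinate lexicographic order). Block face is placed between point and
street segment on the precision scale; precision levels coarser than
street segment are dropped by the default filter, and block-face matches
are retained as "street level or better".

Merged coordinates are projected to UTM zone 18N on NAD83 (GRS80) — the
local planar system for the New York region, configurable to any
transverse Mercator zone — and rounded to the nearest 10 m per axis,
ties away from zero. The projection is implemented in-package with the
Krueger/Karney exact-conformal series (order n^6); tests verify it
against two independent formulations (Snyder's USGS series and a
numerical meridian-arc integral) to well below the rounding scale. The
10 m rounding makes "same location" an exact equality test, absorbing
both geocoder format differences and sub-parcel jitter.

Out-of-region locations (headquarters listings, moves out of the study
area) are excluded by point-in-polygon against region polygons supplied
as GeoJSON and projected into the same planar frame. Boundary points
count as inside, with a 1 µm numerical tolerance because polygon vertices
round-trip through geographic coordinates.

## Categorization

Categories are defined in an editable YAML file
(`data/categories.yaml`): a roster of 25 mutually exclusive
health-relevant categories spanning the food environment, alcohol
outlets, physical-activity venues, medical facilities and other daily
destinations. The shipped definitions are an illustrative template — the
SIC rosters, name patterns and size thresholds are plausible defaults
that exercise every rule type, clearly marked non-canonical; projects
should substitute definitions vetted for their research question.

A definition fires when the SIC matches (exact eight digits or prefix)
OR a name pattern matches the normalized company/trade name, no exclude
pattern matches, and all present size thresholds hold. Missing size
fields fail a threshold-bearing definition (conservative: absence of
evidence of size is not evidence of size). Mutual exclusivity is
enforced by a unique priority rank — the lowest-ranked match wins — so
size-restricted definitions (large supermarket) rank above the residual
categories they carve out of (convenience/small grocery). Upstream
imputation flags on sales/employees are carried but used as-is by
default, matching how such data are normally consumed.

Across years: the modal SIC represents the business if it covers at
least 75 % of its SIC-reporting years (threshold inclusive at exactly
75 %); otherwise the most recently reported SIC is used, since recent
codes tend to be more specific and more likely corrected. Two documented
choices where the rule is underdetermined: the denominator is years with
a *reported* SIC, not all active years (SIC can be missing;
config-switchable), and ties at the mode resolve toward the most
recently reported of the tied codes. Yearly mode reclassifies each
business-year from that year's own SIC, names and size fields; for a
business with a constant SIC and constant size fields the two modes
provably coincide. The scalar rule (`assign_category`) and the
vectorized frame path used on the hot loop (`assign_frame`) are
semantically identical and cross-checked in tests.

Supporting rules: MET banding of physical-activity venues
(light/moderate for 1.6–5.9 METs, vigorous for ≥ 6; ratings below 1.6
are sedentary and rejected; values in the open gap (5.9, 6.0) — possible
only at finer than the customary one-decimal precision — band as
light/moderate) and the SIC review-sampling rule (review all
establishments when a candidate SIC has fewer than 50 in the reference
year; a 20 % sample, rounded up, for 50–250; a flat 50 above 250; a SIC
enters a definition when at least half the reviewed sample is relevant,
inclusive at exactly half).

## Collapsing, counts and trends

Records in the same category, same year, at the same rounded location
collapse to a single representative — the lexicographically smallest
DUNS id, a documented convention (any deterministic choice works, since
counting only needs group sizes). Cross-category co-locations always
remain distinct: malls and medical office buildings legitimately host
many establishment types. Counts per geography × category × year are
produced both raw and collapsed, with zero cells emitted over the
configured year range so trend fits see complete series. Trends are
simple OLS of count on calendar year per geography × category, computed
closed-form (slope, intercept, slope SE); statsmodels serves as an
independent oracle in the tests.

## The synthetic generator

The generator's role is to provide registries whose right answers are
known, under the documented error conditions of real deliveries. Its
defaults are the reference conditions: 21 snapshots (1990–2010), 10 % of
businesses with at least one significant move (up to eight), 7.7 % of
businesses reporting a deviating SIC in some years, zip-level vendor
geocodes for 31 %/16 %/2 % of businesses active in 1990/2000/2010
falling to 5 %/2 %/1 % after re-geocoding, 3 % of locations outside the
study region, and ~0.5 % base provider failure.

Geography is a synthetic street grid in UTM 18N planar metres: east-west
streets every 200 m, address numbers stepping 10 m, five-digit zip zones
tiling the region in 5 km cells, ten county-like geographies in a 5 × 2
layout. A grid address is exactly invertible to coordinates, which is
what the deterministic mock providers do — so at zero noise the pipeline
must recover every planted location exactly, and does. Both margins of
the significant-move predicate are controllable because street and zip
are independent coordinates of the grid.

Specific modelling choices:

* **Lifespans** are 1 + Geometric(0.12) snapshots (minimum two, censored
  at the window end). The minimum of two snapshots keeps the mover draw a
  clean per-business Bernoulli; real registries contain one-year
  businesses, which this generator does not emulate.
* **SIC churn** is a per-business event (matching how the rate is
  reported: the share of businesses that *ever* changed SIC). A
  churner's deviant years are early years — mirroring the observed drift
  toward more specific codes in later years — and for most churners a
  ≥ 75 % majority survives; for the rest the most-recent-SIC fallback
  still recovers the true code. Category recovery under default churn is
  therefore 100 % by design; recovery degrades only when deviant codes
  reach the most recent year, which tests construct explicitly.
* **Precision drift** is mechanistic: vendors began systematic geocoding
  mid-window, so a business's vendor precision depends on its *last
  observed year* — businesses that closed early keep poor geocodes. The
  documented drift patterns are shares among businesses active in a
  calendar year, i.e. mixtures over death cohorts; the generator inverts
  those targets into per-cohort curves by solving a small linear system
  against its own analytic birth/death process (`_calibrate_cohort_curve`).
  Provider failure is concentrated among the zip-only businesses (poor
  addresses fail everywhere), calibrated the same way against the
  residual-share targets.
* **Co-location clusters** place a fraction of businesses (category-
  dependent: health-practitioner offices and light/moderate activity
  venues are the heaviest suite-sharers) at an existing same-category
  site, with birth years drawn inside the host's active span because the
  documented phenomenon is *concurrent* duplicate records. Name
  perturbation for planted duplicates uses suffix/punctuation edits only,
  preserving the tokens that name rules match.
* Vendor coordinates are never point-level (block face at best, offset
  10–20 m from truth), so a vendor-only pipeline cannot recover exact
  locations — re-geocoding is what restores them, reproducing the
  qualitative early-year undercount when filtering vendor-only data at
  the street-segment floor.

What passing tests on this generator do **not** show: robustness to
free-text address noise beyond suffix/punctuation variation (no USPS-style
standardization is attempted), to non-contiguous activity spells, to
one-year businesses, or to adversarial name drift in categorization; the
synthetic geography is a regular grid, not a calibrated model of any real
region, and count series start near zero in 1990 because the population
accumulates from the window start rather than beginning at a stationary
level.

## Numerical and reproducibility notes

* All randomness flows from a single `numpy` Generator per entry point;
  identical parameters and seed give byte-identical output files.
* Rounding to the 10 m grid uses ties-away-from-zero (Python's built-in
  `round` is banker's rounding, which is direction-unstable across the
  grid).
* OLS slope SE uses the n − 2 residual variance; series need at least two
  distinct years, and an exactly collinear series returns SE 0.
* The acceptance script (`scripts/acceptance.py`) runs two
  10,000-business registries (default and zero-noise conditions) through
  the full pipeline and 500 trend replicates — sizes chosen to keep
  binomial standard errors on the reported percentages below a few tenths
  of a point while the whole run stays at a few minutes on one CPU.
* The 2-SE trend-coverage check is expected near 94 % (normal-theory
  coverage of ±2 SE with 19 degrees of freedom), not exactly 95 %.

## Known limitations

* Real geocoding engines are out of scope; providers are modeled by
  their candidate-list contract and a deterministic mock. Interpolation
  error of street-segment geocoding is represented by a fixed 30 m
  offset, not a model of address-range interpolation.
* The shipped category template is illustrative; results on real data
  are only as good as the definitions supplied.
* Manual review of SIC relevance is supported by the sampling worksheet
  and evaluator, not replaced.
* Density normalization (per area, per capita) is deliberately left to
  the user: the count tables expose raw and collapsed counts to divide
  by any denominator.
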