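# Methods

This note documents the models, parameters and design choices behind
`commaddr`: what each stage computes, why the defaults are what they are,
and what the synthetic fixtures do and do not demonstrate.

## Record model and taxonomy

A surveillance extract is a line list: one row per case or per administered
dose. Vaccination extracts stay dose-level — the same person legitimately
appears once per dose, and no patient deduplication is attempted or
implied. Each record carries a free-text street address, a zip, an
optional affiliation field, and 1..k race fields.

Records partition into four categories, in precedence order:

* **on_community_with_affiliation** / **on_community_without_affiliation**
  — the address resolved to the community, either by geocode + buffer join
  or by confirmed keyword fallback;
* **affiliation_only** — affiliation present but the address is
  off-community, a PO box, blank, or otherwise non-geocodable;
* **unrelated** — neither.

The jurisdiction extract is the union of the first three. The
*times-as-many ratio* is `on_community_total / on_community_with_affiliation`:
by construction every affiliated on-community record is also an address
match, so the ratio is ≥ 1 whenever defined.

An affiliation counts as *present* iff non-empty after trimming and not in
a configurable null-token set (default `{"", "UNKNOWN", "NA", "NONE"}`).
Source systems do not document their null conventions, so this set is
explicitly configuration, not fact. A record is AI/AN iff **any** race
field matches a configured code, case-insensitively — single- and
multi-race selections are treated alike.

## Address standardization

`parse_address` uppercases, strips punctuation, collapses whitespace,
splits a leading digit run into the street number, moves trailing unit
designators (`APT 3`, `# B`, …) aside — reference points are
building-level, so units must not perturb name similarity — and keeps the
first five digits of a 5- or 9-digit zip (anything else ⇒ zip absent; a
missing zip only lowers the match score, it is not fatal). Geocodability
classes: `blank`, `po_box` (conservative start-anchored pattern over
`P O BOX / PO BOX / POB / BOX n`), `numberless`, else `geocodable`. Parsing
never raises; junk degrades the class. The three removed classes are
exactly the complement of the geocoder input (a conservation identity the
pipeline asserts on every run).

Correction rules are data (a JSON array of regex → replacement), applied
in order, each once, then a built-in USPS-style abbreviation table
(STREET→ST, NORTH→N, …) last. Load-time validation rejects non-compiling
patterns and replacements that re-match their own pattern (which would
grow without bound under repetition). `validate_ruleset` tests every rule
against the county street inventory — a rule that also rewrites a
non-community street is flagged — and queues any rewritten address with a
non-community zip for manual review. The shipped rules are illustrative:
each deployment derives its own from its community's non-geocodable
addresses.

## Match score

The composite score is, in points out of 100:

```
score = 60·name_similarity + 25·number_agreement + 15·zip_agreement
name_similarity  = 1 − levenshtein(name, ref_name) / max(len)
number_agreement = 1 if equal else 0
zip_agreement    = 1 exact | 0.5 same 3-digit prefix | 0 otherwise/absent
```

with an inclusive threshold of 85. The weights are pinned by two
requirements: an exact street + number with a wholly wrong zip must score
*exactly* 85 and pass (zip typos with an otherwise correct address are a
documented, recurring pattern and must still match), and a wrong street
number alone must fail (60 + 15 = 75 < 85 — street numbers are matched
binarily against a point layer; there is no interpolation). The formula is
evaluated in points (60/25/15) rather than as 100·(0.60+0.25+0.15)-style
fractions so the 85.0 boundary is exact in floating point. Edit distance
comes from edlib; a dynamic-programming oracle cross-checks it in the
tests.

Ties break deterministically: higher name similarity, then exact zip, then
smallest (number, name, zip) reference key. Only the best candidate is
returned.

### Blocking

Candidates are generated from the union of the query's 5-digit zip block,
3-digit zip-prefix block, and exact street-name token blocks. This is
*complete* for any threshold ≥ `w_name + w_num` (= 85 at the defaults): a
point outside all blocks has zero zip agreement, so reaching 85 would
require name similarity 1.0, i.e. an identical name, which shares every
token. For lower thresholds the geocoder switches to a full scan, so
blocked and unblocked results are always identical — an invariant the
acceptance suite checks against a literal full scan, and a separate unit
test checks against an independent brute-force scorer.

Pairwise name similarities are memoized per index; street names repeat
heavily across address points, which is what makes scanning ~300
candidates per record affordable in pure Python.

## Spatial join

Distances are great-circle (haversine) on a sphere of mean radius
6 371 008.8 m, converted at 0.3048 m/ft. At a 150-ft threshold the
sphere-vs-ellipsoid discrepancy is orders of magnitude below 0.1 ft, and
the spherical model removes all projection/datum configuration. A record
is on-community when its matched point lies within `buffer_feet`
(default 150, **inclusive** — the boundary convention is this package's
decision) of any community point; the nearest point and distance are
always reported either way.

Nearest-neighbor search embeds points on the unit sphere in 3-D and
queries a k-d tree on chord length; chord length is monotone in central
angle, so the tree's nearest neighbor is exactly the haversine nearest
neighbor (distances are converted back via `2R·asin(chord/2)`). The
acceptance suite verifies equivalence against an exhaustive all-pairs
haversine scan on random fixtures up to 10 000 × 1 000 points.

The handful of genuine non-community addresses that sit inside the buffer
are handled by an exclusion list — a persisted CSV of reference keys,
replacing a manual GIS step with reproducible configuration. Excluded
matches are forced off-community and annotated; an exclusion key missing
from the reference is a warning, not an error.

## Keyword fallback

Records the geocoder could not place (below threshold, or numberless) are
scanned for keywords: community-unique street-name tokens or phrases.
Matching is whole-word (token-boundary) — `AGENCY` must flag
`OLD AGENCY RD` but not `REGENCY DR` — and deliberately not fuzzy: a typo
inside the keyword itself routes the record to manual review rather than
risking a false match. A flagged record is confirmed only when its parsed
street number and zip match the *same* community address point (the
stricter of the two readings of "number and zip match"; requiring the
same point prevents cross-street number/zip collages). Flagged but
unconfirmed records become the manual-review queue, sorted by record id,
with the matched keyword and a reason (`no_number`, `number_not_found`,
`zip_mismatch`). Geocode-join and keyword-confirmed match sets are
disjoint by construction.

One scoping note: blank and PO-box records are removed before both
branches, while numberless records — removed from geocoder input — do
enter the keyword branch (they can still be keyword-flagged and reviewed).
Conservation is therefore tracked as
`input = blank + po_box + numberless + geocoded + non_geocoded` with
`keyword_pool = non_geocoded + numberless`; both identities are asserted
at run time.

## Reports

Percentages are decimal half-up at 2 decimals; underlying fractions, not
formatted strings, are the contract. The processing evaluation compares
two runs identical except for standardization: the without-processing
geocoding rate uses all records with a non-blank raw address as its
denominator, the with-processing rate uses the post-removal subset, and
the non-community-zip percentage counts matches whose record zip is
present but outside the community zip set (these are overwhelmingly zip
typos on otherwise-correct addresses, matched at exactly 85).

## Synthetic fixtures

`generate_reference` lays out a fictional street grid near lon −112,
lat 32: community streets clustered at the anchor (rows ~130 m apart,
points ~47 m apart), the non-community grid kilometres east, so every
ordinary non-community point is ≥ 300 ft from the community and the
150-ft buffer is unambiguous. `n_confusable` non-community points are
planted 100–149 ft due north of distinct community points; their keys form
the generated exclusion list. Every community street receives a
historical alias (a genuinely different name, so alias'd addresses cannot
be rescued by edit-distance tolerance) and a paired correction rule; the
keyword set is derived as the street-name tokens unique to community
addresses. Community and non-community name lexicons are disjoint and
entirely fictional.

`generate_extract` allocates exactly `round(n·fraction)` community
residents (positions shuffled by the seeded generator), draws addresses
from the corresponding point pools, and applies **at most one**
perturbation per record, drawn categorically — this keeps the planted
truth crisp and each failure attributable. Default rates, chosen once as
the package's standing study conditions (order-of-magnitude realism for
county surveillance extracts):

| perturbation | rate | effect on the pipeline |
|---|---|---|
| abbreviation variant (RD→ROAD, …) | 0.10 | still matches (similarity ≥ ~0.88); normalized away with processing |
| spelling typo (1 edit) | 0.03 | usually still matches; truth records it |
| street-number typo | 0.01 | unmatchable; keyword-flagged → review queue |
| zip typo (first 3 digits) | 0.012 | matches at exactly 85; counted as non-community-zip |
| historical street alias | 0.02 | fails without rules, recovered by the rule set (`recoverable_by_rules`) |
| PO box substitution | 0.02 | removed pre-geocoder |
| blank address | 0.02 | removed pre-geocoder |
| numberless address | 0.014 | keyword branch, `no_number` review |

plus `affiliation_missing_rate` 0.48 among community residents,
`aian_misclassification_rate` 0.32, and an off-community affiliated
subpopulation of 6% of non-community residents — so that, at the default
10% resident fraction, roughly half of affiliated records are
off-community, matching the observed affiliated-on/off split in real
deployments. Only the historical alias is marked rule-recoverable: under
the 60/25/15 score, one-edit typos and abbreviation variants clear the
threshold even unstandardized, so the alias rules are what drives the
measured with/without-processing gap.

What the generator does **not** model: realistic population geography or
density, disease dynamics, person-level dose clustering, multi-unit
buildings, rural route / highway-contract addressing, or correlated noise
(e.g. one clinic mis-keying many records). Passing tests demonstrate the
pipeline's internal correctness and its behavior under these controlled
noise conditions — not field performance on any real extract.

## Problem sizes and determinism

The test suite exercises fixtures up to 10 000 records × 1 000 reference
points; `scripts/acceptance.py` uses a 1 000-point reference (30%
community, 2 confusables) and a 20 000-record extract, chosen as
comfortably large enough for stable percentages while keeping a full run
in seconds on one core. All randomness flows from explicit integer seeds
through one `numpy` generator per artifact; identical config + seed
reproduce byte-identical outputs (the run-summary hash covers the method
parameters and inputs, deliberately not the output directory).

## Known limitations

* The composite score is this package's transparent reconstruction of a
  proprietary locator score; absolute score values are comparable only
  within this implementation (the 85/75 anchor behaviors are the contract).
* Fallback confirmation requires number and zip on the *same* community
  point; a community with repeated street numbers across zips could in
  principle confirm a wrong-street record — the keyword flag plus number
  plus zip triple makes this vanishingly rare, and such records remain
  auditable in the matched extract.
* No polygon (boundary) join is offered: the method is deliberately
  point-based, which is what lets a jurisdiction share zips and even
  streets with its surroundings.
* Race-field codes, null tokens, keywords, rules and exclusions are all
  deployment-specific configuration; the shipped defaults are starting
  points, not standards.
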