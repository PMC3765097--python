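# Methods

## The screening matrix and its semantics

The central object is a tri-state table: rows are GMO transformation events,
columns are genetic elements (screening targets), and every cell is
*present*, *absent* or *unknown*. Unknown is a first-class state, not
missing data to be imputed: for many events, public documentation simply
does not say whether an element is in the construct, and decision support
must not guess. All operations therefore take an explicit unknown-cell
policy:

- **strict** — an unknown cell never satisfies a requirement (conservative;
  the default for detection/coverage claims and for exclusion queries);
- **permissive** — an unknown cell satisfies any requirement (recall-
  preserving upper bound);
- **flagged / default** — unknowns satisfy requirements but every match is
  annotated with the cells it leaned on (queries), or, in interpretation,
  an unknown neither claims a positive nor excludes on a negative but adds
  a caveat.

Elements live in six sections — promoter, terminator, ORF, miscellaneous,
junction, endogenous. The reference schema has 55/31/103/47/11 GM elements
(247 in total) plus 28 endogenous plant targets. Endogenous targets detect
the species, not the modification, so they are excluded from screening-panel
candidates by default. Element names are canonical; a shipped, editable
synonym table resolves historical aliases (`pE35S` → `p35S`; `pFMV34S`,
`pCmoVb`, `peFMV` → `pFMV`). Canonicalization is idempotent and flags
out-of-vocabulary names instead of raising.

The canonical serialization is UTF-8 TSV: five fixed metadata columns
(trade name, unique id, crop, single/stacked, EU status), then one column
per element headed `section:name`, cells `1`/`0`/empty. Output is
byte-deterministic (stable order, LF endings) so matrices diff cleanly and
round-trip exactly. An Excel importer maps identically laid out workbooks
into the same model; it is a convenience reader, never the canonical format.
Stacked events carry full explicit profiles — no inheritance from parents is
inferred, since published stack rows are authoritative as printed.

## Queries, frequencies, banding

A pattern query is a list of lines; each line maps elements to a required
state. Requirements within a line conjoin (AND), lines union (OR), and
metadata filters conjoin with the whole. Matching is monotone in the
expected directions (adding a line can only widen, adding a requirement to
a line can only narrow; permissive ⊇ strict), and these are property-tested
against a naive per-row scan.

Element frequencies over an event subset use the whole subset as
denominator — unknown cells count in the total, not in the numerator, and
are reported alongside. Percentages are integers, rounded **half away from
zero**; the same convention drives coverage figures (116/126 → 92 %,
25/31 → 81 %, 27/42 → 64 %). Banding: red ≥ 30, orange 10–29, yellow 5–9,
pale yellow 2–4, uncoloured 0–1. The published colour legend overlaps at
exactly 2 % (pale yellow "to 2 %", uncoloured "≤ 2 %"); the partition here
assigns 2 % to pale yellow, preferring the more informative colour.

## Panel design

Coverage is detection semantics: an event is covered when **any** panel
element is present in its profile (groups within a panel are alternative
assays; the union of all group members is what detects). Identification is
deliberately not coverage's job — that is interpretation. Unknown cells do
not cover under the default policy.

Greedy selection repeatedly adds the candidate with maximal marginal
coverage; ties break by higher subset frequency, then lexicographically, so
output is reproducible. Maximum coverage is submodular, so greedy is within
(1 − 1/e) of the optimum; the exhaustive optimizer (`brute_force_optimal_panel`,
guarded to 2·10⁵ combinations) doubles as the oracle that this bound is
met on random instances. Second-round selection ranks assays by
discriminating power — the number of unordered pairs of shortlisted
candidate events the assay separates (present in exactly one of the two;
unknowns separate nothing) — and greedily maximizes newly separated pairs.
Gap analysis flags events that no assay-available element can detect and
ranks unassayed elements by how many events carry them.

## Mixture interpretation

An observed pattern maps tested elements to positive/negative; untested
elements are unconstrained. A single event is consistent when it carries
every positive and none of the negatives. When nothing is consistent, the
pattern may be the union of several products: an *explanation* is a set of
events whose combined present elements cover all positives, **no member**
carrying any tested negative (a truly present element should have fired its
assay; detection-limit caveats are surfaced by the diagnosis, not by
relaxing the logic). Explanations are *minimal* — no proper subset
suffices; since cover is monotone, minimality is equivalent to every member
contributing some unique positive, which is how it is checked.

Enumeration is exact by increasing cardinality up to `max_events`
(default 3) while the subset count stays within `enumeration_limit`
(default 10⁶); past that a greedy cover is returned carrying an explicit
non-exhaustive flag. Ranking is a stable sort on (cardinality ascending,
members with the preferred authorization status descending, aggregate
matrix-wide frequency of the explanation's present elements descending,
lexicographic labels) — fewer and commoner events are likelier findings.
The no-match diagnosis distinguishes the three classic causes: (1) every
positive is attributable to some candidate but no single event carries them
all (mixture); (2) some event fits once a single tested negative is ignored
(possible low-level presence under the assay's detection limit; found by
leave-one-negative-out rescan); (3) a positive occurs in no event profile
(unlisted/unknown GMO; further molecular investigation of the sample is
recommended). An independent checker (`check_explanation`) revalidates any
explanation against the three invariants and is used as the test oracle.

## Verification concordance

qPCR verification of the matrix on certified reference materials is encoded
per (material, assay) cell with a closed ten-code vocabulary. Mapping to
categories: `+`, `-` and `R-` are concordant (the last with an impurity
annotation); `R+` is an impurity-explained false positive; `U+` an
unexplained false positive; `U-` a false negative; `BS` ambiguous; the
trace-level late positives `U(+)` and `(+)` are ambiguous on `t35S` and
unexplained false positives elsewhere. The t35S exception reflects assay
chemistry: the t35S consensus target is ~69 bp and ~78 % A/T-rich, so the
usable assay targets a longer, less specific region whose stray late
signals are a known artefact rather than evidence against the matrix.
`expected_state` inverts the coding into the matrix expectation (all
discordant positive-like codes imply *absent*; `U-` implies *present*), and
classification is consistent with it: a record is concordant exactly when
the observed sign (any signal, including bad signals) matches the
expectation.

The bundled fixture transcribes a 31-material study (530 informative tests
of 806 cells). Four cells required editorial resolution against the study's
printed accounting and are documented in
`src/gmomatrix/data/table1_CHANGELOG.md`; the loader integrity-checks the
tallies (530/492/28/3/4/3) and refuses corrupted data. The derived
"mini-matrix" merges the 26 assay columns into 22 canonical elements (three
p35S assays, two tNOS, two bar; the two epsps assays stay distinct because
they detect different gene variants), verifying that assays of the same
element never disagree on the expectation.

## Synthetic data

The generator emulates the statistical shape of a real screening matrix,
not its biology: element inventory mirroring the reference section
proportions (scaled by `inventory_scale`, default 0.1 ≈ 28 elements);
per-element occurrence frequencies either specified or drawn from
Beta(0.8, 3) — a long-tailed mix of a few common screening targets and many
rare elements, matching how a handful of promoters/terminators dominate
real constructs; single events drawing elements independently; a
`stacking_rate` fraction (default 0.25) of events per crop built as exact
unions of 2–3 singles (no segregation loss); endogenous markers present in
every event of their crop; GM cells masked to unknown at `unknown_rate`
(default 0.02, matching the sparseness of real gaps). Samples derive from a
matrix by taking the union of the true events' present tested targets, with
optional dropout (detection-limit misses) and contamination. Every draw is
fixed by an explicit integer seed; identical specs serialize
byte-identically.

What passing tests show — and do not show. Independence of elements within
synthetic singles ignores the real co-occurrence structure of construct
design (e.g. promoter–gene cassettes travel together), so covering-panel
sizes on synthetic data are not calibrated to real crops; zero-noise
recovery of irredundant mixtures demonstrates the enumeration logic, not
performance under real cross-contamination or allelic assay failure, which
enter only through the explicit dropout/contamination knobs.

## Numerical and procedural choices

- Integer percentages everywhere, rounded half away from zero before
  banding or reporting; one published coverage cell (6/9 printed as 66 %)
  is inconsistent with the convention the other printed pairs obey and is
  treated as a typographical artefact.
- Empty subsets yield defined-empty reports (no division by zero); empty
  panels cover nothing; fewer than two candidates have zero discriminating
  power.
- All tie-breaks are total (frequency, then lexicographic), so every
  operation is deterministic given its inputs.
- Validation reports violations as data (a list of messages), reserving
  exceptions for malformed files and out-of-vocabulary references.

## Problem sizes

The test suite and the acceptance script run on desk-scale draws chosen to
exercise every code path while staying comfortably interactive: round-trip
identity on 200 generated matrices (~10 events × 31 elements), pattern-match
oracle agreement on 100 random queries, mixture enumeration against the
all-subsets oracle on instances with ≤ 15 candidate events, the greedy
panel bound on 50 random 12-event × 8-element instances, 100 zero-noise
mixture-recovery seeds, and generator calibration at 1000 single events
against 99 % binomial bounds.

## Known limitations

- No cost model for assay selection (panel design optimizes coverage and
  discrimination only), and no multiplexing constraints.
- Categorical results only: no Cq-value modelling, LOD estimation or
  amplification-curve QC; quantitative sub-pattern splitting by signal
  strength is left to the analyst via separate query lines.
- Regulatory status is a static label on each event, relabelable per
  jurisdiction but not maintained.
- Stacked events are opaque rows; parental relationships are neither stored
  nor inferred.
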