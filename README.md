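# gmomatrix

Matrix-based decision support for GMO screening analysis.

Routine testing for genetically modified plants in food and feed follows the
*matrix approach*: a first round of element-specific qPCR screening assays
(targeting shared transgene components such as the CaMV 35S promoter `p35S`
or the nopaline synthase terminator `tNOS`), interpreted against a table of
which GMO events carry which genetic elements, shortlists the candidate
events before costly event-specific confirmation. `gmomatrix` implements the
data model and the decision-support operations around such a table for GMO
testing laboratories and enforcement analysts:

- **Tri-state screening matrix** — events × elements with cells
  present / absent / unknown (`1` / `0` / empty), five GM-element sections
  (promoters, terminators, ORFs, miscellaneous, junctions) plus endogenous
  species targets, metadata (trade name, OECD unique identifier, crop,
  single/stacked, EU authorization status), synonym canonicalization
  (`pE35S` → `p35S`), deterministic TSV round-trip and a read-only Excel
  importer.
- **Query engine** — drop-down style metadata filters, AND (within a line) /
  OR (across lines) element-pattern search under explicit unknown-cell
  policies, event comparison, and per-element occurrence frequencies with
  the four-colour banding (red ≥ 30 %, orange 10–29 %, yellow 5–9 %, pale
  yellow 2–4 %).
- **Screening-panel design** — coverage of a panel (an event is covered when
  at least one panel element is present), greedy maximum-coverage selection
  with deterministic tie-breaks, an exhaustive small-instance optimizer,
  second-round target choice by discriminating power (pairs of shortlisted
  candidates separated per assay), and gap analysis for events no available
  assay can detect.
- **Interpretation** — events consistent with an observed positive/negative
  pattern; failing that, *minimal mixtures* of events that jointly explain
  the positives while none carries a tested-negative element (the pattern is
  split into complementary sub-patterns); failing that, a structured
  diagnosis of the three classic causes: a mixture, low-level presence below
  detection limits, or a GMO not listed in the matrix.
- **Verification audit** — coded qPCR outcomes on certified reference
  materials (`+`, `-`, `R+` impurity-explained positive, `U-` false
  negative, `U(+)`/`(+)` late trace signals, `BS` bad signal, `N` untested)
  classified against matrix expectations, with a bundled 31-material /
  26-assay verification study.
- **Synthetic fixtures** — seeded generators for matrices (frequency-skewed
  elements, stacked events as unions, sparse unknowns) and screening samples
  with known ground truth, so every operation is testable offline.

## Worked example

```python
from gmomatrix import (
    ObservedPattern, Panel, coverage, explain_mixture, filter_events,
    load_table1_fixture, rank_explanations, summarize,
)

records, mini = load_table1_fixture()   # bundled verification study
rep = summarize(records)
print(f"{rep.n_total} tests: {rep.n_concordant} concordant "
      f"({rep.pct_concordant}%), {rep.n_discordant} discordant "
      f"({rep.pct_discordant}%)")

# a screening pattern that no single event explains: split it into a mixture
pat = ObservedPattern.from_calls(positives=["p35S", "pFMV", "gox"],
                                 negatives=["bar"])
res = explain_mixture(mini, pat, max_events=2)
for e in rank_explanations(res.explanations, mini,
                           preferred_status="authorized")[:2]:
    print(e.labels())

cov = coverage(mini, Panel.parse("p35S,tNOS"),
               filter_events(mini, crop_species="maize"))
print("p35S+tNOS maize coverage:", cov.fraction_label())
```

prints

```
530 tests: 492 concordant (93%), 38 discordant (7%)
('GT73', 'NK603')
('GT73', 'MON88017')
p35S+tNOS maize coverage: 14/14 - 100%
```

Of the 530 informative verification tests, 492 (93 %) agree with the matrix;
the 38 discordances decompose into 28 false positives explained by GMO
impurities in the reference materials, 3 unexplained trace-level late
positives, 4 ambiguous t35S signals and 3 false negatives. The observed
pattern `p35S+ pFMV+ gox+ bar−` fits no single event, but a two-event
mixture such as the rapeseed event GT73 (`pFMV`, `gox`) with the maize event
NK603 (`p35S`) reproduces it exactly; and the classic `p35S`/`tNOS` duo
still detects all 14 maize events of this (verification-derived) matrix.

A `gmomatrix` CLI mirrors the library (`stats`, `query`, `coverage`,
`select`, `explain`, `verify`, `synth`, `report`); every subcommand emits
JSON or TSV.

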