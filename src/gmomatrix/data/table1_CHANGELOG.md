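# table1_records.tsv — transcription notes

Long-format transcription of a 31-material qPCR verification study (26 assay
columns over promoters/terminators and genes/junctions).  One record per
(material, assay) cell, including untested (`N`) cells; 806 records, of
which 530 are informative.

Cells resolved during transcription so that the category tallies equal the
study's reported totals (530 tests; 492 concordant; 28 impurity-explained
false positives; 3 unexplained late positives on two materials; 4 ambiguous
t35S results; 3 false negatives — one t35S on maize 3272, two p35S on maize
98140):

- **T45, p35S-hsp70**: printed `U-` transcribed as `-`. The study's
  false-negative accounting names exactly three cells (t35S on 3272 and the
  two enhancer-targeting p35S assays on 98140); a fourth `U-` is
  irreconcilable with it.
- **T45, CTP2-cp4epsps**: printed `0` transcribed as `-` (the tables use
  `-` for negatives everywhere else; evident typographical variant).
- **Topas 19/2, pFMV (part A)** and **Topas 19/2, bar, unreferenced assay
  (part B)**: printed `N` transcribed as tested-negative `-` to reach the
  reported total of 530 informative tests. Topas 19/2 is the row with the
  most untested cells, and its sibling line T45 was tested on both assays.

Assay reference tags (`B50`…`B57`, `B39`) identify the published detection
methods distinguishing multiple assays for the same element (three p35S,
two tNOS, two bar); `-` marks assays without a reference tag.
`impurity_source` is filled for impurity-explained results (`R+`, `R-`) and
for trace-level late positives whose impurity was not identified.
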