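# randucla

RAND/UCLA appropriateness statistics for expert consensus panels, plus a
five-criterion instrument for grading moderator (subgroup) analyses of
randomised controlled trials in systematic reviews.

## Who this is for

Methodologists running Delphi-style consensus studies, and systematic
reviewers who need to decide whether a trial's subgroup finding counts as
confirmatory evidence, exploratory evidence, or neither.  Consensus panels
are small (typically 15–21 experts) and rate candidate items on a 9-point
scale (0 = completely inappropriate … 8 = extremely important); the
RAND/UCLA appropriateness method summarizes each item's ratings and detects
genuine panel disagreement, rather than mere spread.

## The statistics

For each item with ratings summarized by median *M* and the 30th/70th
centiles *p30*, *p70* on a scale with midpoint *m* (4 on 0–8):

```
IPR   = p70 − p30                 inter-percentile range
IPRCP = (p30 + p70) / 2           central point of the IPR
AI    = |m − IPRCP|               asymmetry index
IPRAS = IPRr + AI × CFA           disagreement threshold (IPRr = 2.35, CFA = 1.5)
DI    = IPR / IPRAS               disagreement index
```

Disagreement is declared when DI ≥ 1.  The asymmetry correction widens the
threshold when ratings cluster near a scale end, where a given IPR is weaker
evidence of a genuine split; IPRr and CFA are the constants derived
empirically for 9-point scales to reproduce classic RAND disagreement
definitions on panels of any size.  The verdict on the item itself uses the
median alone: *appropriate* if M ≥ 6, *inappropriate* if M < 3, *uncertain*
between.

The moderator instrument encodes five appraisal criteria for a trial's
subgroup analysis — a-priori hypothesis (C1), theory/evidence-driven factor
selection (C2), pre-randomisation measurement (C3), measurement quality
(C4), explicit interaction test (C5).  All five satisfied ⇒ confirmatory;
C3–C5 only ⇒ exploratory; any of C3–C5 failing ⇒ excluded.  C3 admits
not-applicable exceptions (time-invariant factors such as sex; cluster
randomisation with pre-awareness measurement).

## Worked example

Recompute a published two-stage panel summary table (bundled as
`randucla.datasets.moderator_panel_summaries()`):

```python
from randucla import statistics_from_percentiles, check_summary_row
from randucla.datasets import moderator_panel_summaries

for row in moderator_panel_summaries().itertuples():
    s = statistics_from_percentiles(row.item, row.median, row.p30, row.p70)
    flags = check_summary_row(s, row.disagreement_index, row.appropriateness)
    print(row.stage, row.item, s.di_display(), s.appropriateness.value, flags)
```

Selected output:

```
1 1a 0.16 appropriate ()
1 2a 0.85 uncertain ()
1 3a 0.22 uncertain ('category_mismatch',)
2 2 1.09 inappropriate ()
2 3 0.22 appropriate ('di_mismatch',)
2 4 0.0 uncertain ('di_mismatch',)
```

Item 1a's centiles (6, 7) give IPR 1, IPRCP 6.5, AI 2.5, IPRAS 6.10 and so
DI 0.16 — matching the printed index.  Fifteen of the seventeen printed rows
reproduce exactly; the consistency checker flags the two second-stage rows
whose printed indices cannot be derived from their own centiles, and the one
row whose printed verdict contradicts the median rule.  The only
disagreement (DI ≥ 1) is second-stage item 2.

The `examples/` directory holds short narrative scripts for each
capability: analyzing raw ratings, re-analyzing printed summaries, grading
studies, simulating panels, and reconstructing rating multisets from printed
summaries.  A thin CLI wraps the same functions:

```
randucla analyze ratings.csv --out results.csv
randucla from-summaries table.csv --out recomputed.csv
randucla grade appraisals.csv --out grades.csv
randucla simulate profiles.yaml --seed 42 --out generated.csv
```

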