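# Methods

## The appropriateness model

Each item rated by a panel of experts on a bounded integer scale is
summarized by its median and the 30th/70th centiles.  The disagreement
statistics treat the inter-percentile range IPR = p70 − p30 as the evidence
of a split and compare it to an item-specific threshold
IPRAS = IPRr + AI·CFA, where AI = |midpoint − (p30+p70)/2| measures how far
the bulk of ratings sits from the scale centre.  The constants IPRr = 2.35
and CFA = 1.5 are the values derived empirically for 9-point scales to
reproduce classic RAND panel-disagreement definitions while applying to
panels of any size.  The disagreement index DI = IPR/IPRAS is scale-free;
DI ≥ 1 is read as disagreement (only DI < 1 is defined as agreement, so the
boundary counts as disagreement).  Appropriateness is a function of the
median alone — appropriate at or above the upper threshold (6 on 0–8),
inappropriate below the lower (3), uncertain between — and a disagreement
verdict does not demote the category by default; classic-RAND
demotion-to-uncertain is available as `EngineConfig(demote_on_disagreement=True)`.

Assumptions: raters are exchangeable (statistics depend only on the rating
multiset), items are independent, and per-item nonresponse is handled by
per-item deletion — an item's statistics use only its observed ratings, with
no imputation.  Panels below a configurable floor (`min_stable_n`, default 7
responses) are still computed but flagged `unstable`.

## Parameters

| parameter | default | meaning |
|---|---|---|
| scale | 0–8 | integer rating scale; midpoint (min+max)/2 = 4 |
| thresholds | 3, 6 | median cut-points for inappropriate / appropriate |
| `ipr_r` | 2.35 | IPR needed for disagreement under perfect symmetry |
| `cfa` | 1.5 | widening of the threshold per unit of asymmetry |
| `lower_p`, `upper_p` | 0.30, 0.70 | centile pair defining the IPR |
| `quantile_method` | linear_interpolation | see below |
| `display_decimals_di` | 2 | half-up display rounding of DI |
| `min_stable_n` | 7 | response floor below which results are flagged |

## Numerical choices

*Quantile estimator.*  Published summaries of this kind do not state the
estimator.  The default is linear interpolation at position h = (n−1)p + 1
over the sorted ratings (the classic order-statistic convention, identical
to `numpy.quantile(..., method="linear")`); a nearest-rank alternative
x(⌈np⌉) is provided.  The choice is immaterial for summary-mode analysis,
which starts from printed centiles, but affects which raw multisets can
produce a given printed triple.

*Rounding.*  Display rounding is half-away-from-zero (2 decimals for DI, 1
for medians); all intermediate arithmetic keeps full precision, and
rounding is applied only at reporting and when comparing against printed
values.

*Degenerate inputs.*  Empty rating multisets are hard errors; a zero IPR
forces DI = 0 regardless of asymmetry; p30 > p70 is rejected (row-level in
batch summary mode, so one malformed row does not abort a run).

## The consistency checker

Re-running the chain on a printed summary row recovers the printed DI
exactly at 2 decimals whenever the row is internally consistent, which makes
printed tables checkable.  On the bundled two-stage table, fifteen of
seventeen rows reproduce; the two second-stage anomalies (a printed 0.29
where the centiles give 0.22, and centiles (2, 2) — hence DI 0 — printed
with 0.96) are flagged `di_mismatch`, and the first-stage row printing
"Appropriate" with median 5.5 is flagged `category_mismatch` against the
stated median rule.  The checker follows the stated rules, not the printed
exceptions.

## Inverse reconstruction

`find_ratings_matching` searches nondecreasing integer sequences of length n
in lexicographic order, depth-first, pruning a branch as soon as an order
statistic read by the quantile estimator is fixed and violates its target at
printed precision (median 1 dp, centiles 0 dp, optionally DI 2 dp, computed
from the unrounded centiles).  Exhaustion of the search is a proof of
infeasibility.  First-match-in-lexicographic-order makes outputs stable
across runs and platforms.  Notable infeasibility class: a half-integer
median is impossible at odd n (the sample median is then a single integer
order statistic), which is how the seven first-stage rows with .5 medians
betray per-item response counts that differed from the nominal 17.

## Synthetic panels

The generator draws discrete scores i.i.d. from stylised profiles —
`consensus_high` (mass {6: .1, 7: .3, 8: .6}), `consensus_low` (mirrored),
`indifferent` (uniform on {3, 4, 5}), `polarized` (½/½ on the scale
extremes) — with independent per-rater nonresponse and a single explicit
integer seed (no global state).  Default panel size is 17 raters, a typical
first-round size; the polarized example uses 16.  Profiles emulate rating
shape only: no per-rater severity/leniency, no opinion change across
rounds, no item correlation.  Consequently, passing recovery tests show the
chain classifies the designed shapes correctly; they say nothing about
rater-level structure in real panels, which the rater-exchangeable
statistics could not see anyway.

Recovery of designed verdicts is exact for `consensus_high` (support
{6, 7, 8} forces median ≥ 6 and IPR ≤ 2 < IPRAS) and `indifferent` (support
{3, 4, 5} pins the median in the uncertain band).  For `polarized` at 16
raters, the centiles land on the extremes only when each extreme is drawn at
least 6 times, an event of exact probability P(6 ≤ Bin(16, ½) ≤ 10) =
0.7899: that is the method's true sensitivity to an evenly split panel of
this size, rising above 0.95 only near 30 raters.  The recovery experiment
reports the observed fraction over seeded replicates (200 by default).

## Design decisions

- Summary-mode analysis (`statistics_from_percentiles`) is first-class, not
  a fallback: it is the only route available for published tables and is
  estimator-independent.
- The appraisal instrument accepts `unknown` (not reported) as a sixth
  response state, mapped to unsatisfied with its own rationale tag; it never
  waives a requirement.  Not-applicable is accepted only where an exception
  code exists (C3: time-invariant factor, cluster randomisation with
  pre-awareness measurement) and then satisfies the criterion.
- A C2 (theory/evidence) failure can demote a study from confirmatory to
  exploratory but never excludes it; exclusion is reserved for the three
  core criteria (C3–C5).
- Multiple appraisals per study are storable, but no adjudication rule
  between appraisers is imposed.

## Known limitations

- Per-item response denominators for the bundled table are unknowable from
  the published summaries; reconstruction at the nominal panel sizes
  documents, rather than resolves, this.
- The instrument does not extract answers from trial reports; appraisal is
  manual input.
- Inter-rater reliability coefficients, rater weighting, and pooling of
  interaction effects across trials are out of scope.
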