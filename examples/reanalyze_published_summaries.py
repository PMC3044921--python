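"""Recompute disagreement indices from a published panel summary table.

Round reports of RAND/UCLA-style consensus panels print, per item, the
median, the 30th and 70th centiles, a verdict, and a disagreement index.
This example re-runs the statistic chain on the bundled two-stage summary
table and checks every printed index and verdict for internal consistency.
"""

from randucla import check_summary_row, statistics_from_percentiles
from randucla.datasets import moderator_panel_summaries

table = moderator_panel_summaries()
print(f"{'stage':>5} {'item':>4} {'median':>6} {'p30':>3} {'p70':>3} "
      f"{'DI':>5} {'printed':>7}  verdict      flags")
for row in table.itertuples():
    stats = statistics_from_percentiles(
        row.item, row.median, row.p30, row.p70, stage=row.stage
    )
    flags = check_summary_row(
        stats, printed_di=row.disagreement_index,
        printed_appropriateness=row.appropriateness,
    )
    print(f"{row.stage:>5} {row.item:>4} {row.median:>6.1f} {row.p30:>3} {row.p70:>3} "
          f"{stats.di_display():>5.2f} {row.disagreement_index:>7.2f}  "
          f"{stats.appropriateness.value:<12} {';'.join(flags)}")

# The DI column recomputes the printed index from the printed centiles:
# IPR = p70 - p30, IPRAS = 2.35 + 1.5*|4 - (p30+p70)/2|, DI = IPR/IPRAS.
# Two second-stage rows flag di_mismatch (their printed indices cannot be
# derived from their own centiles) and one first-stage row flags
# category_mismatch (printed "Appropriate" with a median below 6).
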