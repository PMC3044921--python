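"""Invert printed summary statistics into concrete rating multisets.

Raw panel ratings are rarely published.  Given a printed (median, p30, p70)
triple and the panel size, the inverse search either reconstructs a rating
multiset that reproduces the triple (and, optionally, the printed
disagreement index) at printed precision, or proves that none exists.
"""

from randucla import ItemRatings, analyze_item, find_ratings_matching
from randucla.datasets import STAGE_PANEL_SIZES, moderator_panel_summaries

table = moderator_panel_summaries()
for row in table.itertuples():
    n = STAGE_PANEL_SIZES[row.stage]
    multiset = find_ratings_matching(
        n, row.median, row.p30, row.p70, target_di=row.disagreement_index
    )
    if multiset is None:
        print(f"stage {row.stage} item {row.item:>2}: no multiset of {n} scores "
              f"can print ({row.median}, {row.p30}, {row.p70}, DI {row.disagreement_index})")
        continue
    stats = analyze_item(ItemRatings(item_id=row.item, ratings=multiset))
    print(f"stage {row.stage} item {row.item:>2}: {multiset} -> "
          f"median {stats.median:.1f}, DI {stats.di_display():.2f}")

# Infeasible rows fall in two classes: half-integer medians with 17 raters
# (an odd-size sample median is a single integer order statistic, so the
# per-item response counts must have differed from 17), and the two
# second-stage rows whose printed disagreement indices cannot be derived
# from their own printed centiles.
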