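"""Generate synthetic panels and measure how often verdicts are recovered.

Draws small expert panels from three stylised response profiles and reports
the fraction of replicates in which the statistic chain reproduces each
profile's designed verdict.
"""

from randucla import PanelProfile, analyze_round, generate_panel, recovery_experiment

profiles = {
    "endorsed": PanelProfile.consensus_high(n_raters=17),
    "middling": PanelProfile.indifferent(n_raters=17),
    "split": PanelProfile.polarized(n_raters=16),
}

generated = generate_panel(list(profiles), profiles, seed=42)
for stats in analyze_round(generated.round):
    print(f"{stats.item_id:>8}: median {stats.median:.1f}, DI {stats.di_display():.2f} "
          f"-> {stats.appropriateness.value}"
          f"{', DISAGREEMENT' if stats.disagreement else ''}")

report = recovery_experiment(
    [profiles["endorsed"], profiles["middling"], profiles["split"]],
    replicates=200, seed=42,
)
for row in report.as_rows():
    print(f"{row['profile']:>15}: recovered {row['matches']}/{row['replicates']} "
          f"({row['recovery_fraction']:.2f})")

# consensus_high and indifferent recover their verdicts in every replicate
# (their score supports force the median into the right band and keep the
# centile range below the disagreement threshold).  The polarized profile is
# detected in ~79% of replicates at 16 raters: a half/half split only puts
# both centiles on the extremes when each extreme is drawn at least 6 times,
# an event with probability P(6 <= Bin(16, 1/2) <= 10) = 0.79.
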