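"""Built-in example data: a published two-stage expert-panel summary table.

The table carries the per-item summary block of a two-stage international
expert consensus on criteria for appraising moderator (subgroup) analyses in
RCTs: 13 candidate criteria rated by 17 panelists in the first stage and 4
additional criteria rated by 15 panelists in the second, each row printing
the median, the 30th and 70th centiles, the appropriateness verdict, and the
disagreement index on the 0-8 scale.  Raw ratings were never published, so
this summary table is the reference input for summary-only analysis, the
consistency checker, and the inverse rating-reconstruction search.

Two second-stage rows are known to be internally inconsistent as printed
(row "3" prints a disagreement index of 0.29 where the centiles give 0.22;
row "4" prints centiles (2, 2), which force an index of 0, alongside 0.96),
and one first-stage row ("3a") prints "Appropriate" for a median of 5.5,
below the stated threshold of 6.  They are retained verbatim: flagging them
is precisely what the consistency checker is for.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = [
    "moderator_panel_summaries",
    "INCONSISTENT_DI_ITEMS",
    "CATEGORY_RULE_EXCEPTIONS",
    "STAGE_PANEL_SIZES",
]

_SUMMARY_CSV = """\
stage,item,median,p30,p70,appropriateness,disagreement_index
1,1a,6.0,6,7,Appropriate,0.16
1,1b,6.5,6,8,Appropriate,0.29
1,2a,4.0,3,5,Uncertain,0.85
1,2b,8.0,7,8,Appropriate,0.13
1,3a,5.5,5,6,Appropriate,0.22
1,3b,4.5,3,6,Uncertain,0.97
1,4a,4.5,3,6,Uncertain,0.97
1,4b,5.0,4,5,Uncertain,0.32
1,5a,6.5,6,8,Appropriate,0.29
1,5b,5.0,3,6,Uncertain,0.97
1,6a,8.0,8,8,Appropriate,0.00
1,6b,4.5,3,6,Uncertain,0.97
1,6c,6.5,5,7,Appropriate,0.37
2,1,6.0,4,7,Appropriate,0.65
2,2,0.0,0,5,Inappropriate,1.09
2,3,6.0,5,6,Appropriate,0.29
2,4,4.0,2,2,Uncertain,0.96
"""

#: (stage, item) pairs whose printed disagreement index cannot be reproduced
#: from their own printed centiles
INCONSISTENT_DI_ITEMS = (("2", "3"), ("2", "4"))

#: (stage, item) pairs whose printed verdict contradicts the median rule
CATEGORY_RULE_EXCEPTIONS = (("1", "3a"),)

#: raters providing usable quantitative data per stage
STAGE_PANEL_SIZES = {"1": 17, "2": 15}


def moderator_panel_summaries() -> pd.DataFrame:
    """The published per-item summary table as a DataFrame.

    Columns: ``stage`` (str), ``item`` (str), ``median`` (float), ``p30``,
    ``p70`` (int), ``appropriateness`` (printed verdict), and
    ``disagreement_index`` (printed, 2 dp).
    """
    df = pd.read_csv(
        io.StringIO(_SUMMARY_CSV),
        dtype={"stage": str, "item": str, "median": float, "p30": int, "p70": int},
    )
    return df
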