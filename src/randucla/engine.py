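"""The RAND/UCLA appropriateness statistic chain and disagreement detection.

For each item rated by an expert panel on a bounded scale, the chain is:

* median and the 30th/70th percentiles of the ratings;
* IPR, the inter-percentile range ``p70 - p30``;
* IPRCP, the central point of that range ``(p30 + p70) / 2``;
* AI, the asymmetry index ``|midpoint - IPRCP|`` — how far the bulk of the
  ratings sits from the centre of the scale;
* IPRAS, the asymmetry-adjusted disagreement threshold
  ``IPRr + AI * CFA`` with the empirically derived nine-point-scale
  constants IPRr = 2.35 and CFA = 1.5;
* the disagreement index DI = IPR / IPRAS, with DI >= 1 read as panel
  disagreement.

The asymmetry correction widens the threshold when ratings cluster near a
scale end, where the same IPR is weaker evidence of a genuine split; on a
perfectly centred spread IPRAS collapses to IPRr.  The appropriateness
verdict uses the median alone: appropriate when it reaches the scale's upper
threshold (6 on 0-8), inappropriate below the lower one (3), uncertain
between.

The chain can start either from a raw rating multiset (:func:`analyze_item`)
or from already-summarized median/centile triples as printed in round
reports (:func:`statistics_from_percentiles`), which also powers the
consistency checker for published tables.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Literal, Sequence

import numpy as np

from .panel import ItemRatings, PanelRound, PanelValidationError, RatingScale

__all__ = [
    "Appropriateness",
    "EngineConfig",
    "ItemStatistics",
    "percentile",
    "median",
    "classify_appropriateness",
    "classify_disagreement",
    "statistics_from_percentiles",
    "analyze_item",
    "analyze_round",
    "check_summary_row",
    "round_half_up",
]


class Appropriateness(str, Enum):
    APPROPRIATE = "appropriate"
    UNCERTAIN = "uncertain"
    INAPPROPRIATE = "inappropriate"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


QuantileMethod = Literal["linear_interpolation", "nearest_rank"]


@dataclass(frozen=True)
class EngineConfig:
    """Tunable constants of the statistic chain.

    ``ipr_r`` and ``cfa`` are the disagreement-threshold constants derived for
    nine-point scales (2.35 and 1.5); ``lower_p``/``upper_p`` select the
    percentile pair (0.30/0.70).  ``min_stable_n`` is the response floor below
    which statistics are still computed but flagged unstable — consensus
    panels are small by design, so a hard error would be unusable.
    """

    ipr_r: float = 2.35
    cfa: float = 1.5
    lower_p: float = 0.30
    upper_p: float = 0.70
    quantile_method: QuantileMethod = "linear_interpolation"
    display_decimals_di: int = 2
    display_decimals_median: int = 1
    min_stable_n: int = 7
    demote_on_disagreement: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.lower_p < self.upper_p < 1):
            raise ValueError("need 0 < lower_p < upper_p < 1")
        if self.ipr_r <= 0:
            raise ValueError("ipr_r must be positive")
        if self.cfa < 0:
            raise ValueError("cfa must be non-negative")
        if self.quantile_method not in ("linear_interpolation", "nearest_rank"):
            raise ValueError(f"unknown quantile method {self.quantile_method!r}")


def round_half_up(value: float, decimals: int) -> float:
    """Round half away from zero (so 0.005 -> 0.01), unlike banker's rounding."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def percentile(
    ratings: Sequence[float],
    p: float,
    method: QuantileMethod = "linear_interpolation",
) -> float:
    """Percentile of a rating multiset.

    ``linear_interpolation`` uses the classic order-statistic convention
    h = (n-1)p + 1 with linear interpolation between x(floor h) and the next
    order statistic.  ``nearest_rank`` returns x(ceil(n*p)) (x(1) at p = 0).
    """
    if len(ratings) == 0:
        raise ValueError("percentile of an empty multiset")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    values = np.sort(np.asarray(ratings, dtype=float))
    if method == "linear_interpolation":
        return float(np.quantile(values, p, method="linear"))
    if method == "nearest_rank":
        n = len(values)
        rank = max(1, math.ceil(n * p))
        return float(values[rank - 1])
    raise ValueError(f"unknown quantile method {method!r}")


def median(ratings: Sequence[float]) -> float:
    """Sample median: middle order statistic, or mean of the middle pair."""
    if len(ratings) == 0:
        raise ValueError("median of an empty multiset")
    return float(np.median(np.asarray(ratings, dtype=float)))


def classify_appropriateness(
    median_rating: float, scale: RatingScale | None = None
) -> Appropriateness:
    """Three-way verdict on the median: >=6 appropriate, <3 inappropriate."""
    scale = scale or RatingScale()
    if not (scale.minimum <= median_rating <= scale.maximum):
        raise ValueError(f"median {median_rating} outside scale")
    if median_rating >= scale.appropriate_threshold:
        return Appropriateness.APPROPRIATE
    if median_rating < scale.inappropriate_threshold:
        return Appropriateness.INAPPROPRIATE
    return Appropriateness.UNCERTAIN


def classify_disagreement(disagreement_index: float) -> bool:
    """True iff the disagreement index reaches 1.0.

    Only DI < 1 is defined as "no disagreement", so the boundary value counts
    as disagreement.
    """
    if disagreement_index < 0:
        raise ValueError("disagreement index cannot be negative")
    return disagreement_index >= 1.0


@dataclass
class ItemStatistics:
    """The full statistic chain for one item, at full precision.

    ``n`` is None in summary-only mode (statistics recomputed from printed
    median/centiles rather than raw ratings).  Display rounding happens only
    in :meth:`as_row` / :meth:`di_display`.
    """

    item_id: str
    median: float
    p30: float
    p70: float
    ipr: float
    iprcp: float
    ai: float
    ipras: float
    disagreement_index: float
    appropriateness: Appropriateness
    disagreement: bool
    n: int | None = None
    stage: str = "1"
    flags: tuple[str, ...] = ()
    config: EngineConfig = field(default_factory=EngineConfig, repr=False)

    @property
    def summary_only(self) -> bool:
        return self.n is None

    def di_display(self) -> float:
        return round_half_up(self.disagreement_index, self.config.display_decimals_di)

    def as_row(self) -> dict:
        """Display-rounded mapping matching the results-table columns."""
        return {
            "item": self.item_id,
            "stage": self.stage,
            "n": self.n if self.n is not None else "",
            "median": round_half_up(self.median, self.config.display_decimals_median),
            "p30": self.p30,
            "p70": self.p70,
            "ipr": self.ipr,
            "iprcp": self.iprcp,
            "ai": self.ai,
            "ipras": round_half_up(self.ipras, 2),
            "disagreement_index": self.di_display(),
            "appropriateness": self.appropriateness.value,
            "disagreement": self.disagreement,
            "flags": ";".join(self.flags),
        }


def _chain(
    item_id: str,
    med: float,
    p30: float,
    p70: float,
    scale: RatingScale,
    config: EngineConfig,
    *,
    n: int | None,
    stage: str,
    flags: tuple[str, ...] = (),
) -> ItemStatistics:
    ipr = p70 - p30
    iprcp = (p30 + p70) / 2.0
    ai = abs(scale.midpoint - iprcp)
    ipras = config.ipr_r + ai * config.cfa
    di = ipr / ipras
    verdict = classify_appropriateness(med, scale)
    disagreement = classify_disagreement(di)
    if config.demote_on_disagreement and disagreement:
        verdict = Appropriateness.UNCERTAIN
    if n is not None and n < config.min_stable_n:
        flags = flags + ("unstable",)
    return ItemStatistics(
        item_id=item_id,
        median=med,
        p30=p30,
        p70=p70,
        ipr=ipr,
        iprcp=iprcp,
        ai=ai,
        ipras=ipras,
        disagreement_index=di,
        appropriateness=verdict,
        disagreement=disagreement,
        n=n,
        stage=stage,
        flags=flags,
        config=config,
    )


def statistics_from_percentiles(
    item_id: str,
    median_rating: float,
    p30: float,
    p70: float,
    scale: RatingScale | None = None,
    config: EngineConfig | None = None,
    *,
    stage: str = "1",
) -> ItemStatistics:
    """Run the chain from already-summarized statistics (summary-only mode).

    This is how published round tables — which print only median and the
    30th/70th centiles per item — are re-analyzed without the raw ratings.
    """
    scale = scale or RatingScale()
    config = config or EngineConfig()
    for name, v in (("median", median_rating), ("p30", p30), ("p70", p70)):
        if not (scale.minimum <= v <= scale.maximum):
            raise ValueError(f"{name} {v} outside scale for item {item_id!r}")
    if p30 > p70:
        raise ValueError(f"item {item_id!r}: p30 {p30} exceeds p70 {p70}")
    return _chain(item_id, median_rating, p30, p70, scale, config, n=None, stage=stage)


def analyze_item(
    item: ItemRatings,
    scale: RatingScale | None = None,
    config: EngineConfig | None = None,
) -> ItemStatistics:
    """Run the full chain on one item's raw rating multiset."""
    scale = scale or item.scale
    config = config or EngineConfig()
    if item.n_responses == 0:
        raise ValueError(f"item {item.item_id!r} has no ratings")
    med = median(item.ratings)
    p30 = percentile(item.ratings, config.lower_p, config.quantile_method)
    p70 = percentile(item.ratings, config.upper_p, config.quantile_method)
    return _chain(
        item.item_id, med, p30, p70, scale, config, n=item.n_responses, stage=item.stage
    )


def analyze_round(
    round_: PanelRound, config: EngineConfig | None = None
) -> list[ItemStatistics]:
    """Per-item statistics for a whole round, input order preserved."""
    config = config or EngineConfig()
    return [analyze_item(item, round_.scale, config) for item in round_]


def check_summary_row(
    stats: ItemStatistics,
    printed_di: float | None = None,
    printed_appropriateness: str | None = None,
) -> tuple[str, ...]:
    """Consistency flags for a recomputed summary row against printed values.

    Returns flags among ``di_mismatch`` (printed disagreement index differs
    from the recomputed one at display precision — with the side condition
    that a zero IPR forces DI = 0, so any nonzero printed DI there is
    internally impossible) and ``category_mismatch`` (printed verdict
    contradicts the median rule).
    """
    flags: list[str] = []
    if printed_di is not None and not (isinstance(printed_di, float) and math.isnan(printed_di)):
        if abs(stats.di_display() - round_half_up(float(printed_di), stats.config.display_decimals_di)) > 1e-9:
            flags.append("di_mismatch")
    if isinstance(printed_appropriateness, str) and printed_appropriateness.strip():
        if printed_appropriateness.strip().lower() != stats.appropriateness.value:
            flags.append("category_mismatch")
    return tuple(flags)
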