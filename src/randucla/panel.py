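"""Domain types for rating panels and the delimited-text formats they travel in.

A consensus round is a set of items, each rated by a small expert panel on a
bounded integer scale (by default 0 = completely inappropriate to
8 = extremely important).  Ratings are kept as per-item multisets: the
appropriateness statistics downstream are rater-exchangeable, and per-item
nonresponse simply shrinks the multiset (no imputation).
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "RatingScale",
    "ItemRatings",
    "PanelRound",
    "DistributionSummary",
    "PanelValidationError",
    "load_ratings",
    "distribution_summary",
    "write_results",
]


class PanelValidationError(ValueError):
    """A rating table or domain object violates a panel invariant."""


@dataclass(frozen=True)
class RatingScale:
    """A bounded integer rating scale with appropriateness thresholds.

    The midpoint anchors the asymmetry index of the disagreement statistics;
    the thresholds drive the three-way appropriateness verdict on the median
    (``median >= appropriate_threshold`` is appropriate,
    ``median < inappropriate_threshold`` inappropriate, uncertain between).
    The default is the nine-point 0-8 scale with midpoint 4 and thresholds
    3 and 6.
    """

    minimum: int = 0
    maximum: int = 8
    inappropriate_threshold: float = 3.0
    appropriate_threshold: float = 6.0

    def __post_init__(self) -> None:
        if self.minimum >= self.maximum:
            raise PanelValidationError(
                f"scale minimum {self.minimum} must be below maximum {self.maximum}"
            )
        if not self.inappropriate_threshold < self.appropriate_threshold:
            raise PanelValidationError(
                "inappropriate_threshold must be below appropriate_threshold "
                f"(got {self.inappropriate_threshold} and {self.appropriate_threshold})"
            )

    @property
    def midpoint(self) -> float:
        return (self.minimum + self.maximum) / 2.0

    @property
    def points(self) -> range:
        """All integer scale points, ascending."""
        return range(self.minimum, self.maximum + 1)

    def check_rating(self, value: float) -> None:
        if not (self.minimum <= value <= self.maximum):
            raise PanelValidationError(
                f"rating {value} outside scale [{self.minimum}, {self.maximum}]"
            )


@dataclass
class ItemRatings:
    """One item's multiset of rater scores.

    ``raters`` is optional parallel bookkeeping (same length as ``ratings``)
    used for duplicate detection on load; statistics never depend on it.
    """

    item_id: str
    ratings: tuple[int, ...]
    stage: str = "1"
    n_raters_invited: int | None = None
    raters: tuple[str, ...] | None = None
    scale: RatingScale = field(default_factory=RatingScale)

    def __post_init__(self) -> None:
        self.ratings = tuple(int(r) for r in self.ratings)
        for r in self.ratings:
            try:
                self.scale.check_rating(r)
            except PanelValidationError as exc:
                raise PanelValidationError(f"item {self.item_id!r}: {exc}") from None
        if self.raters is not None and len(self.raters) != len(self.ratings):
            raise PanelValidationError(
                f"item {self.item_id!r}: {len(self.raters)} rater ids for "
                f"{len(self.ratings)} ratings"
            )
        if self.n_raters_invited is not None and self.n_responses > self.n_raters_invited:
            raise PanelValidationError(
                f"item {self.item_id!r}: {self.n_responses} responses exceed "
                f"{self.n_raters_invited} raters invited"
            )

    @property
    def n_responses(self) -> int:
        return len(self.ratings)


@dataclass
class PanelRound:
    """An ordered collection of items rated in one consensus round."""

    items: list[ItemRatings]
    stage: str = "1"
    scale: RatingScale = field(default_factory=RatingScale)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for item in self.items:
            if item.item_id in seen:
                raise PanelValidationError(f"duplicate item id {item.item_id!r} in round")
            seen.add(item.item_id)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def item(self, item_id: str) -> ItemRatings:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)


@dataclass(frozen=True)
class DistributionSummary:
    """Counts of raters per scale point for one item (a rating histogram)."""

    item_id: str
    counts: Mapping[int, int]

    @property
    def n_responses(self) -> int:
        return sum(self.counts.values())


def distribution_summary(item: ItemRatings) -> DistributionSummary:
    """Tabulate an item's ratings over every scale point (zeros included)."""
    tally = Counter(item.ratings)
    counts = {score: tally.get(score, 0) for score in item.scale.points}
    return DistributionSummary(item_id=item.item_id, counts=counts)


def _is_missing(value) -> bool:
    return pd.isna(value) or (isinstance(value, str) and value.strip() == "")


def _coerce_rating(value, item_id: str, rater: str, scale: RatingScale) -> int:
    try:
        fval = float(value)
        ival = int(fval)
        if ival != fval:
            raise ValueError
    except (TypeError, ValueError):
        raise PanelValidationError(
            f"item {item_id!r}, rater {rater!r}: rating {value!r} is not an integer"
        ) from None
    if not (scale.minimum <= ival <= scale.maximum):
        raise PanelValidationError(
            f"item {item_id!r}, rater {rater!r}: rating {ival} outside scale "
            f"[{scale.minimum}, {scale.maximum}]"
        )
    return ival


def load_ratings(
    path: str | Path,
    *,
    dialect: str = "long",
    stage: str = "1",
    scale: RatingScale | None = None,
) -> PanelRound:
    """Read a ratings CSV into a validated :class:`PanelRound`.

    Two dialects are accepted.  ``"long"`` (canonical) has columns
    ``item, rater, rating``, one row per observed rating.  ``"wide"`` has a
    ``rater`` column plus one column per item.  Blank cells are missing
    responses and are simply absent from the item's multiset.

    Raises
    ------
    PanelValidationError
        On an out-of-scale or non-integer rating (named by item and rater) or
        a duplicated (item, rater) pair.
    """
    scale = scale or RatingScale()
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]

    if dialect == "long":
        required = {"item", "rater", "rating"}
        if not required.issubset(df.columns):
            raise PanelValidationError(
                f"long-form file {path} must have columns item, rater, rating "
                f"(found {list(df.columns)})"
            )
        per_item: dict[str, list[tuple[str, int]]] = {}
        seen_pairs: set[tuple[str, str]] = set()
        for row in df.itertuples(index=False):
            item_id, rater = str(row.item).strip(), str(row.rater).strip()
            if (item_id, rater) in seen_pairs:
                raise PanelValidationError(
                    f"duplicate rating for item {item_id!r} by rater {rater!r}"
                )
            seen_pairs.add((item_id, rater))
            if _is_missing(row.rating):
                per_item.setdefault(item_id, [])
                continue
            rating = _coerce_rating(row.rating, item_id, rater, scale)
            per_item.setdefault(item_id, []).append((rater, rating))
    elif dialect == "wide":
        if "rater" not in df.columns:
            raise PanelValidationError(f"wide-form file {path} must have a rater column")
        item_cols = [c for c in df.columns if c != "rater"]
        raters = [str(r).strip() for r in df["rater"]]
        if len(set(raters)) != len(raters):
            raise PanelValidationError(f"duplicate rater id in wide-form file {path}")
        per_item = {}
        for col in item_cols:
            obs: list[tuple[str, int]] = []
            for rater, value in zip(raters, df[col]):
                if _is_missing(value):
                    continue
                obs.append((rater, _coerce_rating(value, col, rater, scale)))
            per_item[col] = obs
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'long' or 'wide'")

    n_invited = len({r for obs in per_item.values() for r, _ in obs}) or None
    items = [
        ItemRatings(
            item_id=item_id,
            ratings=tuple(r for _, r in sorted(obs)),
            raters=tuple(r for r, _ in sorted(obs)),
            stage=stage,
            n_raters_invited=n_invited,
            scale=scale,
        )
        for item_id, obs in per_item.items()
    ]
    return PanelRound(items=items, stage=stage, scale=scale)


def write_round(round_: PanelRound, path: str | Path) -> None:
    """Write a round back to canonical long-form CSV (round-trips with load)."""
    rows = []
    for item in round_:
        raters = item.raters or tuple(f"r{i+1}" for i in range(item.n_responses))
        for rater, rating in zip(raters, item.ratings):
            rows.append({"item": item.item_id, "rater": rater, "rating": rating})
    pd.DataFrame(rows, columns=["item", "rater", "rating"]).to_csv(path, index=False)


#: column order of the per-item results table
RESULT_COLUMNS = [
    "item",
    "stage",
    "n",
    "median",
    "p30",
    "p70",
    "ipr",
    "iprcp",
    "ai",
    "ipras",
    "disagreement_index",
    "appropriateness",
    "disagreement",
    "flags",
]


def write_results(
    round_results: Iterable,
    path: str | Path,
    *,
    full_precision: bool = False,
) -> None:
    """Serialize computed :class:`~randucla.engine.ItemStatistics` to CSV.

    Numeric columns carry display rounding (median 1 dp, centiles as computed,
    disagreement index 2 dp); ``full_precision=True`` appends unrounded
    companion columns for downstream numeric reuse.
    """
    rows = []
    for stats in round_results:
        row = stats.as_row()
        if full_precision:
            row.update(
                {
                    "median_full": stats.median,
                    "ipr_full": stats.ipr,
                    "ipras_full": stats.ipras,
                    "disagreement_index_full": stats.disagreement_index,
                }
            )
        rows.append(row)
    columns = list(RESULT_COLUMNS)
    if full_precision:
        columns += ["median_full", "ipr_full", "ipras_full", "disagreement_index_full"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
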