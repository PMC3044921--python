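"""Synthetic rating panels and the inverse problem of matching printed summaries.

Consensus-panel raw ratings are rarely published; round reports print only
per-item medians and centiles.  This module closes the gap in two ways:

* :func:`generate_panel` draws small panels of discrete scores from stylised
  response profiles — consensus (mass piled on one end), indifferent (mass in
  the middle), polarized (mass split between the extremes) — with optional
  per-rater nonresponse, so the full analysis pipeline can be exercised under
  known ground truth.
* :func:`find_ratings_matching` inverts a printed (median, p30, p70) triple
  into a concrete rating multiset of given size whose computed statistics
  reproduce the triple at printed precision, or proves no such multiset
  exists under the configured quantile estimator.

Profiles emulate rating *shapes* only (tall-and-thin distributions meaning
agreement, flat or bimodal ones meaning less agreement or a split panel); no
per-rater severity structure is modelled, because the statistics downstream
are rater-exchangeable and could never see it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .engine import (
    Appropriateness,
    EngineConfig,
    ItemStatistics,
    analyze_item,
    round_half_up,
)
from .panel import ItemRatings, PanelRound, RatingScale

__all__ = [
    "PanelProfile",
    "GeneratedRound",
    "RecoveryReport",
    "generate_panel",
    "find_ratings_matching",
    "recovery_experiment",
]


@dataclass(frozen=True)
class PanelProfile:
    """A stylised distribution of panel responses for one item.

    ``score_probabilities`` maps scale points to sampling probabilities;
    ``response_rate`` thins each rater's response independently.  The named
    constructors give the canonical shapes; panels default to 17 raters, a
    typical first-round size for this kind of expert panel.
    """

    name: str
    score_probabilities: Mapping[int, float]
    n_raters: int = 17
    response_rate: float = 1.0

    def __post_init__(self) -> None:
        total = sum(self.score_probabilities.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"profile {self.name!r}: probabilities sum to {total}, not 1")
        if any(p < 0 for p in self.score_probabilities.values()):
            raise ValueError(f"profile {self.name!r}: negative probability")
        if not (0.0 < self.response_rate <= 1.0):
            raise ValueError(f"profile {self.name!r}: response_rate must be in (0, 1]")
        if self.n_raters < 1:
            raise ValueError(f"profile {self.name!r}: need at least one rater")

    @classmethod
    def consensus_high(cls, n_raters: int = 17, response_rate: float = 1.0) -> "PanelProfile":
        """Strong agreement that the item is important: all mass on scores 6-8."""
        return cls("consensus_high", {6: 0.1, 7: 0.3, 8: 0.6}, n_raters, response_rate)

    @classmethod
    def consensus_low(cls, n_raters: int = 17, response_rate: float = 1.0) -> "PanelProfile":
        """Strong agreement that the item is inappropriate: mass on scores 0-2."""
        return cls("consensus_low", {0: 0.6, 1: 0.3, 2: 0.1}, n_raters, response_rate)

    @classmethod
    def indifferent(cls, n_raters: int = 17, response_rate: float = 1.0) -> "PanelProfile":
        """Lukewarm panel: uniform over the middle scores 3-5."""
        third = 1.0 / 3.0
        return cls("indifferent", {3: third, 4: third, 5: third}, n_raters, response_rate)

    @classmethod
    def polarized(cls, n_raters: int = 16, response_rate: float = 1.0) -> "PanelProfile":
        """Split panel: probability half on each extreme score."""
        return cls("polarized", {0: 0.5, 8: 0.5}, n_raters, response_rate)

    @classmethod
    def custom(
        cls,
        score_probabilities: Mapping[int, float],
        n_raters: int = 17,
        response_rate: float = 1.0,
        name: str = "custom",
    ) -> "PanelProfile":
        return cls(name, dict(score_probabilities), n_raters, response_rate)


@dataclass
class GeneratedRound:
    """A generated panel round together with its reproducibility metadata."""

    round: PanelRound
    seed: int
    profiles_used: dict[str, PanelProfile]


def _sample_item(
    item_id: str, profile: PanelProfile, rng: np.random.Generator, scale: RatingScale
) -> ItemRatings:
    scores = np.array(sorted(profile.score_probabilities), dtype=int)
    probs = np.array([profile.score_probabilities[s] for s in scores], dtype=float)
    for s in scores:
        scale.check_rating(int(s))
    draws = rng.choice(scores, size=profile.n_raters, p=probs)
    responded = rng.random(profile.n_raters) < profile.response_rate
    ratings = tuple(int(v) for v in draws[responded])
    return ItemRatings(
        item_id=item_id,
        ratings=ratings,
        n_raters_invited=profile.n_raters,
        scale=scale,
    )


def generate_panel(
    items: int | Sequence[str],
    profiles: PanelProfile | Mapping[str, PanelProfile],
    seed: int,
    *,
    scale: RatingScale | None = None,
    stage: str = "1",
) -> GeneratedRound:
    """Draw one round of panel ratings, deterministic given the seed.

    ``items`` is either a count (item ids ``item1..itemK``) or explicit ids;
    ``profiles`` is one profile for all items or a per-item mapping.
    """
    scale = scale or RatingScale()
    if isinstance(items, int):
        item_ids = [f"item{i + 1}" for i in range(items)]
    else:
        item_ids = list(items)
    if isinstance(profiles, PanelProfile):
        profile_map = {iid: profiles for iid in item_ids}
    else:
        profile_map = {iid: profiles[iid] for iid in item_ids}
    rng = np.random.default_rng(seed)
    rated = [_sample_item(iid, profile_map[iid], rng, scale) for iid in item_ids]
    round_ = PanelRound(items=rated, stage=stage, scale=scale)
    return GeneratedRound(round=round_, seed=seed, profiles_used=profile_map)


# ---------------------------------------------------------------------------
# inverse problem: printed summary triple -> concrete rating multiset


def _order_stat_checks(
    n: int,
    config: EngineConfig,
    scale: RatingScale,
    target_median: float,
    target_p30: float,
    target_p70: float,
    target_di: float | None,
) -> list[tuple[int, callable]]:
    """Constraint checks keyed by the last 0-based order statistic each reads.

    Each check takes the partial sorted sequence and returns True if the
    corresponding printed statistic is reproduced at printed precision
    (median 1 dp, centiles 0 dp, disagreement index 2 dp, half-up rounding).
    """

    def linear_value(x: Sequence[int], p: float) -> float:
        h = (n - 1) * p  # 0-based virtual index, same arithmetic as np.quantile
        lo = math.floor(h)
        frac = h - lo
        if frac < 1e-12:
            return float(x[lo])
        return x[lo] + frac * (x[lo + 1] - x[lo])

    def nearest_value(x: Sequence[int], p: float) -> float:
        rank = max(1, math.ceil(n * p))
        return float(x[rank - 1])

    if config.quantile_method == "linear_interpolation":
        value = linear_value

        def last_index(p: float) -> int:
            h = (n - 1) * p
            return math.floor(h) if (h - math.floor(h)) < 1e-12 else math.floor(h) + 1

    else:
        value = nearest_value

        def last_index(p: float) -> int:
            return max(1, math.ceil(n * p)) - 1

    checks: list[tuple[int, callable]] = []

    for p, target in ((config.lower_p, target_p30), (config.upper_p, target_p70)):
        tgt = round_half_up(target, 0)
        checks.append(
            (last_index(p), lambda x, p=p, t=tgt: round_half_up(value(x, p), 0) == t)
        )

    if target_di is not None:
        # the disagreement index is computed from the *unrounded* centiles,
        # both fixed once the later centile's order statistics are assigned
        tgt_di = round_half_up(target_di, config.display_decimals_di)

        def di_check(x: Sequence[int]) -> bool:
            p30v = value(x, config.lower_p)
            p70v = value(x, config.upper_p)
            ipras = config.ipr_r + abs(scale.midpoint - (p30v + p70v) / 2.0) * config.cfa
            di = (p70v - p30v) / ipras
            return round_half_up(di, config.display_decimals_di) == tgt_di

        checks.append((max(last_index(config.lower_p), last_index(config.upper_p)), di_check))

    med_last = n // 2
    if n % 2 == 1:
        med_fn = lambda x: float(x[n // 2])
    else:
        med_fn = lambda x: (x[n // 2 - 1] + x[n // 2]) / 2.0
    tgt_med = round_half_up(target_median, 1)
    checks.append((med_last, lambda x: round_half_up(med_fn(x), 1) == tgt_med))

    checks.sort(key=lambda c: c[0])
    return checks


def find_ratings_matching(
    n: int,
    target_median: float,
    target_p30: float,
    target_p70: float,
    scale: RatingScale | None = None,
    config: EngineConfig | None = None,
    *,
    target_di: float | None = None,
) -> tuple[int, ...] | None:
    """Find a rating multiset reproducing a printed summary triple, or None.

    Searches nondecreasing integer sequences of length ``n`` over the scale
    in lexicographic order, depth-first, pruning a branch as soon as an order
    statistic the quantile estimator reads is fixed and violates its target
    at printed precision (median to 1 decimal, centiles to integers).  The
    first match is returned, so results are stable across runs.  Returns
    None when no multiset can reproduce the triple under the configured
    estimator — e.g. a median printed below the 30th centile, or a
    half-integer median at odd ``n``, where the sample median is necessarily
    an integer.

    ``target_di`` additionally requires the disagreement index recomputed
    from the multiset's *unrounded* centiles to reproduce a printed index at
    display precision.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    scale = scale or RatingScale()
    config = config or EngineConfig()
    for name, v in (("median", target_median), ("p30", target_p30), ("p70", target_p70)):
        if not (scale.minimum <= v <= scale.maximum):
            raise ValueError(f"target {name} {v} outside scale")
    if not (target_p30 <= target_median <= target_p70):
        return None

    checks = _order_stat_checks(
        n, config, scale, target_median, target_p30, target_p70, target_di
    )
    by_index: dict[int, list] = {}
    for idx, fn in checks:
        by_index.setdefault(idx, []).append(fn)

    lo, hi = scale.minimum, scale.maximum
    x: list[int] = [lo] * n

    def verify(candidate: tuple[int, ...]) -> bool:
        # confirm through the actual statistic chain, not the search's own
        # order-statistic shortcuts
        stats = analyze_item(
            ItemRatings(item_id="candidate", ratings=candidate, scale=scale), scale, config
        )
        ok = (
            round_half_up(stats.median, 1) == round_half_up(target_median, 1)
            and round_half_up(stats.p30, 0) == round_half_up(target_p30, 0)
            and round_half_up(stats.p70, 0) == round_half_up(target_p70, 0)
        )
        if ok and target_di is not None:
            ok = stats.di_display() == round_half_up(target_di, config.display_decimals_di)
        return ok

    def dfs(pos: int, min_val: int) -> bool:
        if pos == n:
            return verify(tuple(x))
        for v in range(min_val, hi + 1):
            x[pos] = v
            if all(fn(x) for fn in by_index.get(pos, ())):
                if dfs(pos + 1, v):
                    return True
        return False

    if dfs(0, lo):
        return tuple(x)
    return None


# ---------------------------------------------------------------------------
# recovery experiments


#: designed engine outcome per named profile: (appropriateness, disagreement)
DESIGNED_OUTCOMES: dict[str, tuple[Appropriateness | None, bool | None]] = {
    "consensus_high": (Appropriateness.APPROPRIATE, False),
    "consensus_low": (Appropriateness.INAPPROPRIATE, False),
    "indifferent": (Appropriateness.UNCERTAIN, None),
    "polarized": (None, True),
}


@dataclass
class RecoveryReport:
    """Fraction of replicates whose verdicts match each profile's design."""

    replicates: int
    seed: int
    fractions: dict[str, float]
    matches: dict[str, int] = field(default_factory=dict)

    def as_rows(self) -> list[dict]:
        return [
            {
                "profile": name,
                "replicates": self.replicates,
                "matches": self.matches.get(name, 0),
                "recovery_fraction": frac,
            }
            for name, frac in self.fractions.items()
        ]


def _matches_design(stats: ItemStatistics, profile: PanelProfile) -> bool:
    expected = DESIGNED_OUTCOMES.get(profile.name)
    if expected is None:
        raise ValueError(
            f"profile {profile.name!r} has no designed outcome; "
            f"known profiles: {sorted(DESIGNED_OUTCOMES)}"
        )
    want_cat, want_dis = expected
    if want_cat is not None and stats.appropriateness is not want_cat:
        return False
    if want_dis is not None and stats.disagreement is not want_dis:
        return False
    return True


def recovery_experiment(
    profiles: Iterable[PanelProfile],
    replicates: int,
    seed: int,
    *,
    scale: RatingScale | None = None,
    config: EngineConfig | None = None,
) -> RecoveryReport:
    """For each profile, how often the engine recovers the designed verdict.

    Each replicate draws a fresh panel from the profile and runs the full
    statistic chain; the report gives, per profile, the fraction of
    replicates whose appropriateness/disagreement verdicts match the
    profile's design (consensus_high -> appropriate without disagreement,
    indifferent -> uncertain, polarized -> disagreement).  Deterministic
    given the seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be at least 1")
    scale = scale or RatingScale()
    config = config or EngineConfig()
    rng = np.random.default_rng(seed)
    fractions: dict[str, float] = {}
    matches: dict[str, int] = {}
    for profile in profiles:
        hit = 0
        for _ in range(replicates):
            item = _sample_item(profile.name, profile, rng, scale)
            if item.n_responses == 0:
                continue
            stats = analyze_item(item, scale, config)
            if _matches_design(stats, profile):
                hit += 1
        matches[profile.name] = hit
        fractions[profile.name] = hit / replicates
    return RecoveryReport(replicates=replicates, seed=seed, fractions=fractions, matches=matches)
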