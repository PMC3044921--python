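"""The appropriateness statistic chain: percentiles, IPRAS, disagreement index."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from randucla import (
    Appropriateness,
    EngineConfig,
    ItemRatings,
    RatingScale,
    analyze_item,
    analyze_round,
    classify_appropriateness,
    classify_disagreement,
    median,
    percentile,
    round_half_up,
    statistics_from_percentiles,
)
from randucla.panel import PanelRound

ratings_strategy = st.lists(st.integers(0, 8), min_size=1, max_size=25)


def oracle_percentile(values, p):
    """Independent sort-and-interpolate reference for the linear estimator."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    h = (n - 1) * p + 1  # 1-based position
    lo = math.floor(h)
    frac = h - lo
    if lo >= n:
        return xs[-1]
    if frac == 0:
        return xs[lo - 1]
    return xs[lo - 1] + frac * (xs[lo] - xs[lo - 1])


class TestPercentile:
    @pytest.mark.parametrize(
        "ratings, p, expected",
        [
            ((4, 4, 4, 4, 4), 0.3, 4.0),
            ((0, 1, 2, 3, 4, 5, 6, 7, 8), 0.5, 4.0),
            # h = (10-1)*0.3 + 1 = 3.7 -> x(3) + 0.7*(x(4)-x(3)) = 2.7
            ((0, 1, 2, 3, 4, 5, 6, 7, 8, 8), 0.3, 2.7),
        ],
    )
    def test_linear_interpolation_hand_values(self, ratings, p, expected):
        assert percentile(ratings, p) == pytest.approx(expected)

    def test_nearest_rank(self):
        xs = (0, 1, 2, 3, 4, 5, 6, 7, 8, 8)
        assert percentile(xs, 0.3, "nearest_rank") == 2.0  # x(ceil(3)) = x(3)
        assert percentile(xs, 0.0, "nearest_rank") == 0.0  # x(1) at p=0
        assert percentile(xs, 1.0, "nearest_rank") == 8.0

    def test_empty_multiset_rejected(self):
        with pytest.raises(ValueError):
            percentile((), 0.3)

    @settings(max_examples=200, derandomize=True)
    @given(ratings=ratings_strategy, p=st.floats(0, 1, allow_nan=False))
    def test_matches_independent_oracle_and_stays_in_range(self, ratings, p):
        value = percentile(ratings, p)
        assert value == pytest.approx(oracle_percentile(ratings, p), abs=1e-9)
        assert min(ratings) <= value <= max(ratings)


class TestMedian:
    @pytest.mark.parametrize(
        "ratings, expected",
        [((8, 8, 8), 8.0), ((6, 7), 6.5), ((0, 0, 8, 8), 4.0)],
    )
    def test_hand_values(self, ratings, expected):
        assert median(ratings) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median(())


class TestClassification:
    @pytest.mark.parametrize(
        "med, expected",
        [
            (8.0, Appropriateness.APPROPRIATE),
            (6.0, Appropriateness.APPROPRIATE),
            (5.5, Appropriateness.UNCERTAIN),
            (4.0, Appropriateness.UNCERTAIN),
            (3.0, Appropriateness.UNCERTAIN),
            (2.9, Appropriateness.INAPPROPRIATE),
            (0.0, Appropriateness.INAPPROPRIATE),
        ],
    )
    def test_median_thresholds(self, med, expected):
        assert classify_appropriateness(med) is expected

    @pytest.mark.parametrize(
        "di, expected", [(1.09, True), (1.0, True), (0.97, False), (0.0, False)]
    )
    def test_disagreement_boundary(self, di, expected):
        # only DI < 1 is defined as agreement, so exactly 1.0 is disagreement
        assert classify_disagreement(di) is expected

    def test_negative_index_rejected(self):
        with pytest.raises(ValueError):
            classify_disagreement(-0.1)


class TestStatisticsFromPercentiles:
    @pytest.mark.parametrize(
        "item_id, med, p30, p70, di_2dp, verdict",
        [
            ("1a", 6.0, 6, 7, 0.16, Appropriateness.APPROPRIATE),
            ("2a", 4.0, 3, 5, 0.85, Appropriateness.UNCERTAIN),
            ("6a", 8.0, 8, 8, 0.00, Appropriateness.APPROPRIATE),
        ],
    )
    def test_published_rows(self, item_id, med, p30, p70, di_2dp, verdict):
        stats = statistics_from_percentiles(item_id, med, p30, p70)
        assert stats.di_display() == di_2dp
        assert stats.appropriateness is verdict
        assert stats.summary_only

    def test_symmetric_pair_hits_bare_threshold(self):
        # centiles (3, 5) centre on the midpoint: AI 0, IPRAS = IPRr = 2.35
        stats = statistics_from_percentiles("2a", 4.0, 3, 5)
        assert stats.ai == 0
        assert stats.ipras == 2.35
        assert stats.disagreement_index == pytest.approx(2 / 2.35)

    def test_inverted_centiles_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            statistics_from_percentiles("x", 4.0, 5, 3)

    def test_out_of_scale_rejected(self):
        with pytest.raises(ValueError, match="outside scale"):
            statistics_from_percentiles("x", 4.0, 3, 9)


class TestAnalyzeItem:
    def test_unanimous_top_rating(self):
        stats = analyze_item(ItemRatings(item_id="u", ratings=(8,) * 10))
        assert stats.median == 8
        assert stats.ipr == 0
        assert stats.disagreement_index == 0
        assert stats.appropriateness is Appropriateness.APPROPRIATE
        assert not stats.disagreement

    def test_even_split_at_extremes(self):
        # eight 0s and eight 8s: IPR 8 centred on the midpoint, DI = 8/2.35
        stats = analyze_item(ItemRatings(item_id="p", ratings=(0,) * 8 + (8,) * 8))
        assert (stats.p30, stats.p70) == (0, 8)
        assert (stats.iprcp, stats.ai) == (4, 0)
        assert stats.ipras == 2.35
        assert stats.di_display() == 3.40
        assert stats.disagreement

    def test_matches_summary_mode_on_own_percentiles(self):
        ratings = (0, 2, 3, 3, 4, 5, 5, 6, 6, 7, 8)
        raw = analyze_item(ItemRatings(item_id="x", ratings=ratings))
        summary = statistics_from_percentiles("x", raw.median, raw.p30, raw.p70)
        assert summary.ipr == pytest.approx(raw.ipr)
        assert summary.ipras == pytest.approx(raw.ipras)
        assert summary.disagreement_index == pytest.approx(raw.disagreement_index)

    def test_small_panel_flagged_unstable(self):
        stats = analyze_item(ItemRatings(item_id="tiny", ratings=(5, 6, 7)))
        assert "unstable" in stats.flags

    def test_round_preserves_item_order(self):
        items = [ItemRatings(item_id=i, ratings=(1, 2, 3, 4, 5, 6, 7)) for i in "cab"]
        results = analyze_round(PanelRound(items=items))
        assert [r.item_id for r in results] == ["c", "a", "b"]
        assert analyze_round(PanelRound(items=[])) == []


class TestChainProperties:
    @settings(max_examples=150, derandomize=True)
    @given(ratings=st.lists(st.integers(0, 8), min_size=2, max_size=21))
    def test_reflection_symmetry(self, ratings):
        """Flipping the scale (r -> 8 - r) preserves spread statistics."""
        fwd = analyze_item(ItemRatings(item_id="f", ratings=tuple(ratings)))
        rev = analyze_item(ItemRatings(item_id="r", ratings=tuple(8 - r for r in ratings)))
        assert rev.ipr == pytest.approx(fwd.ipr)
        assert rev.ai == pytest.approx(fwd.ai)
        assert rev.ipras == pytest.approx(fwd.ipras)
        assert rev.disagreement_index == pytest.approx(fwd.disagreement_index)
        assert rev.median == pytest.approx(8 - fwd.median)

    @settings(max_examples=150, derandomize=True)
    @given(ratings=st.lists(st.integers(0, 8), min_size=2, max_size=21),
           seed=st.integers(0, 2**16))
    def test_permutation_invariance(self, ratings, seed):
        import random

        shuffled = ratings[:]
        random.Random(seed).shuffle(shuffled)
        a = analyze_item(ItemRatings(item_id="a", ratings=tuple(ratings)))
        b = analyze_item(ItemRatings(item_id="b", ratings=tuple(shuffled)))
        assert a.disagreement_index == pytest.approx(b.disagreement_index)
        assert a.median == b.median

    @settings(max_examples=100, derandomize=True)
    @given(
        p30=st.floats(0, 8), p70=st.floats(0, 8), delta=st.floats(0.1, 2.0)
    )
    def test_monotonicity_in_spread_and_asymmetry(self, p30, p70, delta):
        """DI strictly increases with IPR (fixed centre) and decreases with AI."""
        if p30 > p70:
            p30, p70 = p70, p30
        stats = statistics_from_percentiles("m", max(min(p70, 8), 0), p30, p70)
        # widen the range symmetrically about the same IPRCP
        lo, hi = p30 - delta, p70 + delta
        if lo >= 0 and hi <= 8:
            wider = statistics_from_percentiles("w", max(min(hi, 8), 0), lo, hi)
            assert wider.disagreement_index > stats.disagreement_index
        # shift the same IPR further from the midpoint
        shift = statistics_from_percentiles
        if p70 + delta <= 8 and (p30 + p70) / 2 >= 4 and p70 > p30:
            moved = shift("s", max(min(p70 + delta, 8), 0), p30 + delta, p70 + delta)
            assert moved.disagreement_index < stats.disagreement_index

    def test_ipras_floor_reached_only_at_symmetric_centre(self):
        centred = statistics_from_percentiles("c", 4, 3, 5)
        off = statistics_from_percentiles("o", 4, 3, 6)
        assert centred.ipras == 2.35
        assert off.ipras > 2.35


class TestRounding:
    @pytest.mark.parametrize(
        "value, decimals, expected",
        [(0.125, 2, 0.13), (0.845, 2, 0.85), (6.45, 1, 6.5), (0.004999, 2, 0.0)],
    )
    def test_half_away_from_zero(self, value, decimals, expected):
        assert round_half_up(value, decimals) == expected


class TestDemotionMode:
    def test_disagreement_does_not_demote_by_default(self):
        stats = statistics_from_percentiles("2", 0.0, 0, 5)
        assert stats.disagreement
        assert stats.appropriateness is Appropriateness.INAPPROPRIATE

    def test_classic_demotion_mode(self):
        config = EngineConfig(demote_on_disagreement=True)
        stats = statistics_from_percentiles("2", 0.0, 0, 5, config=config)
        assert stats.appropriateness is Appropriateness.UNCERTAIN
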