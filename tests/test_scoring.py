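"""Concordance metrics: boundary values, oracle equivalence, invariants."""
import io
from fractions import Fraction

import pytest

from emrbench.errors import (
    IntegrityError,
    MissingDataError,
    UndefinedScoreError,
)
from emrbench.ratings import (
    ItemRating,
    Pool,
    RaterData,
    RatingLabel,
    ScenarioFamilyRatings,
    ScenarioRatings,
)
from emrbench.scoring import (
    build_report,
    metrics_to_bytes,
    mismatch_exemplars,
    read_metrics,
    score_excluded,
    score_included,
    score_total,
)
from emrbench.strategy_engine import ItemResult, ScenarioResults, StrategyResultSet

MIRROR = {
    RatingLabel.CERTAINLY_RELEVANT: RatingLabel.IRRELEVANT,
    RatingLabel.IRRELEVANT: RatingLabel.CERTAINLY_RELEVANT,
    RatingLabel.PROBABLY_RELEVANT: RatingLabel.UNLIKELY_RELEVANT,
    RatingLabel.UNLIKELY_RELEVANT: RatingLabel.PROBABLY_RELEVANT,
}


def _two_item_instance():
    """One scenario, one rater, two items rated identically, one hit."""
    results = StrategyResultSet(
        family_id="family-1",
        strategy_id="strategy-1",
        scenarios=[
            ScenarioResults(
                scenario_id="scenario-1",
                results=[
                    ItemResult(item_id="item-1", hit=True),
                    ItemResult(item_id="item-2", hit=False),
                ],
            )
        ],
    )
    ratings = ScenarioFamilyRatings(
        family_id="family-1",
        scenarios=[
            ScenarioRatings(
                scenario_id="scenario-1",
                raters=[
                    RaterData(
                        rater_id="rater-1",
                        ratings=[
                            ItemRating(
                                item_id="item-1", label=RatingLabel.CERTAINLY_RELEVANT
                            ),
                            ItemRating(
                                item_id="item-2", label=RatingLabel.CERTAINLY_RELEVANT
                            ),
                        ],
                    )
                ],
            )
        ],
    )
    return results, ratings


def _negate_hits(results):
    return StrategyResultSet(
        family_id=results.family_id,
        strategy_id=results.strategy_id,
        scenarios=[
            ScenarioResults(
                scenario_id=s.scenario_id,
                results=[
                    ItemResult(item_id=r.item_id, hit=not r.hit) for r in s.results
                ],
            )
            for s in results.scenarios
        ],
    )


def _mirror_ratings(ratings):
    return ScenarioFamilyRatings(
        family_id=ratings.family_id,
        scenarios=[
            ScenarioRatings(
                scenario_id=s.scenario_id,
                raters=[
                    RaterData(
                        rater_id=rd.rater_id,
                        ratings=[
                            ItemRating(item_id=r.item_id, label=MIRROR[r.label])
                            for r in rd.ratings
                        ],
                    )
                    for rd in s.raters
                ],
            )
            for s in ratings.scenarios
        ],
    )


class TestBoundaryValues:
    def test_no_correspondence_is_zero(self):
        results, ratings = _two_item_instance()
        assert score_total(results, ratings) == 0
        assert score_total(results, ratings, norm="count") == 0

    def test_mismatched_family_ids_rejected(self):
        results, ratings = _two_item_instance()
        ratings.family_id = "another-family"
        with pytest.raises(IntegrityError, match="family"):
            score_total(results, ratings)

    def test_no_rated_pairs_is_undefined(self):
        results, ratings = _two_item_instance()
        ratings.scenarios[0].raters[0].ratings.clear()
        with pytest.raises(UndefinedScoreError):
            score_total(results, ratings)

    def test_strict_policy_fails_on_missing_rating(self):
        results, ratings = _two_item_instance()
        ratings.scenarios[0].raters[0].ratings.pop()
        with pytest.raises(MissingDataError):
            score_total(results, ratings, missing="strict")
        # skip policy scores the remaining pair: lone hit rated +1
        assert score_total(results, ratings) == 1

    def test_all_positive_consensus_leaves_excluded_undefined(self):
        results, ratings = _two_item_instance()
        assert score_included(results, ratings) == 0
        assert score_excluded(results, ratings) is None


class TestOracleEquivalence:
    def test_matches_naive_triple_loop_on_random_instances(self, oracle, make_instance):
        for seed in range(200):
            results, ratings = make_instance(seed)
            for norm in ("abs", "count"):
                expected = oracle(results, ratings, norm=norm)
                assert score_total(results, ratings, norm=norm) == expected["total"]
                assert score_included(results, ratings, norm=norm) == expected["included"]
                assert score_excluded(results, ratings, norm=norm) == expected["excluded"]

    def test_seed29_instance_frozen_value(self, oracle, make_instance):
        results, ratings = make_instance(29)
        assert score_total(results, ratings) == oracle(results, ratings)["total"]


class TestInvariantSuites:
    def test_bounds_on_random_instances(self, make_instance):
        for seed in range(120):
            results, ratings = make_instance(seed)
            for norm in ("abs", "count"):
                for score in (
                    score_total(results, ratings, norm=norm),
                    score_included(results, ratings, norm=norm),
                    score_excluded(results, ratings, norm=norm),
                ):
                    if score is not None:
                        assert -1 <= score <= 1

    def test_negating_hits_negates_s_total(self, make_instance):
        for seed in range(80):
            results, ratings = make_instance(seed)
            assert score_total(_negate_hits(results), ratings) == -score_total(
                results, ratings
            )

    def test_mirroring_ratings_negates_s_total(self, make_instance):
        for seed in range(80):
            results, ratings = make_instance(seed)
            assert score_total(results, _mirror_ratings(ratings)) == -score_total(
                results, ratings
            )

    def test_flipping_toward_consensus_is_monotone(self, make_instance):
        """Flipping one hit flag toward the sign of the item's consensus
        never decreases S_total, strictly increasing it when the consensus
        is nonzero (and leaving it unchanged at zero consensus)."""
        checked_strict = 0
        for seed in range(60):
            results, ratings = make_instance(seed, p_missing=0.0)
            base = score_total(results, ratings)
            scen = results.scenarios[0]
            scen_ratings = ratings.for_scenario(scen.scenario_id)
            for idx, item_result in enumerate(scen.results):
                total = Fraction(0)
                for rd in scen_ratings.raters:
                    r = rd.rating_for(item_result.item_id)
                    if r is not None:
                        total += r.value
                flipped = score_total(
                    _negate_single(results, scen.scenario_id, idx), ratings
                )
                disagrees = (item_result.hit and total < 0) or (
                    not item_result.hit and total > 0
                )
                if disagrees:  # flip moves toward consensus
                    assert flipped > base
                    checked_strict += 1
                elif total == 0:
                    assert flipped == base
        assert checked_strict > 20

    def test_numerator_decomposes_over_pools(self, make_instance):
        for seed in range(60):
            results, ratings = make_instance(seed)
            total_num, pool_nums = _numerators(results, ratings)
            assert total_num == sum(pool_nums.values())


def _negate_single(results, scenario_id, index):
    return StrategyResultSet(
        family_id=results.family_id,
        strategy_id=results.strategy_id,
        scenarios=[
            ScenarioResults(
                scenario_id=s.scenario_id,
                results=[
                    ItemResult(item_id=r.item_id, hit=(not r.hit) if (s.scenario_id == scenario_id and i == index) else r.hit)
                    for i, r in enumerate(s.results)
                ],
            )
            for s in results.scenarios
        ],
    )


def _numerators(results, ratings):
    """Numerator of S_total and its split across the three consensus pools."""
    total = Fraction(0)
    pools = {Pool.INCLUDED: Fraction(0), Pool.EXCLUDED: Fraction(0), Pool.NEUTRAL: Fraction(0)}
    for scen in results.scenarios:
        scen_ratings = ratings.for_scenario(scen.scenario_id)
        for item_result in scen.results:
            h = 1 if item_result.hit else -1
            values = []
            if scen_ratings is not None:
                for rd in scen_ratings.raters:
                    r = rd.rating_for(item_result.item_id)
                    if r is not None:
                        values.append(r.value)
            if not values:
                continue
            s = sum(values, Fraction(0))
            pool = Pool.INCLUDED if s > 0 else Pool.EXCLUDED if s < 0 else Pool.NEUTRAL
            contrib = sum((h * v for v in values), Fraction(0))
            total += contrib
            pools[pool] += contrib
    return total, pools


class TestReportAndDrillDown:
    def test_single_scenario_per_scenario_score_equals_total(self):
        results, ratings = _two_item_instance()
        report = build_report(results, ratings)
        assert report.per_scenario_scores == [("scenario-1", report.s_total)]
        assert report.n_scenarios == 1
        assert report.n_items_total == 2
        assert report.n_raters_effective == 1

    def test_pool_sizes_sum_to_rated_items(self, make_instance):
        for seed in range(40):
            results, ratings = make_instance(seed)
            report = build_report(results, ratings)
            n_rated = 0
            for scen in results.scenarios:
                scen_ratings = ratings.for_scenario(scen.scenario_id)
                for item_result in scen.results:
                    if scen_ratings and any(
                        rd.rating_for(item_result.item_id) for rd in scen_ratings.raters
                    ):
                        n_rated += 1
            assert sum(report.pool_sizes.values()) == n_rated

    def test_perfect_agreement_has_no_mismatches(self, make_instance):
        results, ratings = _two_item_instance()
        # make the miss agree too
        ratings.scenarios[0].raters[0].ratings[1] = ItemRating(
            item_id="item-2", label=RatingLabel.IRRELEVANT
        )
        assert mismatch_exemplars(results, ratings) == []

    def test_single_disagreeing_item_is_surfaced(self):
        results, ratings = _two_item_instance()
        records = mismatch_exemplars(results, ratings)
        assert [(r.scenario_id, r.item_id) for r in records] == [
            ("scenario-1", "item-2")
        ]
        assert records[0].contribution == Fraction(-1)

    def test_drill_down_sorted_worst_first(self, make_instance):
        for seed in (3, 7, 11):
            results, ratings = make_instance(seed)
            records = mismatch_exemplars(results, ratings)
            assert all(r.contribution < 0 for r in records)
            keys = [(r.contribution, r.scenario_id, r.item_id) for r in records]
            assert keys == sorted(keys)
            top2 = mismatch_exemplars(results, ratings, top_n=2)
            assert top2 == records[:2]

    def test_metrics_xml_round_trips_byte_exactly(self, make_instance):
        results, ratings = make_instance(5)
        report = build_report(results, ratings, drill_down=3)
        data = metrics_to_bytes(report)
        back = read_metrics(io.BytesIO(data))
        assert metrics_to_bytes(back) == data
        assert back.pool_sizes == report.pool_sizes

    def test_undefined_score_serialized_as_marker(self):
        results, ratings = _two_item_instance()
        report = build_report(results, ratings)
        assert report.s_excluded is None
        data = metrics_to_bytes(report)
        assert b'<s_excluded undefined="true"/>' in data
        assert read_metrics(io.BytesIO(data)).s_excluded is None
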