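"""Shared fixtures: hand-rolled instance builders and an independent
triple-loop scoring oracle (deliberately naive, no code shared with the
package's scorer)."""
from __future__ import annotations

import random
from fractions import Fraction

import pytest
from hypothesis import strategies as st

from emrbench.data_model import (
    ClinicalScenario,
    IndexExamination,
    MedicalRecordItem,
    ScenarioFamily,
)
from emrbench.ratings import (
    ItemRating,
    RaterData,
    RatingLabel,
    ScenarioFamilyRatings,
    ScenarioRatings,
)
from emrbench.strategy_engine import ItemResult, ScenarioResults, StrategyResultSet
from emrbench.synthetic import GeneratorConfig, generate_family

LABELS = [
    RatingLabel.IRRELEVANT,
    RatingLabel.UNLIKELY_RELEVANT,
    RatingLabel.PROBABLY_RELEVANT,
    RatingLabel.CERTAINLY_RELEVANT,
]

# independent re-statement of the printed label values
_ORACLE_VALUES = {
    "Certainly relevant": Fraction(1),
    "Probably relevant": Fraction(1, 2),
    "Unlikely relevant": Fraction(-1, 2),
    "Irrelevant": Fraction(-1),
}


def naive_scores(results, ratings, norm="abs"):
    """Brute-force S_total / S_included / S_excluded via explicit loops.

    Returns a dict with Fractions (None for an empty pool/denominator).
    """
    sums = {
        "total": [Fraction(0), Fraction(0)],
        "included": [Fraction(0), Fraction(0)],
        "excluded": [Fraction(0), Fraction(0)],
    }
    for scen_results in results.scenarios:
        scen_ratings = None
        for s in ratings.scenarios:
            if s.scenario_id == scen_results.scenario_id:
                scen_ratings = s
        for item_result in scen_results.results:
            h = 1 if item_result.hit else -1
            values = []
            if scen_ratings is not None:
                for rater in scen_ratings.raters:
                    for r in rater.ratings:
                        if r.item_id == item_result.item_id:
                            values.append(_ORACLE_VALUES[r.label.value])
            consensus_sum = Fraction(0)
            for v in values:
                consensus_sum += v
            targets = ["total"]
            if consensus_sum > 0:
                targets.append("included")
            elif consensus_sum < 0:
                targets.append("excluded")
            for v in values:
                for t in targets:
                    sums[t][0] += h * v
                    sums[t][1] += abs(v) if norm == "abs" else 1
    return {
        key: (num / den if den else None) for key, (num, den) in sums.items()
    }


def random_instance(seed, max_scenarios=4, max_items=6, max_raters=5, p_missing=0.15):
    """One random small (results, ratings) pair with ragged scenarios and
    possible missing ratings."""
    rng = random.Random(seed)
    n_scen = rng.randint(1, max_scenarios)
    scen_results = []
    scen_ratings = []
    n_raters = rng.randint(1, max_raters)
    rater_ids = [f"rater-{k}" for k in range(n_raters)]
    for i in range(n_scen):
        sid = f"scenario-{i}"
        item_ids = [f"item-{i}-{j}" for j in range(rng.randint(1, max_items))]
        scen_results.append(
            ScenarioResults(
                scenario_id=sid,
                results=[
                    ItemResult(item_id=iid, hit=rng.random() < 0.5) for iid in item_ids
                ],
            )
        )
        raters = []
        for rid in rater_ids:
            ratings = [
                ItemRating(item_id=iid, label=rng.choice(LABELS))
                for iid in item_ids
                if rng.random() >= p_missing
            ]
            raters.append(RaterData(rater_id=rid, ratings=ratings))
        scen_ratings.append(ScenarioRatings(scenario_id=sid, raters=raters))
    results = StrategyResultSet(
        family_id="family-0", strategy_id="strategy-0", scenarios=scen_results
    )
    ratings = ScenarioFamilyRatings(family_id="family-0", scenarios=scen_ratings)
    return results, ratings


# ---------------------------------------------------------------------------
# hypothesis strategies for randomized round-trip / property tests
#
# Text is restricted to XML-representable characters; carriage returns are
# excluded (XML parsers normalize them) and attribute-carried strings also
# exclude tab/newline (attribute-value normalization).

_attr_chars = st.characters(
    codec="utf-8", exclude_categories=("Cs", "Cc", "Co", "Cn")
)
attr_text = st.text(_attr_chars, max_size=30)
content_text = st.text(st.one_of(_attr_chars, st.just("\n"), st.just("\t")), max_size=60)
token_text = st.text(
    alphabet="abcdefghijklmnopqrstuvwxyz-", min_size=1, max_size=12
)
id_text = st.uuids(version=4).map(str)


@st.composite
def record_items(draw):
    return MedicalRecordItem(
        item_id=draw(id_text),
        record_type=draw(token_text),
        days_offset=draw(st.integers(-2000, 2000)),
        title=draw(content_text),
        text=draw(content_text),
    )


@st.composite
def clinical_scenarios(draw, min_items=0, max_items=5):
    return ClinicalScenario(
        scenario_id=draw(id_text),
        patient_age=draw(st.integers(0, 110)),
        patient_sex=draw(token_text),
        index_exam=IndexExamination(
            exam_id=draw(id_text),
            modality=draw(token_text),
            description=draw(content_text),
        ),
        items=draw(
            st.lists(
                record_items(),
                min_size=min_items,
                max_size=max_items,
                unique_by=lambda i: i.item_id,
            )
        ),
        demographics=draw(st.dictionaries(token_text, attr_text, max_size=2)),
    )


@st.composite
def scenario_families(draw):
    return ScenarioFamily(
        family_id=draw(id_text),
        clinical_context=draw(content_text),
        scenario_refs=draw(st.lists(id_text, min_size=1, max_size=5, unique=True)),
    )


@st.composite
def family_ratings(draw):
    scenarios = []
    for i in range(draw(st.integers(1, 3))):
        item_ids = [f"item-{i}-{j}" for j in range(draw(st.integers(1, 4)))]
        raters = []
        for k in range(draw(st.integers(0, 3))):
            ratings = [
                ItemRating(item_id=iid, label=draw(st.sampled_from(LABELS)))
                for iid in item_ids
                if draw(st.booleans())
            ]
            raters.append(RaterData(rater_id=f"rater-{k}", ratings=ratings))
        scenarios.append(ScenarioRatings(scenario_id=f"scenario-{i}", raters=raters))
    return ScenarioFamilyRatings(family_id=draw(id_text), scenarios=scenarios)


@st.composite
def result_sets(draw):
    scenarios = []
    for i in range(draw(st.integers(1, 3))):
        results = [
            ItemResult(item_id=f"item-{i}-{j}", hit=draw(st.booleans()))
            for j in range(draw(st.integers(0, 4)))
        ]
        scenarios.append(ScenarioResults(scenario_id=f"scenario-{i}", results=results))
    return StrategyResultSet(
        family_id=draw(id_text), strategy_id=draw(id_text), scenarios=scenarios
    )


@pytest.fixture(scope="session")
def oracle():
    return naive_scores


@pytest.fixture(scope="session")
def make_instance():
    return random_instance


@pytest.fixture(scope="session")
def seed17_bundle():
    """The reference synthetic family: seed 17, 5 scenarios x 4 items,
    half the items planted-relevant."""
    config = GeneratorConfig(seed=17)
    family, scenarios, manifest = generate_family(config)
    return config, family, scenarios, manifest
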