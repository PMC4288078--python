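"""Expert relevance ratings: the four-step scale, XML hierarchy, consensus.

Each expert on a panel rates every medical-record item of a scenario for its
relevance to the clinical task on a four-step ordinal scale: "Irrelevant",
"Unlikely relevant", "Probably relevant", "Certainly relevant". The labels
map to the signed values -1, -1/2, +1/2, +1, so the sum of a panel's mapped
ratings for one item (its *consensus*) is positive exactly when the panel
leans relevant. Items with positive consensus form the included-pool used by
the sensitivity-style restricted score, negative consensus the
excluded-pool, and a zero sum is neutral (counted in the overall score but
in neither restricted pool).

All arithmetic uses exact rationals (sums of halves), so pool assignment at
the zero boundary is never subject to floating-point error.

The rating file is a four-level XML hierarchy — scenario_family_ratings →
scenario_ratings → rater_data → item_rating — shipped with a RELAX NG
schema.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from fractions import Fraction

from lxml import etree

from ._xmlio import parse_validated, serialize, write_document
from .data_model import ClinicalScenario, ScenarioFamily
from .errors import DomainError, IntegrityError, MissingDataError

__all__ = [
    "RatingLabel",
    "Pool",
    "ItemRating",
    "RaterData",
    "ScenarioRatings",
    "ScenarioFamilyRatings",
    "ItemConsensus",
    "map_rating_label",
    "consensus",
    "read_ratings",
    "write_ratings",
    "ratings_to_bytes",
    "completeness_report",
]


class RatingLabel(str, enum.Enum):
    """The four-step relevance scale."""

    IRRELEVANT = "Irrelevant"
    UNLIKELY_RELEVANT = "Unlikely relevant"
    PROBABLY_RELEVANT = "Probably relevant"
    CERTAINLY_RELEVANT = "Certainly relevant"


_LABEL_VALUES: dict[RatingLabel, Fraction] = {
    RatingLabel.CERTAINLY_RELEVANT: Fraction(1),
    RatingLabel.PROBABLY_RELEVANT: Fraction(1, 2),
    RatingLabel.UNLIKELY_RELEVANT: Fraction(-1, 2),
    RatingLabel.IRRELEVANT: Fraction(-1),
}


def map_rating_label(label: RatingLabel | str) -> Fraction:
    """Map a rating label to its signed value.

    "Certainly relevant" → +1, "Probably relevant" → +1/2,
    "Unlikely relevant" → -1/2, "Irrelevant" → -1.
    """
    try:
        label = RatingLabel(label)
    except ValueError:
        raise DomainError(f"unknown rating label {label!r}") from None
    return _LABEL_VALUES[label]


class Pool(str, enum.Enum):
    """Consensus pool of an item: sign of the summed mapped ratings."""

    INCLUDED = "included-pool"
    EXCLUDED = "excluded-pool"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class ItemRating:
    item_id: str
    label: RatingLabel

    def __post_init__(self) -> None:
        if not self.item_id:
            raise IntegrityError("item_id must be non-empty")
        object.__setattr__(self, "label", RatingLabel(self.label))

    @property
    def value(self) -> Fraction:
        return map_rating_label(self.label)


@dataclass
class RaterData:
    """One expert's ratings for one scenario; at most one rating per item."""

    rater_id: str
    ratings: list[ItemRating] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rater_id:
            raise IntegrityError("rater_id must be non-empty")
        seen: set[str] = set()
        for r in self.ratings:
            if r.item_id in seen:
                raise IntegrityError(
                    f"rater {self.rater_id!r} rates item {r.item_id!r} more than once"
                )
            seen.add(r.item_id)

    def rating_for(self, item_id: str) -> ItemRating | None:
        for r in self.ratings:
            if r.item_id == item_id:
                return r
        return None


@dataclass
class ScenarioRatings:
    scenario_id: str
    raters: list[RaterData] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.scenario_id:
            raise IntegrityError("scenario_id must be non-empty")
        rater_ids = [r.rater_id for r in self.raters]
        if len(set(rater_ids)) != len(rater_ids):
            raise IntegrityError(
                f"duplicate rater_id in ratings for scenario {self.scenario_id!r}"
            )


@dataclass
class ScenarioFamilyRatings:
    """The gold standard: per-scenario, per-rater, per-item ordinal ratings."""

    family_id: str
    scenarios: list[ScenarioRatings] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.family_id:
            raise IntegrityError("family_id must be non-empty")
        sids = [s.scenario_id for s in self.scenarios]
        if len(set(sids)) != len(sids):
            raise IntegrityError("duplicate scenario_id in family ratings")

    def for_scenario(self, scenario_id: str) -> ScenarioRatings | None:
        for s in self.scenarios:
            if s.scenario_id == scenario_id:
                return s
        return None


@dataclass(frozen=True)
class ItemConsensus:
    """Panel consensus for one item: the rating sum and its pool."""

    item_id: str
    rating_sum: Fraction
    n_raters: int
    pool: Pool


def consensus(scenario_ratings: ScenarioRatings, item_id: str) -> ItemConsensus:
    """Sum the mapped ratings of every rater who rated ``item_id``.

    Pool assignment follows the sign of the sum: positive → included-pool,
    negative → excluded-pool, zero → neutral. Raises MissingDataError when no
    rater rated the item (the caller decides skip versus fail).
    """
    values = [
        r.value
        for rater in scenario_ratings.raters
        if (r := rater.rating_for(item_id)) is not None
    ]
    if not values:
        raise MissingDataError(
            f"item {item_id!r} is unrated by every rater of scenario "
            f"{scenario_ratings.scenario_id!r}"
        )
    total = sum(values, Fraction(0))
    pool = Pool.INCLUDED if total > 0 else Pool.EXCLUDED if total < 0 else Pool.NEUTRAL
    return ItemConsensus(item_id=item_id, rating_sum=total, n_raters=len(values), pool=pool)


# ---------------------------------------------------------------------------
# ratings XML


def _ratings_element(ratings: ScenarioFamilyRatings) -> etree._Element:
    root = etree.Element("scenario_family_ratings")
    root.set("family_id", ratings.family_id)
    for scen in ratings.scenarios:
        sel = etree.SubElement(root, "scenario_ratings")
        sel.set("scenario_id", scen.scenario_id)
        for rater in scen.raters:
            rel = etree.SubElement(sel, "rater_data")
            rel.set("rater_id", rater.rater_id)
            for r in rater.ratings:
                iel = etree.SubElement(rel, "item_rating")
                iel.set("item_id", r.item_id)
                iel.set("label", r.label.value)
    return root


def read_ratings(
    source,
    family: ScenarioFamily | None = None,
    scenarios: list[ClinicalScenario] | None = None,
) -> ScenarioFamilyRatings:
    """Read and validate a ratings document.

    When ``family``/``scenarios`` are supplied, references are checked:
    the family_id must match, every scenario_ratings must reference a family
    scenario, and every item_rating must reference an item of that scenario.
    """
    root = parse_validated(source, "scenario_family_ratings.rng")
    out = ScenarioFamilyRatings(
        family_id=root.get("family_id"),
        scenarios=[
            ScenarioRatings(
                scenario_id=sel.get("scenario_id"),
                raters=[
                    RaterData(
                        rater_id=rel.get("rater_id"),
                        ratings=[
                            ItemRating(item_id=iel.get("item_id"), label=iel.get("label"))
                            for iel in rel.findall("item_rating")
                        ],
                    )
                    for rel in sel.findall("rater_data")
                ],
            )
            for sel in root.findall("scenario_ratings")
        ],
    )
    if family is not None:
        if out.family_id != family.family_id:
            raise IntegrityError(
                f"ratings reference family {out.family_id!r}, expected {family.family_id!r}"
            )
        known = set(family.scenario_refs)
        for scen in out.scenarios:
            if scen.scenario_id not in known:
                raise IntegrityError(
                    f"ratings reference unknown scenario {scen.scenario_id!r}"
                )
    if scenarios is not None:
        by_id = {s.scenario_id: set(s.item_ids) for s in scenarios}
        for scen in out.scenarios:
            items = by_id.get(scen.scenario_id)
            if items is None:
                continue
            for rater in scen.raters:
                for r in rater.ratings:
                    if r.item_id not in items:
                        raise IntegrityError(
                            f"rating by {rater.rater_id!r} references unknown item "
                            f"{r.item_id!r} in scenario {scen.scenario_id!r}"
                        )
    return out


def ratings_to_bytes(ratings: ScenarioFamilyRatings) -> bytes:
    return serialize(_ratings_element(ratings))


def write_ratings(ratings: ScenarioFamilyRatings, sink) -> None:
    """Write the canonical ratings document to ``sink``."""
    write_document(_ratings_element(ratings), sink)


def completeness_report(
    scenarios: list[ClinicalScenario], ratings: ScenarioFamilyRatings
) -> list[tuple[str, str, str]]:
    """Exhaustive list of (rater_id, scenario_id, item_id) triples lacking a
    rating, over every rater who appears in each scenario's panel."""
    missing: list[tuple[str, str, str]] = []
    for scenario in scenarios:
        scen_ratings = ratings.for_scenario(scenario.scenario_id)
        if scen_ratings is None:
            continue
        for rater in scen_ratings.raters:
            rated = {r.item_id for r in rater.ratings}
            for item_id in scenario.item_ids:
                if item_id not in rated:
                    missing.append((rater.rater_id, scenario.scenario_id, item_id))
    return missing
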