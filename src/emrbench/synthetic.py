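"""Synthetic scenario families, simulated expert panels, planted strategies.

No public gold-standard EMR relevance dataset exists, so the framework is
exercised end to end on synthetic data with known ground truth. The
generator emulates the upstream extraction step: each scenario family gets
a clinical context, and each medical-record item is drawn with a record
type, a day offset relative to the index exam, and template-based synthetic
clinical prose. A fraction of items is flagged *planted-relevant*: those
items receive at least one keyword from a task lexicon embedded in their
text and a latent relevance drawn from a high band ([0.75, 1]); all other
items get only distractor phrases and a low-band latent ([0, 0.25]). The
band gap leaves a margin around the default rating thresholds, so in the
noise-free limit the panel's labels — and a strategy alternating over the
lexicon — recover the planted truth exactly.

The simulated panel perturbs each item's latent relevance with a per-rater
additive bias and per-(rater, item) Gaussian noise, then cuts the perturbed
value at three ascending thresholds to produce the four ordinal labels;
ratings may drop out at a configurable rate. Everything is deterministic
under the configured seeds: one global seed splits into independent
substreams for family, panel, and strategy material, and the manifest
records every drawn value so any component can be regenerated and checked
independently.

What this emulates — and what it does not: latent relevance driving noisy
ordinal judgments, keyword-bearing text discoverable by regex, panel
dropout. It does not model realistic clinical language, correlated rater
errors, or items whose relevance is not text-detectable; conclusions about
those require real rated data.
"""
from __future__ import annotations

import json
import re
import uuid
from dataclasses import dataclass, field, asdict

import numpy as np

from .data_model import (
    ClinicalScenario,
    IndexExamination,
    MedicalRecordItem,
    ScenarioFamily,
)
from .errors import ConfigError
from .ratings import (
    ItemRating,
    RaterData,
    RatingLabel,
    ScenarioFamilyRatings,
    ScenarioRatings,
)
from .strategy_engine import RegexClause, SearchStrategy, StrategyResultSet

__all__ = [
    "GeneratorConfig",
    "PanelConfig",
    "GeneratorManifest",
    "generate_family",
    "simulate_panel",
    "planted_strategy",
    "random_strategy",
    "unanimous_panel",
]

# default lexicons for a liver-MR-style task; planted keywords must never
# occur as substrings of the distractor vocabulary or templates
DEFAULT_KEYWORDS = [
    "hepatic lesion",
    "liver mass",
    "cirrhosis",
    "portal vein thrombus",
    "elevated alpha-fetoprotein",
]
DEFAULT_DISTRACTORS = [
    "seasonal allergies",
    "routine dental cleaning",
    "mild knee discomfort",
    "stable blood pressure",
    "annual wellness visit",
    "resolved ankle sprain",
    "refill of cetirizine",
    "normal lipid panel",
]
DEFAULT_RECORD_TYPES = [
    "clinic-note",
    "discharge-summary",
    "lab-result",
    "imaging-report",
    "medication",
    "pathology-report",
    "operative-note",
]
_SENTENCE_TEMPLATES = [
    "Patient reports {p}.",
    "Assessment notes {p}.",
    "Documented during the encounter: {p}.",
    "Follow-up planned regarding {p}.",
]
_LATENT_HIGH = (0.75, 1.0)
_LATENT_LOW = (0.0, 0.25)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic scenario family.

    Defaults give a small family — five scenarios of four items each with
    half the items relevant — matching the desk-scale fixtures the test
    suite and worked examples use.
    """

    seed: int
    n_scenarios: int = 5
    items_per_scenario: tuple[int, int] = (4, 4)
    record_type_vocabulary: tuple[str, ...] = tuple(DEFAULT_RECORD_TYPES)
    day_offset_range: tuple[int, int] = (-365, 30)
    relevant_fraction: float = 0.5
    keyword_lexicon: tuple[str, ...] = tuple(DEFAULT_KEYWORDS)
    distractor_lexicon: tuple[str, ...] = tuple(DEFAULT_DISTRACTORS)
    clinical_context: str = "interpreting an MRI examination of the liver"

    def __post_init__(self) -> None:
        if self.n_scenarios < 1:
            raise ConfigError("n_scenarios must be positive")
        lo, hi = self.items_per_scenario
        if lo < 0 or lo > hi:
            raise ConfigError("items_per_scenario must be a non-empty range")
        if not 0.0 <= self.relevant_fraction <= 1.0:
            raise ConfigError("relevant_fraction must lie in [0, 1]")
        if self.day_offset_range[0] > self.day_offset_range[1]:
            raise ConfigError("day_offset_range must be non-empty")
        if not self.record_type_vocabulary:
            raise ConfigError("record_type_vocabulary must be non-empty")
        if self.relevant_fraction > 0 and not self.keyword_lexicon:
            raise ConfigError(
                "keyword_lexicon must be non-empty when relevant_fraction > 0"
            )
        if not self.distractor_lexicon:
            raise ConfigError("distractor_lexicon must be non-empty")
        for kw in self.keyword_lexicon:
            for phrase in (*self.distractor_lexicon, *_SENTENCE_TEMPLATES):
                if kw.lower() in phrase.lower():
                    raise ConfigError(
                        f"keyword {kw!r} collides with distractor text {phrase!r}"
                    )
        object.__setattr__(self, "items_per_scenario", tuple(self.items_per_scenario))
        object.__setattr__(
            self, "record_type_vocabulary", tuple(self.record_type_vocabulary)
        )
        object.__setattr__(self, "day_offset_range", tuple(self.day_offset_range))
        object.__setattr__(self, "keyword_lexicon", tuple(self.keyword_lexicon))
        object.__setattr__(self, "distractor_lexicon", tuple(self.distractor_lexicon))


@dataclass(frozen=True)
class PanelConfig:
    """Simulated expert panel.

    ``rater_noise_sd`` is the standard deviation of the per-(rater, item)
    Gaussian perturbation of the latent relevance (latent lives on [0, 1]);
    ``rater_bias_range`` bounds each rater's additive shift (optimists vs
    sceptics); ``thresholds`` are the three ascending cut points mapping the
    perturbed latent value to the four labels; ``dropout_rate`` is the
    probability any one (rater, item) rating is missing.
    """

    seed: int
    n_raters: int = 3
    rater_noise_sd: float = 0.1
    rater_bias_range: tuple[float, float] = (-0.05, 0.05)
    thresholds: tuple[float, float, float] = (0.25, 0.5, 0.75)
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_raters < 1:
            raise ConfigError("n_raters must be positive")
        if self.rater_noise_sd < 0:
            raise ConfigError("rater_noise_sd must be non-negative")
        t1, t2, t3 = self.thresholds
        if not (t1 < t2 < t3):
            raise ConfigError("thresholds must be strictly ascending")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must lie in [0, 1)")
        if self.rater_bias_range[0] > self.rater_bias_range[1]:
            raise ConfigError("rater_bias_range must be non-empty")
        object.__setattr__(self, "rater_bias_range", tuple(self.rater_bias_range))
        object.__setattr__(self, "thresholds", tuple(self.thresholds))


@dataclass
class ManifestItem:
    scenario_id: str
    item_id: str
    latent: float
    planted: bool
    keywords: list[str]


@dataclass
class GeneratorManifest:
    """Ground truth of one generated family; fully determines regeneration
    under the same seed and serves as the oracle for end-to-end tests."""

    seed: int
    family_id: str
    config: dict
    items: list[ManifestItem]
    planted_strategy_spec: dict

    def save(self, path) -> None:
        payload = asdict(self)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "GeneratorManifest":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        payload["items"] = [ManifestItem(**it) for it in payload["items"]]
        return cls(**payload)

    @property
    def planted_item_ids(self) -> set[str]:
        return {it.item_id for it in self.items if it.planted}

    def latent_of(self, item_id: str) -> float:
        for it in self.items:
            if it.item_id == item_id:
                return it.latent
        raise KeyError(item_id)


def _uuid(rng: np.random.Generator) -> str:
    return str(uuid.UUID(bytes=rng.bytes(16), version=4))


def _substream(seed: int, purpose: int) -> np.random.Generator:
    # independent substreams for family / panel / strategy material
    return np.random.default_rng(np.random.SeedSequence([int(seed), purpose]))


def _sentence(rng: np.random.Generator, phrase: str) -> str:
    template = _SENTENCE_TEMPLATES[int(rng.integers(len(_SENTENCE_TEMPLATES)))]
    return template.format(p=phrase)


def generate_family(
    config: GeneratorConfig,
) -> tuple[ScenarioFamily, list[ClinicalScenario], GeneratorManifest]:
    """Generate one scenario family with planted keyword signal.

    Deterministic under ``config.seed``: same config → byte-identical family
    and scenarios. Each planted-relevant item embeds at least one lexicon
    keyword at a random sentence position; non-planted items contain only
    distractor prose.
    """
    rng = _substream(config.seed, 0)
    family_id = _uuid(rng)
    scenarios: list[ClinicalScenario] = []
    manifest_items: list[ManifestItem] = []
    lo, hi = config.items_per_scenario
    for _ in range(config.n_scenarios):
        scenario_id = _uuid(rng)
        exam = IndexExamination(
            exam_id=_uuid(rng),
            modality="MRI",
            description=f"MRI of the liver ({config.clinical_context})",
        )
        n_items = int(rng.integers(lo, hi + 1))
        items: list[MedicalRecordItem] = []
        for _ in range(n_items):
            item_id = _uuid(rng)
            planted = bool(rng.random() < config.relevant_fraction)
            record_type = str(rng.choice(config.record_type_vocabulary))
            days_offset = int(
                rng.integers(config.day_offset_range[0], config.day_offset_range[1] + 1)
            )
            n_sentences = int(rng.integers(2, 5))
            sentences = [
                _sentence(rng, str(rng.choice(config.distractor_lexicon)))
                for _ in range(n_sentences)
            ]
            keywords: list[str] = []
            if planted:
                n_kw = int(rng.integers(1, min(2, len(config.keyword_lexicon)) + 1))
                keywords = [
                    str(kw)
                    for kw in rng.choice(
                        config.keyword_lexicon, size=n_kw, replace=False
                    )
                ]
                for kw in keywords:
                    pos = int(rng.integers(0, len(sentences) + 1))
                    sentences.insert(pos, _sentence(rng, kw))
                latent = float(rng.uniform(*_LATENT_HIGH))
            else:
                latent = float(rng.uniform(*_LATENT_LOW))
            items.append(
                MedicalRecordItem(
                    item_id=item_id,
                    record_type=record_type,
                    days_offset=days_offset,
                    title=f"{record_type} ({days_offset:+d} d)",
                    text=" ".join(sentences),
                )
            )
            manifest_items.append(
                ManifestItem(
                    scenario_id=scenario_id,
                    item_id=item_id,
                    latent=latent,
                    planted=planted,
                    keywords=keywords,
                )
            )
        scenarios.append(
            ClinicalScenario(
                scenario_id=scenario_id,
                patient_age=int(rng.integers(25, 90)),
                patient_sex=str(rng.choice(["F", "M"])),
                index_exam=exam,
                items=items,
            )
        )
    family = ScenarioFamily(
        family_id=family_id,
        clinical_context=config.clinical_context,
        scenario_refs=[s.scenario_id for s in scenarios],
    )
    strategy_spec = _planted_spec(config.keyword_lexicon)
    manifest = GeneratorManifest(
        seed=config.seed,
        family_id=family_id,
        config={
            "n_scenarios": config.n_scenarios,
            "items_per_scenario": list(config.items_per_scenario),
            "record_type_vocabulary": list(config.record_type_vocabulary),
            "day_offset_range": list(config.day_offset_range),
            "relevant_fraction": config.relevant_fraction,
            "keyword_lexicon": list(config.keyword_lexicon),
            "distractor_lexicon": list(config.distractor_lexicon),
            "clinical_context": config.clinical_context,
        },
        items=manifest_items,
        planted_strategy_spec=strategy_spec,
    )
    return family, scenarios, manifest


def _label_for(value: float, thresholds: tuple[float, float, float]) -> RatingLabel:
    t1, t2, t3 = thresholds
    if value < t1:
        return RatingLabel.IRRELEVANT
    if value < t2:
        return RatingLabel.UNLIKELY_RELEVANT
    if value < t3:
        return RatingLabel.PROBABLY_RELEVANT
    return RatingLabel.CERTAINLY_RELEVANT


def simulate_panel(
    family: ScenarioFamily,
    scenarios: list[ClinicalScenario],
    manifest: GeneratorManifest,
    config: PanelConfig,
) -> ScenarioFamilyRatings:
    """Simulate a noisy expert panel over a generated family.

    For rater k and item j the rated value is latent_j + bias_k + noise_jk;
    the three thresholds cut it into the four labels. Deterministic under
    ``config.seed``.
    """
    if manifest.family_id != family.family_id:
        raise ConfigError(
            f"manifest describes family {manifest.family_id!r}, got {family.family_id!r}"
        )
    rng = _substream(config.seed, 1)
    rater_ids = [_uuid(rng) for _ in range(config.n_raters)]
    biases = rng.uniform(*config.rater_bias_range, size=config.n_raters)
    latent = {it.item_id: it.latent for it in manifest.items}
    scen_ratings: list[ScenarioRatings] = []
    for scenario in scenarios:
        raters: list[RaterData] = []
        for k, rater_id in enumerate(rater_ids):
            ratings: list[ItemRating] = []
            for item in scenario.items:
                noise = (
                    float(rng.normal(0.0, config.rater_noise_sd))
                    if config.rater_noise_sd > 0
                    else 0.0
                )
                dropped = bool(rng.random() < config.dropout_rate)
                if dropped:
                    continue
                value = latent[item.item_id] + float(biases[k]) + noise
                ratings.append(
                    ItemRating(
                        item_id=item.item_id,
                        label=_label_for(value, config.thresholds),
                    )
                )
            raters.append(RaterData(rater_id=rater_id, ratings=ratings))
        scen_ratings.append(
            ScenarioRatings(scenario_id=scenario.scenario_id, raters=raters)
        )
    return ScenarioFamilyRatings(family_id=family.family_id, scenarios=scen_ratings)


def _planted_spec(keywords: tuple[str, ...] | list[str]) -> dict:
    pattern = "|".join(re.escape(kw) for kw in keywords) if keywords else None
    clauses = (
        [{"pattern": pattern, "polarity": "require", "case_sensitive": False}]
        if pattern
        else []
    )
    return {
        "name": "planted keyword strategy",
        "clause_logic": "any-required",
        "clauses": clauses
        or [{"pattern": r"(?!)", "polarity": "require", "case_sensitive": False}],
    }


def planted_strategy(manifest: GeneratorManifest) -> SearchStrategy:
    """The strategy the generator planted: an alternation over the keyword
    lexicon. At zero noise its hit set equals the planted-relevant set."""
    spec = manifest.planted_strategy_spec
    clauses = tuple(
        RegexClause(
            pattern=c["pattern"],
            polarity=c["polarity"],
            case_sensitive=c["case_sensitive"],
        )
        for c in spec["clauses"]
    )
    strategy_id = str(
        uuid.uuid5(uuid.NAMESPACE_URL, f"emrbench:planted:{manifest.family_id}")
    )
    return SearchStrategy(
        strategy_id=strategy_id,
        name=spec["name"],
        clauses=clauses,
        clause_logic=spec["clause_logic"],
    )


_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


def random_strategy(seed: int, n_terms: int = 3) -> SearchStrategy:
    """A distractor strategy: an alternation over random letter strings.

    Used to check that the framework discriminates a signal-bearing strategy
    from noise."""
    rng = _substream(seed, 2)
    terms = [
        "".join(rng.choice(list(_ALPHABET), size=int(rng.integers(5, 9))))
        for _ in range(n_terms)
    ]
    return SearchStrategy(
        strategy_id=str(uuid.uuid5(uuid.NAMESPACE_URL, f"emrbench:random:{seed}")),
        name=f"random strategy (seed {seed})",
        clauses=(
            RegexClause(pattern="|".join(terms), polarity="require"),
        ),
        clause_logic="any-required",
    )


def unanimous_panel(
    family: ScenarioFamily,
    scenarios: list[ClinicalScenario],
    results: StrategyResultSet,
    n_raters: int = 3,
    agree: bool = True,
) -> ScenarioFamilyRatings:
    """A deterministic panel at an agreement extreme.

    With ``agree=True`` every rater rates each hit item "Certainly relevant"
    and each miss "Irrelevant" (the perfect-agreement construction, S_total
    = +1); ``agree=False`` mirrors it (perfect disagreement, S_total = -1).
    """
    rater_ids = [
        str(uuid.uuid5(uuid.NAMESPACE_URL, f"emrbench:rater:{family.family_id}:{k}"))
        for k in range(n_raters)
    ]
    scen_ratings = []
    for scenario in scenarios:
        scen_results = results.for_scenario(scenario.scenario_id)
        hits = {r.item_id for r in scen_results.results if r.hit}
        raters = [
            RaterData(
                rater_id=rid,
                ratings=[
                    ItemRating(
                        item_id=item.item_id,
                        label=(
                            RatingLabel.CERTAINLY_RELEVANT
                            if (item.item_id in hits) == agree
                            else RatingLabel.IRRELEVANT
                        ),
                    )
                    for item in scenario.items
                ],
            )
            for rid in rater_ids
        ]
        scen_ratings.append(
            ScenarioRatings(scenario_id=scenario.scenario_id, raters=raters)
        )
    return ScenarioFamilyRatings(family_id=family.family_id, scenarios=scen_ratings)
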