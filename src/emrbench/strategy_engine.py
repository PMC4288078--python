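"""Declarative search strategies and their execution over scenario families.

A search strategy models the kind of task-specific EMR search a designer
would iterate on: *metadata conditions* restrict which items are even
eligible (allowed record types, a closed day-offset window around the index
exam), and *regex clauses* test the item's title and free text. Clauses have
a polarity: ``require`` clauses must match (under ``all-required`` or
``any-required`` logic), while ``forbid`` clauses always veto — the natural
way to handle negative forms of key terms ("no mass", "unremarkable").
Patterns use Python's Perl-compatible regex dialect and are
case-insensitive unless a clause opts out, since clinical free text is rife
with abbreviations, synonyms, and inconsistent casing.

Running a strategy over a scenario family yields exactly one hit/no-hit
decision per item (the h_ij of the scoring metric, hit ↦ +1, miss ↦ -1);
the run is a pure function of (strategy, family).

Strategy definitions are human-editable YAML documents (see
``compile_strategy``); result sets interchange as XML with a shipped
schema.
"""
from __future__ import annotations

import os
import re
import uuid
from dataclasses import dataclass, field

import yaml
from lxml import etree

from ._xmlio import parse_validated, serialize, write_document
from .data_model import ClinicalScenario, MedicalRecordItem, ScenarioFamily
from .errors import IntegrityError, ParseError, StrategyCompileError

__all__ = [
    "MetadataCondition",
    "RegexClause",
    "SearchStrategy",
    "ItemResult",
    "ScenarioResults",
    "StrategyResultSet",
    "compile_strategy",
    "strategy_to_yaml",
    "evaluate_item",
    "run_strategy",
    "read_results",
    "write_results",
    "results_to_bytes",
]

CLAUSE_LOGICS = ("all-required", "any-required")
# separator between title and text when clauses are applied
_FIELD_SEP = "\n"


@dataclass(frozen=True)
class MetadataCondition:
    """Structured filters on item metadata.

    ``day_window`` is a closed interval [min_offset, max_offset] on the
    signed day offset; either bound may be None (unbounded). An absent
    condition (both fields None) passes every item.
    """

    allowed_record_types: frozenset[str] | None = None
    day_window: tuple[int | None, int | None] | None = None

    def __post_init__(self) -> None:
        if self.allowed_record_types is not None:
            object.__setattr__(
                self, "allowed_record_types", frozenset(self.allowed_record_types)
            )
        if self.day_window is not None:
            lo, hi = self.day_window
            if lo is not None and hi is not None and lo > hi:
                raise StrategyCompileError(
                    f"day_window lower bound {lo} exceeds upper bound {hi}"
                )
            object.__setattr__(self, "day_window", (lo, hi))

    @property
    def is_empty(self) -> bool:
        return self.allowed_record_types is None and self.day_window is None

    def passes(self, item: MedicalRecordItem) -> bool:
        if self.allowed_record_types is not None and item.record_type not in self.allowed_record_types:
            return False
        if self.day_window is not None:
            lo, hi = self.day_window
            if lo is not None and item.days_offset < lo:
                return False
            if hi is not None and item.days_offset > hi:
                return False
        return True


@dataclass(frozen=True)
class RegexClause:
    """One pattern with a polarity; compiled eagerly so bad patterns fail at
    strategy-compile time, not mid-run."""

    pattern: str
    polarity: str = "require"
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        if self.polarity not in ("require", "forbid"):
            raise StrategyCompileError(
                f"clause polarity must be 'require' or 'forbid', got {self.polarity!r}"
            )
        flags = 0 if self.case_sensitive else re.IGNORECASE
        try:
            compiled = re.compile(self.pattern, flags)
        except re.error as exc:
            raise StrategyCompileError(
                f"invalid regular expression {self.pattern!r}: {exc}"
            ) from exc
        object.__setattr__(self, "_compiled", compiled)

    def matches(self, text: str) -> bool:
        return self._compiled.search(text) is not None


@dataclass(frozen=True)
class SearchStrategy:
    """Metadata conditions plus regex clauses under one clause logic.

    ``clause_logic`` governs the require-clauses only: ``all-required``
    (conjunctive, the default) or ``any-required`` (disjunctive).
    Forbid-clauses always veto regardless of logic. A strategy must carry at
    least one metadata condition or one clause.
    """

    strategy_id: str
    name: str = ""
    metadata: MetadataCondition = field(default_factory=MetadataCondition)
    clauses: tuple[RegexClause, ...] = ()
    clause_logic: str = "all-required"

    def __post_init__(self) -> None:
        if not self.strategy_id:
            raise StrategyCompileError("strategy_id must be non-empty")
        if self.clause_logic not in CLAUSE_LOGICS:
            raise StrategyCompileError(
                f"clause_logic must be one of {CLAUSE_LOGICS}, got {self.clause_logic!r}"
            )
        object.__setattr__(self, "clauses", tuple(self.clauses))
        if self.metadata.is_empty and not self.clauses:
            raise StrategyCompileError(
                "a strategy must have at least one metadata condition or clause"
            )

    @property
    def require_clauses(self) -> tuple[RegexClause, ...]:
        return tuple(c for c in self.clauses if c.polarity == "require")

    @property
    def forbid_clauses(self) -> tuple[RegexClause, ...]:
        return tuple(c for c in self.clauses if c.polarity == "forbid")


def _strategy_spec(strategy: SearchStrategy) -> dict:
    spec: dict = {"name": strategy.name, "clause_logic": strategy.clause_logic}
    md: dict = {}
    if strategy.metadata.allowed_record_types is not None:
        md["allowed_record_types"] = sorted(strategy.metadata.allowed_record_types)
    if strategy.metadata.day_window is not None:
        md["day_window"] = list(strategy.metadata.day_window)
    if md:
        spec["metadata"] = md
    if strategy.clauses:
        spec["clauses"] = [
            {
                "pattern": c.pattern,
                "polarity": c.polarity,
                "case_sensitive": c.case_sensitive,
            }
            for c in strategy.clauses
        ]
    return spec


def strategy_to_yaml(strategy: SearchStrategy) -> str:
    """Serialize a strategy back to its YAML definition."""
    spec = {"strategy_id": strategy.strategy_id, **_strategy_spec(strategy)}
    return yaml.safe_dump(spec, sort_keys=False)


def compile_strategy(source) -> SearchStrategy:
    """Compile a strategy definition into an executable SearchStrategy.

    ``source`` is a YAML path, file-like object, YAML string, or an
    already-parsed mapping with keys::

        strategy_id: optional (derived deterministically from the content
                     when omitted)
        name: optional free text
        metadata:
          allowed_record_types: [lab-result, imaging-report]   # optional
          day_window: [-365, 0]        # optional; null = unbounded side
        clause_logic: all-required | any-required
        clauses:
          - pattern: "creatinine|GFR"
            polarity: require          # or forbid
            case_sensitive: false
    """
    if isinstance(source, dict):
        spec = source
    else:
        if isinstance(source, (str, os.PathLike)) and os.path.exists(os.fspath(source)):
            with open(source, "r", encoding="utf-8") as fh:
                raw = fh.read()
        elif hasattr(source, "read"):
            raw = source.read()
        else:
            raw = source
        try:
            spec = yaml.safe_load(raw)
        except yaml.YAMLError as exc:
            raise ParseError(f"malformed strategy definition: {exc}") from exc
    if not isinstance(spec, dict):
        raise StrategyCompileError("strategy definition must be a mapping")

    md_spec = spec.get("metadata") or {}
    day_window = md_spec.get("day_window")
    metadata = MetadataCondition(
        allowed_record_types=(
            frozenset(md_spec["allowed_record_types"])
            if md_spec.get("allowed_record_types") is not None
            else None
        ),
        day_window=tuple(day_window) if day_window is not None else None,
    )
    clauses = tuple(
        RegexClause(
            pattern=c["pattern"],
            polarity=c.get("polarity", "require"),
            case_sensitive=bool(c.get("case_sensitive", False)),
        )
        for c in spec.get("clauses") or ()
    )
    strategy_id = spec.get("strategy_id")
    if not strategy_id:
        # content-derived id keeps repeated compilations reproducible
        probe = SearchStrategy(
            strategy_id="probe",
            name=spec.get("name", ""),
            metadata=metadata,
            clauses=clauses,
            clause_logic=spec.get("clause_logic", "all-required"),
        )
        canonical = yaml.safe_dump(_strategy_spec(probe), sort_keys=True)
        strategy_id = str(uuid.uuid5(uuid.NAMESPACE_URL, "emrbench:strategy:" + canonical))
    return SearchStrategy(
        strategy_id=strategy_id,
        name=spec.get("name", ""),
        metadata=metadata,
        clauses=clauses,
        clause_logic=spec.get("clause_logic", "all-required"),
    )


def evaluate_item(strategy: SearchStrategy, item: MedicalRecordItem) -> bool:
    """Hit/no-hit decision for one item.

    Hit iff the metadata condition passes, the require-clauses are satisfied
    under the strategy's clause logic (vacuously satisfied when there are
    none), and no forbid-clause matches. Clauses search the item title and
    text concatenated with a newline.
    """
    if not strategy.metadata.passes(item):
        return False
    haystack = item.title + _FIELD_SEP + item.text
    requires = strategy.require_clauses
    if requires:
        hits = (c.matches(haystack) for c in requires)
        ok = all(hits) if strategy.clause_logic == "all-required" else any(hits)
        if not ok:
            return False
    return not any(c.matches(haystack) for c in strategy.forbid_clauses)


@dataclass(frozen=True)
class ItemResult:
    item_id: str
    hit: bool

    def __post_init__(self) -> None:
        if not self.item_id:
            raise IntegrityError("item_id must be non-empty")


@dataclass
class ScenarioResults:
    scenario_id: str
    results: list[ItemResult] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.item_id for r in self.results]
        if len(set(ids)) != len(ids):
            raise IntegrityError(
                f"duplicate item_result in scenario {self.scenario_id!r}"
            )


@dataclass
class StrategyResultSet:
    """Per-item hit/no-hit decisions of one strategy over one family."""

    family_id: str
    strategy_id: str
    scenarios: list[ScenarioResults] = field(default_factory=list)

    def __post_init__(self) -> None:
        sids = [s.scenario_id for s in self.scenarios]
        if len(set(sids)) != len(sids):
            raise IntegrityError("duplicate scenario_results in result set")

    def for_scenario(self, scenario_id: str) -> ScenarioResults | None:
        for s in self.scenarios:
            if s.scenario_id == scenario_id:
                return s
        return None

    @property
    def n_results(self) -> int:
        return sum(len(s.results) for s in self.scenarios)


def run_strategy(
    strategy: SearchStrategy,
    family: ScenarioFamily,
    scenarios: list[ClinicalScenario],
) -> StrategyResultSet:
    """Evaluate the strategy over every item of every scenario.

    Deterministic: one ItemResult per item, in scenario/item order.
    """
    _check_scenarios_cover_family(family, scenarios)
    return StrategyResultSet(
        family_id=family.family_id,
        strategy_id=strategy.strategy_id,
        scenarios=[
            ScenarioResults(
                scenario_id=s.scenario_id,
                results=[
                    ItemResult(item_id=item.item_id, hit=evaluate_item(strategy, item))
                    for item in s.items
                ],
            )
            for s in scenarios
        ],
    )


def _check_scenarios_cover_family(
    family: ScenarioFamily, scenarios: list[ClinicalScenario]
) -> None:
    got = [s.scenario_id for s in scenarios]
    if got != list(family.scenario_refs):
        raise IntegrityError(
            f"scenario list {got!r} does not match family references "
            f"{family.scenario_refs!r}"
        )


def _check_coverage(
    result_set: StrategyResultSet, scenarios: list[ClinicalScenario]
) -> None:
    """Every item of every scenario covered exactly once."""
    by_id = {s.scenario_id: s for s in scenarios}
    result_sids = {s.scenario_id for s in result_set.scenarios}
    for sid in by_id:
        if sid not in result_sids:
            raise IntegrityError(f"result set missing scenario {sid!r}")
    for scen_results in result_set.scenarios:
        scenario = by_id.get(scen_results.scenario_id)
        if scenario is None:
            raise IntegrityError(
                f"result set references unknown scenario {scen_results.scenario_id!r}"
            )
        expected = set(scenario.item_ids)
        got = {r.item_id for r in scen_results.results}
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise IntegrityError(
                f"result set for scenario {scen_results.scenario_id!r} does not "
                f"cover its items exactly once (missing={missing}, extra={extra})"
            )


# ---------------------------------------------------------------------------
# result-set XML


def _results_element(result_set: StrategyResultSet) -> etree._Element:
    root = etree.Element("strategy_result_set")
    root.set("family_id", result_set.family_id)
    root.set("strategy_id", result_set.strategy_id)
    for scen in result_set.scenarios:
        sel = etree.SubElement(root, "scenario_results")
        sel.set("scenario_id", scen.scenario_id)
        for r in scen.results:
            rel = etree.SubElement(sel, "item_result")
            rel.set("item_id", r.item_id)
            rel.set("hit", "true" if r.hit else "false")
    return root


def read_results(
    source, scenarios: list[ClinicalScenario] | None = None
) -> StrategyResultSet:
    """Read and validate a result-set document.

    When ``scenarios`` is given, the coverage invariant is enforced: every
    item of every scenario appears exactly once.
    """
    root = parse_validated(source, "strategy_result_set.rng")
    result_set = StrategyResultSet(
        family_id=root.get("family_id"),
        strategy_id=root.get("strategy_id"),
        scenarios=[
            ScenarioResults(
                scenario_id=sel.get("scenario_id"),
                results=[
                    ItemResult(item_id=rel.get("item_id"), hit=rel.get("hit") == "true")
                    for rel in sel.findall("item_result")
                ],
            )
            for sel in root.findall("scenario_results")
        ],
    )
    if scenarios is not None:
        _check_coverage(result_set, scenarios)
    return result_set


def results_to_bytes(result_set: StrategyResultSet) -> bytes:
    return serialize(_results_element(result_set))


def write_results(result_set: StrategyResultSet, sink) -> None:
    """Write the canonical result-set document to ``sink``."""
    write_document(_results_element(result_set), sink)
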