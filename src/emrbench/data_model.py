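"""Domain types and XML I/O for clinical scenarios and scenario families.

A *clinical scenario* is one patient's anonymized context for a clinical
task: demographics, the index examination that anchors the task (for example
an MRI of the liver awaiting interpretation), and the medical-record items a
practitioner could consult. Each item carries a controlled-vocabulary record
type and a signed day offset — record date minus index-exam date, so records
that precede the exam are negative. A *scenario family* groups scenarios
that exemplify the same clinical task and is the dataset a search strategy
is validated against.

Both document kinds ship with a RELAX NG schema and are read/written through
a canonical, deterministic serializer (see :mod:`emrbench._xmlio`), so
``read(write(x)) == x`` exactly and repeated writes are byte-identical.
"""
from __future__ import annotations

import warnings
from collections.abc import Callable, Mapping
from dataclasses import dataclass, field

from lxml import etree

from ._xmlio import parse_validated, serialize, write_document
from .errors import IntegrityError, ResolutionError

__all__ = [
    "MedicalRecordItem",
    "IndexExamination",
    "ClinicalScenario",
    "ScenarioFamily",
    "read_scenario",
    "write_scenario",
    "scenario_to_bytes",
    "canonicalize_scenario",
    "read_family",
    "write_family",
    "family_to_bytes",
]


def _require_token(value: str, what: str) -> None:
    if not value or value.split() != [value]:
        raise IntegrityError(f"{what} must be a non-empty whitespace-free token, got {value!r}")


def _require_id(value: str, what: str) -> None:
    if not value:
        raise IntegrityError(f"{what} must be a non-empty identifier")


@dataclass(frozen=True)
class MedicalRecordItem:
    """One anonymized unit of EMR content (note, lab, report...).

    ``days_offset`` is record date minus index-exam date in days; negative
    means the record precedes the index exam. ``text`` may be empty but is
    never absent.
    """

    item_id: str
    record_type: str
    days_offset: int
    title: str = ""
    text: str = ""

    def __post_init__(self) -> None:
        _require_id(self.item_id, "item_id")
        _require_token(self.record_type, "record_type")
        if not isinstance(self.days_offset, int) or isinstance(self.days_offset, bool):
            raise IntegrityError("days_offset must be an integer number of days")


@dataclass(frozen=True)
class IndexExamination:
    """The examination anchoring the clinical task; item day offsets are
    measured relative to it."""

    exam_id: str
    modality: str
    description: str = ""

    def __post_init__(self) -> None:
        _require_id(self.exam_id, "exam_id")
        _require_token(self.modality, "modality")


@dataclass
class ClinicalScenario:
    """One patient's anonymized context: demographics, index exam, items.

    ``demographics`` is an open attribute bag for extra demographic fields
    beyond age and sex (stored as name → value strings).
    """

    scenario_id: str
    patient_age: int
    patient_sex: str
    index_exam: IndexExamination
    items: list[MedicalRecordItem] = field(default_factory=list)
    demographics: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require_id(self.scenario_id, "scenario_id")
        _require_token(self.patient_sex, "patient_sex")
        seen: set[str] = set()
        for item in self.items:
            if item.item_id in seen:
                raise IntegrityError(
                    f"duplicate item_id {item.item_id!r} in scenario {self.scenario_id!r}"
                )
            seen.add(item.item_id)

    @property
    def item_ids(self) -> list[str]:
        return [item.item_id for item in self.items]


@dataclass
class ScenarioFamily:
    """A set of scenarios exemplifying one clinical task."""

    family_id: str
    clinical_context: str
    scenario_refs: list[str]

    def __post_init__(self) -> None:
        _require_id(self.family_id, "family_id")
        if not self.scenario_refs:
            raise IntegrityError("a scenario family must reference at least one scenario")
        if len(set(self.scenario_refs)) != len(self.scenario_refs):
            raise IntegrityError("scenario_refs must be distinct")


# ---------------------------------------------------------------------------
# scenario XML


def _scenario_element(scenario: ClinicalScenario) -> etree._Element:
    root = etree.Element("clinical_scenario")
    root.set("scenario_id", scenario.scenario_id)
    root.set("patient_age", str(scenario.patient_age))
    root.set("patient_sex", scenario.patient_sex)
    for name in sorted(scenario.demographics):
        demo = etree.SubElement(root, "demographic")
        demo.set("name", name)
        demo.set("value", scenario.demographics[name])
    exam = etree.SubElement(root, "index_examination")
    exam.set("exam_id", scenario.index_exam.exam_id)
    exam.set("modality", scenario.index_exam.modality)
    etree.SubElement(exam, "description").text = scenario.index_exam.description or None
    for item in scenario.items:
        el = etree.SubElement(root, "medical_record_item")
        el.set("item_id", item.item_id)
        el.set("record_type", item.record_type)
        el.set("days_offset", str(item.days_offset))
        etree.SubElement(el, "title").text = item.title or None
        etree.SubElement(el, "text").text = item.text or None
    return root


def read_scenario(source) -> ClinicalScenario:
    """Read and validate one clinical-scenario document.

    ``source`` is a filesystem path or a binary file-like object. A scenario
    with zero record items is accepted with a warning (it cannot be rated).
    """
    root = parse_validated(source, "clinical_scenario.rng")
    exam_el = root.find("index_examination")
    exam = IndexExamination(
        exam_id=exam_el.get("exam_id"),
        modality=exam_el.get("modality"),
        description=exam_el.findtext("description") or "",
    )
    items = [
        MedicalRecordItem(
            item_id=el.get("item_id"),
            record_type=el.get("record_type"),
            days_offset=int(el.get("days_offset")),
            title=el.findtext("title") or "",
            text=el.findtext("text") or "",
        )
        for el in root.findall("medical_record_item")
    ]
    scenario = ClinicalScenario(
        scenario_id=root.get("scenario_id"),
        patient_age=int(root.get("patient_age")),
        patient_sex=root.get("patient_sex"),
        index_exam=exam,
        items=items,
        demographics={el.get("name"): el.get("value") for el in root.findall("demographic")},
    )
    if not items:
        warnings.warn(
            f"scenario {scenario.scenario_id!r} contains no medical_record_item elements",
            stacklevel=2,
        )
    return scenario


def scenario_to_bytes(scenario: ClinicalScenario) -> bytes:
    """Canonical serialized form of a scenario."""
    return serialize(_scenario_element(scenario))


def write_scenario(scenario: ClinicalScenario, sink) -> None:
    """Write the canonical scenario document to ``sink`` (path or file-like)."""
    write_document(_scenario_element(scenario), sink)


def canonicalize_scenario(source) -> bytes:
    """Canonical bytes for an existing scenario document (read then re-emit)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return scenario_to_bytes(read_scenario(source))


# ---------------------------------------------------------------------------
# family XML


def _family_element(family: ScenarioFamily) -> etree._Element:
    root = etree.Element("scenario_family")
    root.set("family_id", family.family_id)
    etree.SubElement(root, "clinical_context").text = family.clinical_context or None
    for ref in family.scenario_refs:
        etree.SubElement(root, "scenario_reference").set("scenario_id", ref)
    return root


def read_family(
    family_source,
    scenario_resolver: Mapping[str, object] | Callable[[str], object] | None = None,
) -> tuple[ScenarioFamily, list[ClinicalScenario]]:
    """Read a scenario-family document and resolve its scenario references.

    ``scenario_resolver`` maps a scenario_id to a readable scenario source
    (path or file-like); it may be a mapping or a callable returning None /
    raising KeyError for unknown ids. When omitted, only the family document
    is read and the scenario list is empty.

    Raises ResolutionError listing every missing id if any reference cannot
    be resolved.
    """
    root = parse_validated(family_source, "scenario_family.rng")
    family = ScenarioFamily(
        family_id=root.get("family_id"),
        clinical_context=root.findtext("clinical_context") or "",
        scenario_refs=[el.get("scenario_id") for el in root.findall("scenario_reference")],
    )
    if scenario_resolver is None:
        return family, []

    def _resolve(sid: str):
        if callable(scenario_resolver) and not isinstance(scenario_resolver, Mapping):
            try:
                return scenario_resolver(sid)
            except KeyError:
                return None
        return scenario_resolver.get(sid)

    missing = [sid for sid in family.scenario_refs if _resolve(sid) is None]
    if missing:
        raise ResolutionError(missing)
    scenarios = [read_scenario(_resolve(sid)) for sid in family.scenario_refs]
    for sid, scenario in zip(family.scenario_refs, scenarios):
        if scenario.scenario_id != sid:
            raise IntegrityError(
                f"resolved scenario has id {scenario.scenario_id!r}, expected {sid!r}"
            )
    return family, scenarios


def family_to_bytes(family: ScenarioFamily) -> bytes:
    return serialize(_family_element(family))


def write_family(family: ScenarioFamily, sink) -> None:
    """Write the canonical family document to ``sink``."""
    write_document(_family_element(family), sink)
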