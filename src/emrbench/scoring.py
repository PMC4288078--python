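"""Concordance scoring between strategy results and expert ratings.

The overall score S_total measures agreement between a strategy's hit/miss
decisions and the expert panel's ratings across a scenario family:

    S_total = ( Σ_i Σ_j Σ_k  h_ij · r_ijk ) / ( Σ_i Σ_j Σ_k |r_ijk| )

where i runs over scenarios, j over the items of scenario i, k over the
raters who rated item j; h_ij is +1 when the strategy includes item j of
scenario i as a hit and -1 when it does not; and r_ijk is the k-th rater's
mapped rating (+1, +1/2, -1/2, -1). Dividing by Σ|r| normalizes the score
to [-1, +1]: +1 is perfect agreement with the panel (every hit rated
relevant, every miss irrelevant, at any rating magnitude), -1 perfect
disagreement, 0 no correspondence. A documented variant divides instead by
the count of (scenario, item, rater) triples — a plain mean of h·r that
reaches ±1 only when all ratings are extreme; the two coincide on
all-extreme panels.

S_included applies the same formula restricted to items whose panel
consensus Σ_k r_ijk is positive — how reliably the strategy *includes* what
the experts deem relevant (its "sensitivity") — and S_excluded to items
with negative consensus — how reliably it *excludes* the irrelevant.
Neutral items (consensus exactly 0) count in S_total but in neither
restricted score, and an empty pool leaves its restricted score undefined
(never 0, which has a defined meaning). All arithmetic is exact rational;
scores are emitted with six decimal places in the metrics XML.

The mismatch drill-down surfaces the items whose hit decision contradicts
the panel consensus (h_ij · Σ_k r_ijk < 0), worst first — the exemplars a
strategy designer inspects to refine metadata conditions and patterns.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from fractions import Fraction

from lxml import etree

from ._xmlio import parse_validated, serialize, write_document
from .errors import IntegrityError, MissingDataError, UndefinedScoreError
from .ratings import Pool, ScenarioFamilyRatings, map_rating_label
from .strategy_engine import StrategyResultSet

__all__ = [
    "Normalization",
    "MissingPolicy",
    "MetricsReport",
    "MismatchRecord",
    "score_total",
    "score_included",
    "score_excluded",
    "build_report",
    "mismatch_exemplars",
    "write_metrics",
    "read_metrics",
    "metrics_to_bytes",
]


class Normalization(str, enum.Enum):
    """Denominator variant: sum of |r_ijk| (default) or triple count."""

    ABS = "abs"
    COUNT = "count"


class MissingPolicy(str, enum.Enum):
    """How to treat an unrated (item, rater) pair: skip it, or fail."""

    SKIP = "skip"
    STRICT = "strict"


@dataclass(frozen=True)
class MismatchRecord:
    """An item whose hit decision contradicts the panel consensus."""

    scenario_id: str
    item_id: str
    hit: bool
    rating_sum: Fraction
    contribution: Fraction  # h_ij · Σ_k r_ijk, negative by construction


@dataclass
class MetricsReport:
    """All scores and counts for one (strategy, family) evaluation."""

    family_id: str
    strategy_id: str
    s_total: Fraction
    s_included: Fraction | None
    s_excluded: Fraction | None
    n_scenarios: int
    n_items_total: int
    n_raters_effective: int
    per_scenario_scores: list[tuple[str, Fraction | None]]
    pool_sizes: dict[Pool, int]
    normalization: Normalization = Normalization.ABS
    mismatches: list[MismatchRecord] = field(default_factory=list)


@dataclass(frozen=True)
class _ItemCell:
    """Joined view of one item: hit flag and its raters' mapped values."""

    scenario_id: str
    item_id: str
    h: int  # +1 hit, -1 miss
    values: tuple[Fraction, ...]

    @property
    def rating_sum(self) -> Fraction:
        return sum(self.values, Fraction(0))


def _join(
    results: StrategyResultSet,
    ratings: ScenarioFamilyRatings,
    missing: MissingPolicy,
) -> list[_ItemCell]:
    """Join hit decisions with ratings item by item.

    Under the skip policy an unrated (item, rater) pair simply contributes
    nothing; under strict it raises. Ratings for items absent from the
    result set violate the coverage contract and always raise.
    """
    if results.family_id != ratings.family_id:
        raise IntegrityError(
            f"result set references family {results.family_id!r} but ratings "
            f"reference {ratings.family_id!r}"
        )
    missing = MissingPolicy(missing)
    cells: list[_ItemCell] = []
    result_sids = {s.scenario_id for s in results.scenarios}
    for scen_ratings in ratings.scenarios:
        if scen_ratings.scenario_id not in result_sids:
            raise IntegrityError(
                f"ratings reference scenario {scen_ratings.scenario_id!r} absent "
                "from the result set"
            )
    for scen_results in results.scenarios:
        scen_ratings = ratings.for_scenario(scen_results.scenario_id)
        raters = scen_ratings.raters if scen_ratings is not None else []
        result_item_ids = {r.item_id for r in scen_results.results}
        for rater in raters:
            for r in rater.ratings:
                if r.item_id not in result_item_ids:
                    raise IntegrityError(
                        f"rating references item {r.item_id!r} absent from the "
                        f"result set of scenario {scen_results.scenario_id!r}"
                    )
        for item_result in scen_results.results:
            values = []
            for rater in raters:
                rating = rater.rating_for(item_result.item_id)
                if rating is None:
                    if missing is MissingPolicy.STRICT:
                        raise MissingDataError(
                            f"rater {rater.rater_id!r} has no rating for item "
                            f"{item_result.item_id!r} of scenario "
                            f"{scen_results.scenario_id!r}"
                        )
                    continue
                values.append(map_rating_label(rating.label))
            cells.append(
                _ItemCell(
                    scenario_id=scen_results.scenario_id,
                    item_id=item_result.item_id,
                    h=1 if item_result.hit else -1,
                    values=tuple(values),
                )
            )
    return cells


def _score_cells(
    cells: list[_ItemCell], norm: Normalization
) -> Fraction | None:
    numerator = Fraction(0)
    denominator = Fraction(0)
    for cell in cells:
        for value in cell.values:
            numerator += cell.h * value
            denominator += abs(value) if norm is Normalization.ABS else 1
    if denominator == 0:
        return None
    return numerator / denominator


def score_total(
    results: StrategyResultSet,
    ratings: ScenarioFamilyRatings,
    norm: Normalization | str = Normalization.ABS,
    missing: MissingPolicy | str = MissingPolicy.SKIP,
) -> Fraction:
    """S_total over every rated (scenario, item, rater) triple.

    Raises UndefinedScoreError when no rated pair survives the missing-data
    policy, and IntegrityError when results and ratings reference different
    families.
    """
    cells = _join(results, ratings, MissingPolicy(missing))
    score = _score_cells(cells, Normalization(norm))
    if score is None:
        raise UndefinedScoreError("no rated (item, rater) pairs: S_total is undefined")
    return score


def _restricted(
    results: StrategyResultSet,
    ratings: ScenarioFamilyRatings,
    pool: Pool,
    norm: Normalization,
    missing: MissingPolicy,
) -> Fraction | None:
    cells = _join(results, ratings, missing)
    if not any(cell.values for cell in cells):
        raise UndefinedScoreError("no rated (item, rater) pairs")
    if pool is Pool.INCLUDED:
        selected = [c for c in cells if c.rating_sum > 0]
    else:
        selected = [c for c in cells if c.rating_sum < 0]
    return _score_cells(selected, norm)


def score_included(
    results: StrategyResultSet,
    ratings: ScenarioFamilyRatings,
    norm: Normalization | str = Normalization.ABS,
    missing: MissingPolicy | str = MissingPolicy.SKIP,
) -> Fraction | None:
    """S_total restricted to items with positive consensus (Σ_k r_ijk > 0);
    None when the included-pool is empty."""
    return _restricted(
        results, ratings, Pool.INCLUDED, Normalization(norm), MissingPolicy(missing)
    )


def score_excluded(
    results: StrategyResultSet,
    ratings: ScenarioFamilyRatings,
    norm: Normalization | str = Normalization.ABS,
    missing: MissingPolicy | str = MissingPolicy.SKIP,
) -> Fraction | None:
    """S_total restricted to items with negative consensus (Σ_k r_ijk < 0);
    None when the excluded-pool is empty. A miss on a negative-consensus
    item contributes positively."""
    return _restricted(
        results, ratings, Pool.EXCLUDED, Normalization(norm), MissingPolicy(missing)
    )


def mismatch_exemplars(
    results: StrategyResultSet,
    ratings: ScenarioFamilyRatings,
    top_n: int | None = None,
    missing: MissingPolicy | str = MissingPolicy.SKIP,
) -> list[MismatchRecord]:
    """Items whose hit decision contradicts the consensus, worst first.

    Sorted ascending by contribution h_ij · Σ_k r_ijk (most negative first),
    ties broken by (scenario_id, item_id); at most ``top_n`` records.
    """
    cells = _join(results, ratings, MissingPolicy(missing))
    records = [
        MismatchRecord(
            scenario_id=c.scenario_id,
            item_id=c.item_id,
            hit=c.h > 0,
            rating_sum=c.rating_sum,
            contribution=c.h * c.rating_sum,
        )
        for c in cells
        if c.values and c.h * c.rating_sum < 0
    ]
    records.sort(key=lambda r: (r.contribution, r.scenario_id, r.item_id))
    return records if top_n is None else records[:top_n]


def build_report(
    results: StrategyResultSet,
    ratings: ScenarioFamilyRatings,
    norm: Normalization | str = Normalization.ABS,
    missing: MissingPolicy | str = MissingPolicy.SKIP,
    drill_down: int = 0,
) -> MetricsReport:
    """Full evaluation of one strategy against one panel.

    Per-scenario scores apply the S_total formula to one scenario's cells
    (None for a scenario with no rated pairs). ``drill_down`` > 0 attaches
    that many mismatch exemplars.
    """
    norm = Normalization(norm)
    missing = MissingPolicy(missing)
    cells = _join(results, ratings, missing)
    total = _score_cells(cells, norm)
    if total is None:
        raise UndefinedScoreError("no rated (item, rater) pairs: S_total is undefined")

    rated = [c for c in cells if c.values]
    pool_sizes = {Pool.INCLUDED: 0, Pool.EXCLUDED: 0, Pool.NEUTRAL: 0}
    for cell in rated:
        s = cell.rating_sum
        pool = Pool.INCLUDED if s > 0 else Pool.EXCLUDED if s < 0 else Pool.NEUTRAL
        pool_sizes[pool] += 1

    per_scenario: list[tuple[str, Fraction | None]] = []
    for scen in results.scenarios:
        scen_cells = [c for c in cells if c.scenario_id == scen.scenario_id]
        per_scenario.append((scen.scenario_id, _score_cells(scen_cells, norm)))

    rater_ids = {
        rater.rater_id for scen in ratings.scenarios for rater in scen.raters
    }
    return MetricsReport(
        family_id=results.family_id,
        strategy_id=results.strategy_id,
        s_total=total,
        s_included=_score_cells([c for c in rated if c.rating_sum > 0], norm),
        s_excluded=_score_cells([c for c in rated if c.rating_sum < 0], norm),
        n_scenarios=len(results.scenarios),
        n_items_total=results.n_results,
        n_raters_effective=len(rater_ids),
        per_scenario_scores=per_scenario,
        pool_sizes=pool_sizes,
        normalization=norm,
        mismatches=(
            mismatch_exemplars(results, ratings, top_n=drill_down, missing=missing)
            if drill_down
            else []
        ),
    )


# ---------------------------------------------------------------------------
# metrics XML


def _format_score(value: Fraction) -> str:
    # six fractional digits, half-even never needed: denominators divide 10^6
    # only for the abs norm on half-ratings; round via Fraction for safety
    scaled = round(value * 10**6)
    sign = "-" if scaled < 0 else ""
    scaled = abs(scaled)
    return f"{sign}{scaled // 10**6}.{scaled % 10**6:06d}"


def _score_attrs(el: etree._Element, value: Fraction | None) -> None:
    if value is None:
        el.set("undefined", "true")
    else:
        el.set("value", _format_score(value))


def _metrics_element(report: MetricsReport) -> etree._Element:
    root = etree.Element("metrics_report")
    root.set("family_id", report.family_id)
    root.set("strategy_id", report.strategy_id)
    root.set("normalization", report.normalization.value)
    for tag, value in (
        ("s_total", report.s_total),
        ("s_included", report.s_included),
        ("s_excluded", report.s_excluded),
    ):
        _score_attrs(etree.SubElement(root, tag), value)
    counts = etree.SubElement(root, "counts")
    counts.set("n_scenarios", str(report.n_scenarios))
    counts.set("n_items_total", str(report.n_items_total))
    counts.set("n_raters_effective", str(report.n_raters_effective))
    pools = etree.SubElement(root, "pool_sizes")
    pools.set("included", str(report.pool_sizes[Pool.INCLUDED]))
    pools.set("excluded", str(report.pool_sizes[Pool.EXCLUDED]))
    pools.set("neutral", str(report.pool_sizes[Pool.NEUTRAL]))
    per = etree.SubElement(root, "per_scenario_scores")
    for sid, score in report.per_scenario_scores:
        el = etree.SubElement(per, "scenario_score")
        el.set("scenario_id", sid)
        _score_attrs(el, score)
    if report.mismatches:
        mm = etree.SubElement(root, "mismatch_exemplars")
        for rec in report.mismatches:
            el = etree.SubElement(mm, "mismatch")
            el.set("scenario_id", rec.scenario_id)
            el.set("item_id", rec.item_id)
            el.set("hit", "true" if rec.hit else "false")
            el.set("rating_sum", str(rec.rating_sum))
            el.set("contribution", str(rec.contribution))
    return root


def _parse_score(el: etree._Element) -> Fraction | None:
    if el.get("undefined") == "true":
        return None
    return Fraction(el.get("value"))


def read_metrics(source) -> MetricsReport:
    """Read a metrics document back into a MetricsReport (scores as the
    exact decimal fractions that were emitted)."""
    root = parse_validated(source, "metrics_report.rng")
    pools = root.find("pool_sizes")
    mismatches = [
        MismatchRecord(
            scenario_id=el.get("scenario_id"),
            item_id=el.get("item_id"),
            hit=el.get("hit") == "true",
            rating_sum=Fraction(el.get("rating_sum")),
            contribution=Fraction(el.get("contribution")),
        )
        for el in root.findall("mismatch_exemplars/mismatch")
    ]
    counts = root.find("counts")
    return MetricsReport(
        family_id=root.get("family_id"),
        strategy_id=root.get("strategy_id"),
        s_total=_parse_score(root.find("s_total")),
        s_included=_parse_score(root.find("s_included")),
        s_excluded=_parse_score(root.find("s_excluded")),
        n_scenarios=int(counts.get("n_scenarios")),
        n_items_total=int(counts.get("n_items_total")),
        n_raters_effective=int(counts.get("n_raters_effective")),
        per_scenario_scores=[
            (el.get("scenario_id"), _parse_score(el))
            for el in root.findall("per_scenario_scores/scenario_score")
        ],
        pool_sizes={
            Pool.INCLUDED: int(pools.get("included")),
            Pool.EXCLUDED: int(pools.get("excluded")),
            Pool.NEUTRAL: int(pools.get("neutral")),
        },
        normalization=Normalization(root.get("normalization")),
        mismatches=mismatches,
    )


def metrics_to_bytes(report: MetricsReport) -> bytes:
    return serialize(_metrics_element(report))


def write_metrics(report: MetricsReport, sink) -> None:
    """Write the canonical metrics document to ``sink``."""
    write_document(_metrics_element(report), sink)
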