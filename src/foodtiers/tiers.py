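"""Layered tier assignment, recommendations, and threshold probing.

Six ordered tier labels — III, II-C, II-B, II-A, I-B, I-A — with five gated
ascents. Tier III is the unconditional floor for conventional foods and
beverages and carries no criteria of its own; the criteria at levels 1..5
gate each ascent. A product's label is the highest tier whose gating levels
*all* pass (a not-applicable, out-of-scope criterion counts as passed).
There is no compensation: one failed harm-reduction criterion pins a product
at Tier III no matter how many higher-level positives it collects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib.resources import files
from typing import Optional

from .criteria import (
    Criterion,
    CriterionOutcome,
    ProductContext,
    RatioPredicate,
    ThresholdPredicate,
    evaluate,
)
from .errors import IncompleteEvaluationError, ProbeError
from .product_model import AssumptionRecord
from . import vocabulary

#: total order, lowest first
TIER_LADDER = ["III", "II-C", "II-B", "II-A", "I-B", "I-A"]
N_LEVELS = 5


def tier_rank(label: str) -> int:
    return TIER_LADDER.index(label)


@dataclass(frozen=True)
class Recommendation:
    criterion_id: str
    current_value: Optional[float]
    target_value: Optional[float]
    unit: Optional[str]
    strategy_texts: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "criterion_id": self.criterion_id,
            "current_value": self.current_value,
            "target_value": self.target_value,
            "unit": self.unit,
            "strategy_texts": list(self.strategy_texts),
        }


@dataclass
class TierResult:
    label: str
    per_level_pass: dict[int, bool]
    blocking: list[CriterionOutcome]
    recommendations: list[Recommendation] = field(default_factory=list)
    assumptions: list[AssumptionRecord] = field(default_factory=list)


def assign_tier(
    outcomes: list[CriterionOutcome],
    criteria_set: list[Criterion],
    assumptions: Optional[list[AssumptionRecord]] = None,
) -> TierResult:
    """Assign the tier label from criterion outcomes. No averaging of any kind.

    The label is the highest tier whose gating levels 1..L all pass;
    failures above the first blocked level are recorded in the outcomes but
    do not move the label. Raises :class:`IncompleteEvaluationError` when an
    outcome is missing for any configured criterion.
    """
    by_id = {o.criterion_id: o for o in outcomes}
    missing = [c.id for c in criteria_set if c.id not in by_id]
    if missing:
        raise IncompleteEvaluationError(
            f"outcomes missing for configured criteria: {missing}"
        )
    per_level_pass: dict[int, bool] = {}
    for level in range(1, N_LEVELS + 1):
        level_outcomes = [by_id[c.id] for c in criteria_set if c.level == level]
        per_level_pass[level] = all(o.status != "fail" for o in level_outcomes)
    rank = 0
    for level in range(1, N_LEVELS + 1):
        if per_level_pass[level]:
            rank += 1
        else:
            break
    label = TIER_LADDER[rank]
    blocking: list[CriterionOutcome] = []
    if rank < N_LEVELS:
        first_blocked = rank + 1
        blocking = [
            by_id[c.id]
            for c in criteria_set
            if c.level == first_blocked and by_id[c.id].status == "fail"
        ]
    return TierResult(
        label=label,
        per_level_pass=per_level_pass,
        blocking=blocking,
        assumptions=list(assumptions or []),
    )


# ---------------------------------------------------------------------------
# recommendations

_SUGAR_NUTRIENTS = {"sugar_added", "sugar_total", "sucrose", "glucose", "fructose",
                    "galactose", "lactose"}
_CONTAMINANTS = {"lead", "arsenic", "cadmium", "mercury", "glyphosate"}


def load_strategy_templates() -> dict[str, list[str]]:
    raw = json.loads(files("foodtiers.data").joinpath("strategies.json").read_text())
    return raw["templates"]


def _template_key(criterion: Criterion) -> str:
    pred = criterion.predicate
    if isinstance(pred, ThresholdPredicate):
        n = pred.nutrient
        if n in _SUGAR_NUTRIENTS:
            return "sugar"
        if n == "omega6_total":
            return "omega6"
        if n == "omega3_total":
            return "omega3"
        if n == "fat_trans":
            return "trans-fat"
        if n == "fiber_total":
            return "fiber"
        if n == "sodium":
            return "sodium"
        if n in _CONTAMINANTS:
            return "contaminants"
        if pred.direction == "min":
            return "micronutrient"
        return "default"
    if isinstance(pred, RatioPredicate):
        return "ratio"
    kind = pred.kind
    if kind == "forbid-ingredient":
        return f"concern:{pred.concern_category}"
    if kind == "require-attribute":
        return "attribute"
    if kind == "list-membership":
        return "list"
    return "default"


def recommend(
    tier_result: TierResult,
    criteria_set: list[Criterion],
    templates: Optional[dict[str, list[str]]] = None,
) -> list[Recommendation]:
    """One recommendation per blocking outcome at the next gated level.

    Numeric targets are set to the criterion boundary; strategy texts are
    drawn from the template registry by nutrient/concern topic. An I-A
    product yields an empty list.
    """
    if templates is None:
        templates = load_strategy_templates()
    if not tier_result.blocking:
        return []
    by_id = {c.id: c for c in criteria_set}
    recs: list[Recommendation] = []
    for outcome in tier_result.blocking:
        criterion = by_id[outcome.criterion_id]
        key = _template_key(criterion)
        texts = templates.get(key)
        if texts is None and key.startswith("concern:"):
            texts = templates.get("additives")
        if texts is None:
            texts = templates.get("default", [])
        target = None
        unit = None
        pred = criterion.predicate
        if isinstance(pred, ThresholdPredicate):
            unit = vocabulary.canonical_unit(pred.nutrient)
            target = vocabulary.convert(pred.value, pred.unit, unit, pred.nutrient)
        elif isinstance(pred, RatioPredicate):
            target = pred.max_value
        recs.append(
            Recommendation(
                criterion_id=criterion.id,
                current_value=outcome.measured_value,
                target_value=target,
                unit=unit,
                strategy_texts=tuple(texts),
            )
        )
    return recs


# ---------------------------------------------------------------------------
# threshold probing (verification instrument)


def probe_threshold(
    criterion: Criterion,
    ctx: ProductContext,
    nutrient_id: str,
    low: float,
    high: float,
    tolerance: float = 1e-6,
) -> float:
    """Recover a criterion's pass/fail boundary by bisection.

    Varies ``nutrient_id`` in the product's resolved profile over
    [low, high]; requires the criterion verdict to differ at the endpoints
    (otherwise :class:`ProbeError`). Returns the boundary to within
    ``tolerance``.
    """
    if low >= high:
        raise ProbeError(f"invalid probe interval [{low}, {high}]")

    def passes(x: float) -> bool:
        return evaluate(ctx.with_nutrient(nutrient_id, x), criterion).status == "pass"

    lo_pass = passes(low)
    hi_pass = passes(high)
    if lo_pass == hi_pass:
        raise ProbeError(
            f"criterion {criterion.id!r} verdict does not change over "
            f"[{low}, {high}] when varying {nutrient_id!r}"
        )
    lo, hi = low, high
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if passes(mid) == lo_pass:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
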