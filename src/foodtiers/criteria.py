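"""Declarative criterion model and evaluator.

Each criterion is one rule — a nutrient threshold on a serving or per-100g
basis, a nutrient ratio cap, an ingredient prohibition filtered by concern
category and confidence, a required product attribute, or membership on a
named inclusion/exclusion list — and evaluates to a fully explained
pass/fail/not-applicable outcome. There is deliberately no numeric scoring
and no averaging anywhere: positive attributes can never compensate for a
failed rule, and every verdict carries the measured value and threshold that
produced it.

Boundary conventions follow the rule phrasings: "more than X" caps fail
strictly above X (X itself passes), "at least X" floors pass at X. A missing
nutrient measurement fails the criterion (conservatively, with an explicit
"value unavailable" explanation) rather than passing silently.
"""

from __future__ import annotations

import json
from bisect import bisect_left
from dataclasses import dataclass
from enum import Enum
from importlib.resources import files
from typing import Annotated, Literal, Optional, Union

from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import vocabulary
from .errors import ConfigurationError
from .lexicon import CONFIDENCE_RANK, Lexicon, ParsedIngredient
from .product_model import NutrientProfile, Product


class Pillar(str, Enum):
    FEED_GUT = "feed-gut"
    PROTECT_LIVER = "protect-liver"
    SUPPORT_BRAIN = "support-brain"
    TRANSPARENCY = "transparency"
    SUSTAINABILITY = "sustainability"


class ThresholdPredicate(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["threshold"]
    nutrient: str
    direction: Literal["max", "min"]
    value: float = Field(ge=0.0)
    unit: str
    basis: Literal["per-serving", "per-100g"] = "per-serving"
    inclusive: bool = True


class RatioPredicate(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["ratio"]
    numerator: str
    denominator: str
    max_value: float = Field(gt=0.0)


class ForbidIngredientPredicate(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["forbid-ingredient"]
    target: str
    target_kind: Literal["group", "canonical"] = "group"
    concern_category: str
    min_confidence: Literal["established", "probable", "suspected"] = "probable"


class RequireAttributePredicate(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["require-attribute"]
    attribute: str


class ListMembershipPredicate(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["list-membership"]
    list_id: str
    mode: Literal["include", "exclude"]


Predicate = Annotated[
    Union[
        ThresholdPredicate,
        RatioPredicate,
        ForbidIngredientPredicate,
        RequireAttributePredicate,
        ListMembershipPredicate,
    ],
    Field(discriminator="kind"),
]


class Criterion(BaseModel):
    model_config = ConfigDict(extra="ignore")

    id: str
    label: str
    level: int = Field(ge=1, le=5)
    pillar: Pillar
    scope: list[str] = Field(default_factory=list)  # empty = all categories
    predicate: Predicate
    normative: bool = False

    @model_validator(mode="after")
    def _check_nutrients(self):
        pred = self.predicate
        refs = []
        if isinstance(pred, ThresholdPredicate):
            refs = [pred.nutrient]
        elif isinstance(pred, RatioPredicate):
            refs = [pred.numerator, pred.denominator]
        unknown = [n for n in refs if not vocabulary.is_known(n)]
        if unknown:
            raise ValueError(
                f"criterion {self.id!r} references nutrient ids outside the "
                f"controlled vocabulary: {unknown}"
            )
        return self


@dataclass(frozen=True)
class CriterionOutcome:
    criterion_id: str
    level: int
    status: str  # "pass" | "fail" | "not-applicable"
    explanation: str
    measured_value: Optional[float] = None
    unit: Optional[str] = None
    threshold: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "criterion_id": self.criterion_id,
            "level": self.level,
            "status": self.status,
            "measured_value": self.measured_value,
            "unit": self.unit,
            "threshold": self.threshold,
            "explanation": self.explanation,
        }


@dataclass
class ProductContext:
    """Everything a criterion needs: the product, its resolved per-serving
    profile, its parsed ingredient statement, the lexicon, and the named
    product-id lists from the active configuration."""

    product: Product
    profile: NutrientProfile
    parsed_ingredients: list[ParsedIngredient]
    lexicon: Lexicon
    lists: dict[str, list[str]]

    def with_nutrient(self, nutrient_id: str, value: float) -> "ProductContext":
        q = dict(self.profile.quantities)
        q[nutrient_id] = value
        return ProductContext(
            product=self.product,
            profile=NutrientProfile(basis=self.profile.basis, quantities=q),
            parsed_ingredients=self.parsed_ingredients,
            lexicon=self.lexicon,
            lists=self.lists,
        )


# ---------------------------------------------------------------------------
# evaluation


def _scope_check(ctx: ProductContext, criterion: Criterion) -> Optional[CriterionOutcome]:
    if criterion.scope and ctx.product.category.value not in criterion.scope:
        return CriterionOutcome(
            criterion_id=criterion.id,
            level=criterion.level,
            status="not-applicable",
            explanation=(
                f"category {ctx.product.category.value!r} is outside the "
                f"criterion scope {criterion.scope}"
            ),
        )
    return None


def _eval_threshold(ctx: ProductContext, criterion: Criterion) -> CriterionOutcome:
    pred: ThresholdPredicate = criterion.predicate  # type: ignore[assignment]
    canonical = vocabulary.canonical_unit(pred.nutrient)
    limit = vocabulary.convert(pred.value, pred.unit, canonical, pred.nutrient)
    raw = ctx.profile.get(pred.nutrient)
    if raw is None:
        return CriterionOutcome(
            criterion_id=criterion.id,
            level=criterion.level,
            status="fail",
            threshold=limit,
            unit=canonical,
            explanation=(
                f"value unavailable: {pred.nutrient} was not measured or declared; "
                f"the rule ({pred.direction} {limit:g} {canonical} {pred.basis}) "
                f"fails conservatively"
            ),
        )
    if pred.basis == "per-100g":
        value = raw / ctx.product.serving_size * 100.0
        basis_note = f"per 100{ctx.product.serving_unit}"
    else:
        value = raw
        basis_note = "per serving"
    if pred.direction == "max":
        ok = value <= limit if pred.inclusive else value < limit
        relation = "at most" if pred.inclusive else "strictly below"
    else:
        ok = value >= limit if pred.inclusive else value > limit
        relation = "at least" if pred.inclusive else "strictly above"
    status = "pass" if ok else "fail"
    return CriterionOutcome(
        criterion_id=criterion.id,
        level=criterion.level,
        status=status,
        measured_value=value,
        unit=canonical,
        threshold=limit,
        explanation=(
            f"{pred.nutrient} = {value:g} {canonical} {basis_note}; rule requires "
            f"{relation} {limit:g} {canonical}; {status}"
        ),
    )


def _eval_ratio(ctx: ProductContext, criterion: Criterion) -> CriterionOutcome:
    pred: RatioPredicate = criterion.predicate  # type: ignore[assignment]
    num = ctx.profile.get(pred.numerator)
    den = ctx.profile.get(pred.denominator)
    if num is None or den is None:
        missing = [n for n, v in ((pred.numerator, num), (pred.denominator, den)) if v is None]
        return CriterionOutcome(
            criterion_id=criterion.id,
            level=criterion.level,
            status="fail",
            threshold=pred.max_value,
            explanation=(
                f"value unavailable: {', '.join(missing)} not measured or declared; "
                f"the ratio rule (max {pred.max_value:g}) fails conservatively"
            ),
        )
    if den == 0.0:
        if num == 0.0:
            return CriterionOutcome(
                criterion_id=criterion.id,
                level=criterion.level,
                status="pass",
                measured_value=0.0,
                threshold=pred.max_value,
                explanation=(
                    f"{pred.numerator} and {pred.denominator} are both 0; the "
                    f"ratio cap of {pred.max_value:g} holds vacuously; pass"
                ),
            )
        return CriterionOutcome(
            criterion_id=criterion.id,
            level=criterion.level,
            status="fail",
            threshold=pred.max_value,
            explanation=(
                f"{pred.numerator} = {num:g} with {pred.denominator} = 0: the "
                f"ratio is unbounded and exceeds the cap of {pred.max_value:g}; fail"
            ),
        )
    ratio = num / den
    status = "pass" if ratio <= pred.max_value else "fail"
    return CriterionOutcome(
        criterion_id=criterion.id,
        level=criterion.level,
        status=status,
        measured_value=ratio,
        threshold=pred.max_value,
        explanation=(
            f"{pred.numerator}:{pred.denominator} = {num:g}:{den:g} = {ratio:g}; "
            f"rule requires no more than {pred.max_value:g}; {status}"
        ),
    )


def _eval_forbid(ctx: ProductContext, criterion: Criterion) -> CriterionOutcome:
    pred: ForbidIngredientPredicate = criterion.predicate  # type: ignore[assignment]
    min_rank = CONFIDENCE_RANK[pred.min_confidence]
    violations: list[str] = []
    for entry in ctx.parsed_ingredients:
        for item in entry.flatten():
            cid = item.canonical_id
            if cid is None:
                continue
            if pred.target_kind == "canonical":
                matched = cid == pred.target
            else:
                matched = pred.target in ctx.lexicon.classify_groups(cid)
            if not matched:
                continue
            concern = ctx.lexicon.concern_for(cid, pred.concern_category)
            if concern is None or CONFIDENCE_RANK[concern.confidence] < min_rank:
                continue
            whitelist = ctx.lists.get(f"whitelist:{pred.concern_category}", [])
            status = ctx.lexicon.resolve_concern(
                item, pred.concern_category, whitelist, ctx.product.id
            )
            if status in ("offending", "potentially-offending"):
                violations.append(
                    f"{item.raw_span!r} -> {cid} ({status}, {concern.confidence})"
                )
    if violations:
        return CriterionOutcome(
            criterion_id=criterion.id,
            level=criterion.level,
            status="fail",
            explanation=(
                f"forbidden {pred.target_kind} {pred.target!r} "
                f"[{pred.concern_category}, confidence >= {pred.min_confidence}] "
                f"matched: {'; '.join(violations)}; fail"
            ),
        )
    return CriterionOutcome(
        criterion_id=criterion.id,
        level=criterion.level,
        status="pass",
        explanation=(
            f"no ingredient matched the forbidden {pred.target_kind} "
            f"{pred.target!r} with an effective {pred.concern_category} status at "
            f"confidence >= {pred.min_confidence}; pass"
        ),
    )


def _eval_attribute(ctx: ProductContext, criterion: Criterion) -> CriterionOutcome:
    pred: RequireAttributePredicate = criterion.predicate  # type: ignore[assignment]
    claims = {c.strip().lower() for c in ctx.product.claims}
    present = pred.attribute.lower() in claims
    status = "pass" if present else "fail"
    verb = "is declared" if present else "is not declared"
    return CriterionOutcome(
        criterion_id=criterion.id,
        level=criterion.level,
        status=status,
        explanation=f"required attribute {pred.attribute!r} {verb} on the product; {status}",
    )


def _eval_list(ctx: ProductContext, criterion: Criterion) -> CriterionOutcome:
    pred: ListMembershipPredicate = criterion.predicate  # type: ignore[assignment]
    if pred.list_id not in ctx.lists:
        raise ConfigurationError(
            [f"criterion {criterion.id!r} references unknown list {pred.list_id!r}"]
        )
    member = ctx.product.id in ctx.lists[pred.list_id]
    ok = member if pred.mode == "include" else not member
    status = "pass" if ok else "fail"
    membership = "is" if member else "is not"
    return CriterionOutcome(
        criterion_id=criterion.id,
        level=criterion.level,
        status=status,
        explanation=(
            f"product id {ctx.product.id!r} {membership} on list {pred.list_id!r} "
            f"(mode {pred.mode}); {status}"
        ),
    )


_DISPATCH = {
    "threshold": _eval_threshold,
    "ratio": _eval_ratio,
    "forbid-ingredient": _eval_forbid,
    "require-attribute": _eval_attribute,
    "list-membership": _eval_list,
}


def evaluate(ctx: ProductContext, criterion: Criterion) -> CriterionOutcome:
    """Evaluate one criterion against a resolved product. Pure and deterministic."""
    scoped = _scope_check(ctx, criterion)
    if scoped is not None:
        return scoped
    return _DISPATCH[criterion.predicate.kind](ctx, criterion)


def evaluate_all(
    ctx: ProductContext, criteria_set: list[Criterion]
) -> list[CriterionOutcome]:
    """One outcome per criterion, order preserved; duplicate ids are a
    configuration error."""
    seen: set[str] = set()
    dupes = []
    for c in criteria_set:
        if c.id in seen:
            dupes.append(c.id)
        seen.add(c.id)
    if dupes:
        raise ConfigurationError([f"duplicate criterion id {d!r}" for d in dupes])
    return [evaluate(ctx, c) for c in criteria_set]


# ---------------------------------------------------------------------------
# calculated ratings (pluggable front-of-pack demonstrations)


class RatingBand(BaseModel):
    model_config = ConfigDict(extra="forbid")

    nutrient: str
    basis: Literal["per-serving", "per-100g"]
    cut_points: list[float]
    labels: list[str]

    @model_validator(mode="after")
    def _check(self):
        if sorted(self.cut_points) != self.cut_points or len(
            set(self.cut_points)
        ) != len(self.cut_points):
            raise ValueError("cut points must be strictly increasing")
        if len(self.labels) != len(self.cut_points) + 1:
            raise ValueError("need exactly one more label than cut points")
        return self


class RatingSystemConfig(BaseModel):
    model_config = ConfigDict(extra="ignore")

    name: str
    bands: list[RatingBand]

    @classmethod
    def load_demo(cls) -> "RatingSystemConfig":
        return cls.model_validate_json(
            files("foodtiers.data").joinpath("ratings.traffic_light.json").read_text()
        )


def compute_rating(ctx: ProductContext, config: RatingSystemConfig) -> dict[str, str]:
    """Per-nutrient interval-lookup rating, independent of the tier ladder.

    A value exactly on a cut point takes the lower band. Missing nutrients
    rate as "unrated".
    """
    out: dict[str, str] = {}
    for band in config.bands:
        raw = ctx.profile.get(band.nutrient)
        if raw is None:
            out[band.nutrient] = "unrated"
            continue
        value = raw
        if band.basis == "per-100g":
            value = raw / ctx.product.serving_size * 100.0
        out[band.nutrient] = band.labels[bisect_left(band.cut_points, value)]
    return out


def load_criteria(text: str) -> list[Criterion]:
    """Parse a JSON list of criterion records, reporting every violation."""
    raw = json.loads(text)
    violations: list[str] = []
    criteria: list[Criterion] = []
    for i, rec in enumerate(raw):
        try:
            criteria.append(Criterion.model_validate(rec))
        except Exception as exc:  # pydantic ValidationError
            violations.append(f"criteria[{i}]: {exc}")
    if violations:
        raise ConfigurationError(violations)
    return criteria
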