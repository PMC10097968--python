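"""Per-product evaluation reports and the portfolio overview table.

Each product gets a criterion-by-criterion report (JSON canonical form plus
a deterministic Markdown rendering) containing the tier label, blocking
criteria listed first, recommendations, and the assumption log. The overview
is one CSV row per product combining identity, outcome statuses and measured
values, and the tier label — deliberately excluding recommendations and
assumptions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .engine import ProductEvaluation
from .errors import ReportError


@dataclass
class ProductReport:
    product_id: str
    product_name: str
    category: str
    serving_size: float
    serving_unit: str
    tier: str
    outcome_rows: list[dict]  # blocking outcomes first, then matrix order
    recommendations: list[dict]
    assumptions: list[dict]
    allergens: list[str]
    unknown_ingredients: list[str]
    warnings: list[str]
    engine_version: str = ""
    config_version: str = ""
    extra: dict = field(default_factory=dict)

    # -- serialization ------------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "product_id": self.product_id,
            "product_name": self.product_name,
            "category": self.category,
            "serving_size": self.serving_size,
            "serving_unit": self.serving_unit,
            "tier": self.tier,
            "outcomes": self.outcome_rows,
            "recommendations": self.recommendations,
            "assumptions": self.assumptions,
            "allergens": self.allergens,
            "unknown_ingredients": self.unknown_ingredients,
            "warnings": self.warnings,
            "engine_version": self.engine_version,
            "config_version": self.config_version,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), indent=2, sort_keys=False)

    @classmethod
    def from_json(cls, text: str) -> "ProductReport":
        raw = json.loads(text)
        return cls(
            product_id=raw["product_id"],
            product_name=raw["product_name"],
            category=raw["category"],
            serving_size=raw["serving_size"],
            serving_unit=raw["serving_unit"],
            tier=raw["tier"],
            outcome_rows=raw["outcomes"],
            recommendations=raw["recommendations"],
            assumptions=raw["assumptions"],
            allergens=raw["allergens"],
            unknown_ingredients=raw["unknown_ingredients"],
            warnings=raw["warnings"],
            engine_version=raw["engine_version"],
            config_version=raw["config_version"],
        )

    def to_markdown(self) -> str:
        lines = [
            f"# Product report: {self.product_name} ({self.product_id})",
            "",
            f"- Category: {self.category}",
            f"- Serving size: {self.serving_size:g} {self.serving_unit}",
            f"- **Tier: {self.tier}**",
            f"- Engine {self.engine_version}, configuration {self.config_version}",
            "",
            "## Criteria",
            "",
            "| Criterion | Level | Status | Measured | Threshold | Explanation |",
            "|---|---|---|---|---|---|",
        ]
        for row in self.outcome_rows:
            measured = "" if row["measured_value"] is None else f"{row['measured_value']:g}"
            threshold = "" if row["threshold"] is None else f"{row['threshold']:g}"
            unit = row["unit"] or ""
            expl = row["explanation"].replace("|", "\\|")
            lines.append(
                f"| {row['criterion_id']} | {row['level']} | {row['status']} "
                f"| {measured} {unit} | {threshold} {unit} | {expl} |"
            )
        lines += ["", "## Recommendations", ""]
        if not self.recommendations:
            lines.append("None — the product already satisfies every configured criterion.")
        for rec in self.recommendations:
            cur = "" if rec["current_value"] is None else f"{rec['current_value']:g}"
            tgt = "" if rec["target_value"] is None else f"{rec['target_value']:g}"
            unit = rec["unit"] or ""
            lines.append(f"- **{rec['criterion_id']}** (current {cur} {unit}, target {tgt} {unit})")
            for s in rec["strategy_texts"]:
                lines.append(f"  - {s}")
        lines += ["", "## Assumptions", ""]
        if not self.assumptions:
            lines.append("None.")
        for a in self.assumptions:
            lines.append(
                f"- component `{a['component_id']}`: reference entry "
                f"`{a['reference_entry_id']}` substituted ({len(a['substituted_fields'])} "
                f"nutrients). {a['note']}"
            )
        lines += ["", "## Allergens", ""]
        lines.append(", ".join(sorted(self.allergens)) if self.allergens else "None detected.")
        if self.unknown_ingredients:
            lines += ["", "## Unrecognized ingredients", ""]
            for u in self.unknown_ingredients:
                lines.append(f"- {u}")
        if self.warnings:
            lines += ["", "## Warnings", ""]
            for w in self.warnings:
                lines.append(f"- {w}")
        return "\n".join(lines) + "\n"


def render_report(evaluation: ProductEvaluation, engine_version: str,
                  config_version: str) -> ProductReport:
    """Build the report for one evaluated product (blocking criteria first)."""
    if not evaluation.outcomes:
        raise ReportError("evaluation has no criterion outcomes")
    blocking_ids = {o.criterion_id for o in evaluation.tier.blocking}
    ordered = [o for o in evaluation.outcomes if o.criterion_id in blocking_ids] + [
        o for o in evaluation.outcomes if o.criterion_id not in blocking_ids
    ]
    product = evaluation.product
    return ProductReport(
        product_id=product.id,
        product_name=product.name,
        category=product.category.value,
        serving_size=product.serving_size,
        serving_unit=product.serving_unit,
        tier=evaluation.tier.label,
        outcome_rows=[o.to_dict() for o in ordered],
        recommendations=[r.to_dict() for r in evaluation.tier.recommendations],
        assumptions=[a.to_dict() for a in evaluation.assumptions],
        allergens=sorted(evaluation.allergens),
        unknown_ingredients=evaluation.unknown_ingredients,
        warnings=list(evaluation.resolution_warnings),
        engine_version=engine_version,
        config_version=config_version,
    )


def render_overview(reports: list[ProductReport]) -> pd.DataFrame:
    """Combine reports into one overview table (no recommendations, no
    assumptions). All reports must come from the same configuration version."""
    if not reports:
        raise ReportError("no reports to combine")
    versions = {r.config_version for r in reports}
    if len(versions) > 1:
        raise ReportError(
            f"reports span multiple configuration versions {sorted(versions)}; "
            f"rows would not be comparable"
        )
    # stable criterion order: (level, matrix position) from the first report,
    # which lists blocking first — re-sort by (level, id) for stability
    ids = sorted(
        ((row["level"], row["criterion_id"]) for row in reports[0].outcome_rows)
    )
    ordered_ids = [cid for _, cid in ids]
    rows = []
    for rep in reports:
        by_id = {row["criterion_id"]: row for row in rep.outcome_rows}
        if set(by_id) != set(ordered_ids):
            raise ReportError(
                f"report {rep.product_id!r} covers a different criterion set"
            )
        row: dict = {
            "product_id": rep.product_id,
            "product_name": rep.product_name,
            "category": rep.category,
            "serving_size": rep.serving_size,
            "serving_unit": rep.serving_unit,
            "tier": rep.tier,
            "allergens": ";".join(rep.allergens),
        }
        for cid in ordered_ids:
            row[f"{cid}.status"] = by_id[cid]["status"]
            row[f"{cid}.value"] = by_id[cid]["measured_value"]
        rows.append(row)
    return pd.DataFrame(rows)


def write_overview_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")
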