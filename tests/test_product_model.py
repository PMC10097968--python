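"""Product ingestion, validation, unit conversion, and nutrient rollup."""

import json
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foodtiers.errors import (
    ParseError,
    ProductValidationError,
    SchemaValidationError,
    UnresolvableComponentError,
    UnsupportedConversionError,
)
from foodtiers.product_model import (
    NutrientProfile,
    Product,
    ReferenceRegistry,
    convert,
    load_product,
    resolve_profile,
    validate_product,
)


def doc(**over):
    base = {
        "id": "p1",
        "name": "test product",
        "category": "juice",
        "serving_size": 200,
        "serving_unit": "mL",
        "declared_profile": {
            "basis": "per-serving",
            "quantities": {"sugar_total": 10.0, "fructose": 5.0, "glucose": 5.0},
        },
    }
    base.update(over)
    return base


def two_component_doc(frac_a=0.5, frac_b=0.5, sugar_a=10.0, sugar_b=0.0):
    return doc(
        declared_profile=None,
        components=[
            {
                "id": "a", "name": "part a", "mass_fraction": frac_a,
                "profile": {"basis": "per-100g", "quantities": {"sugar_total": sugar_a}},
            },
            {
                "id": "b", "name": "part b", "mass_fraction": frac_b,
                "profile": {"basis": "per-100g", "quantities": {"sugar_total": sugar_b}},
            },
        ],
    )


class TestLoadProduct:
    def test_minimal_document_loads_with_empty_components(self):
        product = load_product(json.dumps(doc()))
        assert product.components == []
        assert product.category.value == "juice"

    def test_malformed_json_reports_byte_offset(self):
        with pytest.raises(ParseError) as exc:
            load_product('{"id": "p1", }')
        assert exc.value.offset is not None
        assert "byte offset" in str(exc.value)

    def test_schema_errors_list_every_violated_path(self):
        bad = doc()
        bad["serving_size"] = -1
        bad["category"] = "frozen-pizza"
        with pytest.raises(SchemaValidationError) as exc:
            load_product(json.dumps(bad))
        joined = "\n".join(exc.value.violations)
        assert "serving_size" in joined and "category" in joined
        assert len(exc.value.violations) >= 2

    def test_sibling_fractions_not_summing_to_one_names_parent(self):
        bad = two_component_doc(frac_a=0.5, frac_b=0.3)
        with pytest.raises(ProductValidationError) as exc:
            load_product(json.dumps(bad))
        finding = exc.value.findings[0]
        assert finding.rule == "mass-fraction-sum"
        assert "test product" in finding.message

    def test_nested_components_load_with_depth_two(self):
        nested = doc(
            declared_profile=None,
            components=[{
                "id": "juice-blend", "name": "juice blend", "mass_fraction": 1.0,
                "subcomponents": [{
                    "id": "gjc", "name": "grape juice concentrate",
                    "mass_fraction": 1.0,
                    "profile": {"basis": "per-100g", "quantities": {"sugar_total": 52.0}},
                }],
            }],
        )
        product = load_product(json.dumps(nested))
        assert product.components[0].subcomponents[0].profile is not None

    def test_unknown_nutrient_ids_rejected(self):
        bad = doc(declared_profile={"basis": "per-serving",
                                    "quantities": {"unobtainium": 1.0}})
        with pytest.raises(SchemaValidationError) as exc:
            load_product(json.dumps(bad))
        assert "unobtainium" in str(exc.value)

    def test_unknown_top_level_keys_preserved_but_ignored(self):
        product = load_product(json.dumps(doc(marketing_blurb="tasty")))
        assert product.model_dump()["marketing_blurb"] == "tasty"


class TestValidateProduct:
    def test_consistent_product_yields_no_findings(self):
        assert validate_product(load_product(json.dumps(doc()))) == []

    def test_species_sum_violation_names_the_rule(self):
        profile = NutrientProfile(
            basis="per-serving",
            quantities={"sugar_total": 5.0, "fructose": 4.0, "glucose": 3.0},
        )
        product = Product.model_validate(doc())
        product.declared_profile = profile
        findings = validate_product(product)
        assert [f.rule for f in findings] == ["species-sum:sugar_total"]

    def test_species_sum_tolerates_five_percent(self):
        profile = {"basis": "per-serving",
                   "quantities": {"sugar_total": 10.0, "fructose": 10.4}}
        assert validate_product(load_product(json.dumps(doc(declared_profile=profile)))) == []

    def test_pint_declaring_sixteen_servings_warns_on_portion(self):
        d = doc(serving_size=473 / 16, servings_per_package=16)
        findings = validate_product(load_product(json.dumps(d)))
        assert [f.rule for f in findings] == ["portion-plausibility"]
        assert findings[0].severity == "warning"

    def test_validation_is_total_over_broken_fixtures(self):
        broken = [
            doc(declared_profile=None),  # no profile at all
            two_component_doc(frac_a=0.9, frac_b=0.3),
            doc(declared_profile={"basis": "per-serving",
                                  "quantities": {"fat_total": 1.0, "fat_saturated": 2.0}}),
        ]
        for d in broken:
            findings = validate_product(Product.model_validate(d))
            assert any(f.severity == "error" for f in findings)


class TestConvert:
    @pytest.mark.parametrize(
        "amount,src,dst,nutrient,expected",
        [
            (400.0, "IU", "ug", "vitamin_d", 10.0),
            (1.0, "tsp", "g", "sugar_added", 4.2),
            (7.0, "g", "g", "protein", 7.0),
            (1000.0, "mg", "g", "calcium", 1.0),
            (140.0, "mg", "g-salt", "sodium", 0.35),
        ],
    )
    def test_conversion_constants(self, amount, src, dst, nutrient, expected):
        assert convert(amount, src, dst, nutrient) == pytest.approx(expected)

    @given(st.floats(min_value=1e-6, max_value=1e6, allow_nan=False))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip_identity(self, amount):
        for src, dst, nutrient in [("IU", "ug", "vitamin_d"), ("tsp", "g", "sugar_added"),
                                   ("mg", "g-salt", "sodium")]:
            back = convert(convert(amount, src, dst, nutrient), dst, src, nutrient)
            assert math.isclose(back, amount, rel_tol=1e-12)

    def test_undefined_pair_raises(self):
        with pytest.raises(UnsupportedConversionError):
            convert(1.0, "IU", "ug", "calcium")


class TestResolveProfile:
    def test_linear_mixing_of_two_components(self, references):
        product = load_product(json.dumps(two_component_doc()))
        result = resolve_profile(product, references)
        # 0.5*10/100 g/g * 200 g serving = 10 g
        assert result.profile.quantities["sugar_total"] == pytest.approx(10.0)
        assert result.assumptions == []

    def test_reference_substitution_logs_one_assumption(self, references):
        d = doc(
            declared_profile=None,
            components=[
                {"id": "gj", "name": "Grape Juice", "mass_fraction": 0.5},
                {"id": "w", "name": "water", "mass_fraction": 0.5},
            ],
        )
        result = resolve_profile(load_product(json.dumps(d)), references)
        by_component = {a.component_id: a for a in result.assumptions}
        assert set(by_component) == {"gj", "w"}
        assert by_component["gj"].reference_entry_id == "grape-juice"
        assert len(by_component["gj"].substituted_fields) > 0

    def test_unresolvable_component_names_it(self, references):
        d = doc(declared_profile=None,
                components=[{"id": "x", "name": "mystery paste", "mass_fraction": 1.0}])
        with pytest.raises(UnresolvableComponentError) as exc:
            resolve_profile(load_product(json.dumps(d)), references)
        assert "mystery paste" in str(exc.value)

    def test_declared_wins_with_conflict_warning(self, references):
        d = two_component_doc()
        d["declared_profile"] = {"basis": "per-serving",
                                 "quantities": {"sugar_total": 5.0}}
        result = resolve_profile(load_product(json.dumps(d)), references)
        assert result.profile.quantities["sugar_total"] == 5.0
        assert any("sugar_total" in w for w in result.warnings)

    def test_per_100g_declared_panel_rescales_by_serving(self, references):
        d = doc(declared_profile={"basis": "per-100g",
                                  "quantities": {"sugar_total": 5.0}})
        result = resolve_profile(load_product(json.dumps(d)), references)
        assert result.profile.quantities["sugar_total"] == pytest.approx(10.0)

    def test_single_full_fraction_component_conserves_profile(self, references):
        d = doc(
            declared_profile=None,
            serving_size=100,
            components=[{
                "id": "only", "name": "only part", "mass_fraction": 1.0,
                "profile": {"basis": "per-100g",
                            "quantities": {"protein": 3.25, "sodium": 44.0}},
            }],
        )
        result = resolve_profile(load_product(json.dumps(d)), references)
        assert result.profile.quantities == {"protein": 3.25, "sodium": 44.0}

    @given(p=st.floats(min_value=0.0, max_value=1.0),
           a=st.floats(min_value=0.0, max_value=50.0),
           b=st.floats(min_value=0.0, max_value=50.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_rollup_linearity(self, references, p, a, b):
        d = two_component_doc(frac_a=p, frac_b=1.0 - p, sugar_a=a, sugar_b=b)
        result = resolve_profile(Product.model_validate(d), references)
        expected = (p * a + (1.0 - p) * b) / 100.0 * 200.0
        got = result.profile.quantities.get("sugar_total", 0.0)
        assert math.isclose(got, expected, rel_tol=1e-9, abs_tol=1e-9)

    def test_assumption_count_matches_substituted_components(self, references):
        d = doc(
            declared_profile=None,
            components=[
                {"id": "w1", "name": "water", "mass_fraction": 0.4},
                {"id": "gj", "name": "grape juice", "mass_fraction": 0.3},
                {"id": "k", "name": "known", "mass_fraction": 0.3,
                 "profile": {"basis": "per-100g", "quantities": {"sugar_total": 1.0}}},
            ],
        )
        product = load_product(json.dumps(d))
        result = resolve_profile(product, references)
        substituted = [c for c in product.components
                       if c.provenance.value == "reference-substituted"]
        assert len(result.assumptions) == len(substituted) == 2
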