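"""Ingredient parsing, canonical normalization, concerns, and allergens."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foodtiers.lexicon import (
    AllergenRegistry,
    Lexicon,
    UnbalancedParenthesesWarning,
    damerau_levenshtein,
    fold,
    fuzzy_bound,
)

BIG8_STATEMENT = "milk, egg, tuna, shrimp, almond, peanut, wheat, soy, water, salt"


class TestParseStatement:
    def test_modifiers_and_parenthesized_sub_ingredients(self, lexicon):
        parsed = lexicon.parse_statement(
            "water, non-GMO citric acid, stabilizer (carrageenan, guar gum)"
        )
        assert len(parsed) == 3
        assert parsed[1].canonical_id == "citric-acid"
        assert parsed[1].modifiers == ["non-gmo"]
        subs = parsed[2].sub_ingredients
        assert [s.canonical_id for s in subs] == ["carrageenan", "guar-gum"]

    def test_empty_statement_parses_to_empty_list(self, lexicon):
        assert lexicon.parse_statement("") == []
        assert lexicon.parse_statement("   ") == []

    def test_leading_modifier_is_stripped_into_tags(self, lexicon):
        (entry,) = lexicon.parse_statement("organic milk")
        assert entry.canonical_id == "milk"
        assert entry.modifiers == ["organic"]

    def test_offsets_index_into_original_statement(self, lexicon):
        stmt = "water,  organic milk"
        parsed = lexicon.parse_statement(stmt)
        for entry in parsed:
            assert stmt[entry.start:entry.end] == entry.raw_span

    def test_unbalanced_parentheses_warn_and_flat_split(self, lexicon):
        with pytest.warns(UnbalancedParenthesesWarning):
            parsed = lexicon.parse_statement("water, stabilizer (carrageenan, salt")
        assert len(parsed) == 3  # best-effort flat split

    def test_full_phrase_alias_beats_modifier_stripping(self, lexicon):
        (entry,) = lexicon.parse_statement("partially hydrogenated soybean oil")
        assert entry.canonical_id == "partially-hydrogenated-oil"
        assert entry.modifiers == []


class TestNormalize:
    @pytest.mark.parametrize(
        "term,expected",
        [
            ("E330", "citric-acid"),
            ("e-330", "citric-acid"),
            ("E 330", "citric-acid"),
            ("acidum citricum", "citric-acid"),
            ("2-hydroxypropane-1,2,3-tricarboxylic acid", "citric-acid"),
            ("Citric Acid", "citric-acid"),
            ("glycerol monolaurate", "monolaurin"),
            ("HFCS", "high-fructose-corn-syrup"),
        ],
    )
    def test_synonym_resolution(self, lexicon, term, expected):
        assert lexicon.normalize(term) == expected

    def test_peanut_is_not_a_tree_nut(self, lexicon):
        cid = lexicon.normalize("peanut")
        assert cid == "peanut"
        groups = lexicon.classify_groups(cid)
        assert "tree-nut-ingredients" not in groups

    def test_misspelling_resolves_via_unique_nearest_alias(self, lexicon):
        # independent oracle: exhaustive distance scan over all folded aliases
        term = fold("citirc acid")
        distances = {}
        for entry in lexicon.entries.values():
            for alias in entry.aliases:
                d = damerau_levenshtein(term, fold(alias))
                distances.setdefault(d, set()).add(entry.id)
        dmin = min(distances)
        assert dmin == 1 and distances[dmin] == {"citric-acid"}
        assert lexicon.normalize("citirc acid") == "citric-acid"

    def test_unknown_term_returns_unknown_marker(self, lexicon):
        assert lexicon.normalize("xyzzyflux") is None

    def test_e_numbers_never_fuzzy_match(self, lexicon):
        assert lexicon.normalize("E331") is None  # one digit from E330

    def test_empty_term_is_an_argument_error(self, lexicon):
        with pytest.raises(ValueError):
            lexicon.normalize("  - ")

    def test_idempotence_over_every_alias(self, lexicon):
        for entry in lexicon.entries.values():
            for alias in entry.aliases:
                cid = lexicon.normalize(alias)
                assert cid == entry.id
                assert lexicon.normalize(lexicon.preferred_name(cid)) == cid

    @given(data=st.data())
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_no_substring_matching(self, lexicon, data):
        """Embedding an alias inside a longer word never resolves to its id."""
        entry = data.draw(st.sampled_from(sorted(lexicon.entries.values(),
                                                 key=lambda e: e.id)))
        alias = data.draw(st.sampled_from(entry.aliases))
        letters = st.text(alphabet="abcdefghijklmnopqrstuvwxyz", min_size=1, max_size=6)
        prefix = data.draw(letters)
        suffix = data.draw(letters)
        term = prefix + alias + suffix
        assert lexicon.normalize(term) != entry.id or fold(term) == fold(alias)


class TestGroups:
    def test_monolaurin_is_a_mono_and_diglyceride_and_emulsifier(self, lexicon):
        groups = lexicon.classify_groups("monolaurin")
        assert "mono-and-diglycerides" in groups
        assert "emulsifiers" in groups  # transitive via group hierarchy

    def test_carboxymethylcellulose_is_an_emulsifier(self, lexicon):
        assert "emulsifiers" in lexicon.classify_groups("carboxymethylcellulose")

    def test_ungrouped_ingredient_has_empty_classification(self, lexicon):
        assert lexicon.classify_groups("citric-acid") == []

    def test_unknown_id_is_a_lookup_error(self, lexicon):
        with pytest.raises(KeyError):
            lexicon.classify_groups("not-an-id")


class TestResolveConcern:
    def _entry(self, lexicon, text):
        (entry,) = lexicon.parse_statement(text)
        return entry

    def test_non_gmo_modifier_neutralizes_potentially_offending(self, lexicon):
        entry = self._entry(lexicon, "non-GMO citric acid")
        assert lexicon.resolve_concern(entry, "GMO-status", [], "p1") == "benign"

    def test_whitelist_neutralizes_potentially_offending(self, lexicon):
        entry = self._entry(lexicon, "citric acid")
        assert lexicon.resolve_concern(entry, "GMO-status", ["p1"], "p1") == "benign"
        assert (
            lexicon.resolve_concern(entry, "GMO-status", ["other"], "p1")
            == "potentially-offending"
        )

    def test_offending_status_is_never_neutralized(self, lexicon):
        entry = self._entry(lexicon, "organic carboxymethylcellulose")
        assert entry.modifiers == ["organic"]
        status = lexicon.resolve_concern(
            entry, "emulsifier-gut-inflammation", ["p1"], "p1"
        )
        assert status == "offending"

    def test_unknown_concern_category_is_an_argument_error(self, lexicon):
        entry = self._entry(lexicon, "citric acid")
        with pytest.raises(ValueError):
            lexicon.resolve_concern(entry, "astrology", [], "p1")

    def test_neutralization_monotonicity(self, lexicon):
        """Adding a neutralizing modifier never worsens the effective status."""
        order = {"benign": 0, "potentially-offending": 1, "offending": 2}
        for text, category in [
            ("citric acid", "GMO-status"),
            ("carrageenan", "emulsifier-gut-inflammation"),
            ("carboxymethylcellulose", "emulsifier-gut-inflammation"),
        ]:
            bare = self._entry(lexicon, text)
            modded = self._entry(lexicon, f"non-GMO {text}")
            s_bare = lexicon.resolve_concern(bare, category, [], "p1")
            s_mod = lexicon.resolve_concern(modded, category, [], "p1")
            assert order[s_mod] <= order[s_bare]
            if s_bare == "offending":
                assert s_mod == "offending"


class TestAllergens:
    def test_big8_statement_detects_all_eight_categories(self, lexicon):
        registry = AllergenRegistry.load_default("big8")
        parsed = lexicon.parse_statement(BIG8_STATEMENT)
        assert len(lexicon.detect_allergens(parsed, registry)) == 8

    def test_big9_adds_sesame(self, lexicon):
        registry = AllergenRegistry.load_default("big9")
        parsed = lexicon.parse_statement(BIG8_STATEMENT + ", sesame")
        categories = lexicon.detect_allergens(parsed, registry)
        assert len(categories) == 9 and "sesame" in categories

    def test_benign_statement_detects_nothing(self, lexicon):
        parsed = lexicon.parse_statement("water, salt")
        registry = AllergenRegistry.load_default("big9")
        assert lexicon.detect_allergens(parsed, registry) == set()

    def test_sub_ingredients_contribute(self, lexicon):
        parsed = lexicon.parse_statement("chocolate coating (cocoa, whole milk)")
        registry = AllergenRegistry.load_default("big8")
        assert lexicon.detect_allergens(parsed, registry) == {"milk"}

    def test_detection_distributes_over_union(self, lexicon):
        registry = AllergenRegistry.load_default("big9")
        a = lexicon.parse_statement("milk, wheat")
        b = lexicon.parse_statement("shrimp, sesame")
        assert lexicon.detect_allergens(a + b, registry) == (
            lexicon.detect_allergens(a, registry)
            | lexicon.detect_allergens(b, registry)
        )

    def test_big9_registry_is_big8_plus_sesame(self):
        big8 = AllergenRegistry.load_default("big8")
        big9 = AllergenRegistry.load_default("big9")
        assert set(big9.categories) == set(big8.categories) | {"sesame"}


class TestDistance:
    @pytest.mark.parametrize(
        "a,b,d",
        [("abc", "abc", 0), ("abc", "acb", 1), ("abc", "ab", 1),
         ("abc", "axc", 1), ("kitten", "sitting", 3), ("", "ab", 2)],
    )
    def test_known_distances(self, a, b, d):
        assert damerau_levenshtein(a, b) == d

    def test_bound_switches_at_length_eight(self):
        assert fuzzy_bound("12345678") == 1
        assert fuzzy_bound("123456789") == 2
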