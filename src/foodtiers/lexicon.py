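"""Ingredient-statement parsing and normalization.

Ingredient statements arrive in wildly varying forms: chemical names, Latin
names, E-number codes, misspellings, parenthesized sub-lists, and qualifying
prefixes ("organic", "non-GMO", "partially hydrogenated"). This module
resolves free text to canonical ingredient ids with three guarantees that a
naive string match breaks:

* matching is whole-term against whole-alias, never substring containment —
  a "peanut" is never a tree nut just because it contains "nut";
* misspelling tolerance is bounded (Damerau-Levenshtein distance 1 for folded
  terms up to 8 characters, 2 for longer) and a fuzzy hit is accepted only
  when the nearest alias is unique at the minimal distance;
* E-number codes are folded to a canonical form ("E 330", "e-330" -> "E330")
  and matched exactly only, since adjacent codes differ by one digit.

Concern resolution applies the additive registry with neutralization:
a *potentially offending* ingredient is downgraded to benign by a qualifying
modifier or a product whitelist entry; an *offending* one never is.
"""

from __future__ import annotations

import json
import re
import warnings as _warnings
from dataclasses import dataclass, field
from importlib.resources import files
from typing import Iterable, Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import LexiconError

Status = Literal["offending", "potentially-offending", "benign"]
Confidence = Literal["established", "probable", "suspected"]

CONFIDENCE_RANK = {"suspected": 0, "probable": 1, "established": 2}
_STATUS_ORDER = {"benign": 0, "potentially-offending": 1, "offending": 2}

#: Big 8 allergen categories; Big 9 adds sesame.
BIG8_CATEGORIES = frozenset(
    {"milk", "eggs", "fish", "shellfish", "tree-nuts", "peanuts", "wheat", "soybeans"}
)
BIG9_CATEGORIES = BIG8_CATEGORIES | {"sesame"}


class UnbalancedParenthesesWarning(UserWarning):
    """Ingredient statement had unbalanced parentheses; best-effort flat split."""


class ConcernEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")

    concern_category: str
    status: Status
    confidence: Confidence
    neutralizing_modifiers: list[str] = Field(default_factory=list)
    citation_note: str = ""

    @model_validator(mode="after")
    def _check_neutralizers(self):
        if self.neutralizing_modifiers and self.status != "potentially-offending":
            raise ValueError(
                "neutralizing_modifiers may be non-empty only for "
                "potentially-offending entries"
            )
        return self


class CanonicalIngredient(BaseModel):
    model_config = ConfigDict(extra="ignore")

    id: str
    preferred_name: str
    aliases: list[str]
    groups: list[str] = Field(default_factory=list)
    concerns: list[ConcernEntry] = Field(default_factory=list)
    allergen_category: Optional[str] = None


class AllergenRegistry(BaseModel):
    model_config = ConfigDict(extra="ignore")

    mode: Literal["big8", "big9"]
    categories: dict[str, list[str]]

    @model_validator(mode="after")
    def _check_categories(self):
        expected = BIG8_CATEGORIES if self.mode == "big8" else BIG9_CATEGORIES
        got = set(self.categories)
        if got != expected:
            raise ValueError(
                f"{self.mode} registry must define exactly the categories "
                f"{sorted(expected)}; got {sorted(got)}"
            )
        return self

    def trigger_index(self) -> dict[str, str]:
        """canonical ingredient id -> allergen category."""
        out: dict[str, str] = {}
        for cat, ids in self.categories.items():
            for cid in ids:
                out[cid] = cat
        return out

    @classmethod
    def load_default(cls, mode: str = "big9") -> "AllergenRegistry":
        name = {"big8": "allergens.big8.json", "big9": "allergens.big9.json"}[mode]
        return cls.model_validate_json(files("foodtiers.data").joinpath(name).read_text())


@dataclass
class ParsedIngredient:
    """One entry of a parsed ingredient statement."""

    raw_span: str
    start: int
    end: int
    canonical_id: Optional[str] = None  # None = unknown-marker; raw text retained
    modifiers: list[str] = field(default_factory=list)
    sub_ingredients: list["ParsedIngredient"] = field(default_factory=list)

    def flatten(self) -> Iterable["ParsedIngredient"]:
        yield self
        for sub in self.sub_ingredients:
            yield from sub.flatten()


# ---------------------------------------------------------------------------
# folding and bounded fuzzy matching

_E_NUMBER = re.compile(r"e\s?(\d+[a-z]?)$")


def fold(term: str) -> str:
    """Case/punctuation/whitespace folding; E-numbers collapse to 'e<digits>'."""
    t = re.sub(r"[^a-z0-9]+", " ", term.lower()).strip()
    m = _E_NUMBER.fullmatch(t)
    if m:
        return "e" + m.group(1)
    return t


def damerau_levenshtein(a: str, b: str) -> int:
    """Optimal-string-alignment Damerau-Levenshtein distance."""
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        prev2, prev = prev, cur
    return prev[lb]


def fuzzy_bound(folded_term: str) -> int:
    return 1 if len(folded_term) <= 8 else 2


class Lexicon:
    """Canonical-ingredient lexicon with alias index and concern registry."""

    def __init__(
        self,
        entries: list[CanonicalIngredient],
        group_parents: Optional[dict[str, list[str]]] = None,
        modifiers: Optional[dict[str, str]] = None,
    ):
        self.entries: dict[str, CanonicalIngredient] = {}
        self._alias_index: dict[str, str] = {}
        self.group_parents = dict(group_parents or {})
        # folded modifier surface form -> modifier tag
        self.modifiers = dict(modifiers or {})
        for entry in entries:
            if entry.id in self.entries:
                raise LexiconError(f"duplicate ingredient id {entry.id!r}")
            self.entries[entry.id] = entry
            for alias in entry.aliases:
                key = fold(alias)
                if not key:
                    raise LexiconError(f"alias {alias!r} of {entry.id!r} folds to empty")
                if key in self._alias_index and self._alias_index[key] != entry.id:
                    raise LexiconError(
                        f"alias {alias!r} maps to both "
                        f"{self._alias_index[key]!r} and {entry.id!r}"
                    )
                self._alias_index[key] = entry.id
        # sorted for deterministic fuzzy tie-breaking
        self._alias_items = sorted(self._alias_index.items())

    # -- loading ------------------------------------------------------------

    @classmethod
    def from_dict(cls, raw: dict, additives: Optional[dict] = None) -> "Lexicon":
        entries = [CanonicalIngredient.model_validate(e) for e in raw["entries"]]
        lex = cls(
            entries,
            group_parents=raw.get("group_parents"),
            modifiers=raw.get("modifiers"),
        )
        if additives is not None:
            lex.merge_concerns(additives["entries"])
        return lex

    @classmethod
    def load_default(cls) -> "Lexicon":
        data = files("foodtiers.data")
        return cls.from_dict(
            json.loads(data.joinpath("lexicon.seed.json").read_text()),
            additives=json.loads(data.joinpath("additives.seed.json").read_text()),
        )

    def merge_concerns(self, registry_entries: dict[str, list[dict]]) -> None:
        """Attach additive-registry concern entries; ids must resolve here."""
        unresolved = sorted(set(registry_entries) - set(self.entries))
        if unresolved:
            raise LexiconError(
                f"additive registry ids not present in the lexicon: {unresolved}"
            )
        for cid, concerns in registry_entries.items():
            self.entries[cid].concerns = [
                ConcernEntry.model_validate(c) for c in concerns
            ]

    # -- normalization ------------------------------------------------------

    def normalize(self, term: str) -> Optional[str]:
        """Resolve a term to a canonical id, or None for unknown.

        Exact alias match after folding; otherwise a bounded fuzzy match that
        (a) never fires for E-number codes, (b) requires a unique nearest
        alias at the minimal distance, and (c) rejects candidates whose alias
        is a strict substring of the term (so edge-extended words like
        'peanut' vs 'nut' can never match).
        """
        folded = fold(term)
        if not folded:
            raise ValueError("empty term after folding")
        hit = self._alias_index.get(folded)
        if hit is not None:
            return hit
        if _E_NUMBER.fullmatch(folded) or re.fullmatch(r"e\d+[a-z]?", folded):
            return None  # E-number codes match exactly only
        bound = fuzzy_bound(folded)
        # whole-term guard: an id with any alias strictly contained in the
        # term is an edge-extended word (peanut/nut), not a misspelling of it
        contained_ids = {
            cid
            for alias, cid in self._alias_items
            if alias != folded and alias in folded
        }
        best_dist = bound + 1
        best_ids: set[str] = set()
        for alias, cid in self._alias_items:
            if cid in contained_ids:
                continue
            if abs(len(alias) - len(folded)) > bound:
                continue
            d = damerau_levenshtein(folded, alias)
            if d < best_dist:
                best_dist, best_ids = d, {cid}
            elif d == best_dist:
                best_ids.add(cid)
        if best_dist <= bound and len(best_ids) == 1:
            return next(iter(best_ids))
        return None

    def preferred_name(self, canonical_id: str) -> str:
        return self.entries[canonical_id].preferred_name

    # -- groups -------------------------------------------------------------

    def known_groups(self) -> set[str]:
        groups: set[str] = set(self.group_parents)
        for parents in self.group_parents.values():
            groups.update(parents)
        for entry in self.entries.values():
            groups.update(entry.groups)
        return groups

    def classify_groups(self, canonical_id: str) -> list[str]:
        """Transitive group memberships (direct groups plus their ancestors)."""
        if canonical_id not in self.entries:
            raise KeyError(f"unknown canonical id {canonical_id!r}")
        seen: list[str] = []
        stack = list(self.entries[canonical_id].groups)
        while stack:
            g = stack.pop(0)
            if g in seen:
                continue
            seen.append(g)
            stack.extend(self.group_parents.get(g, []))
        return seen

    # -- concerns -----------------------------------------------------------

    def concern_categories(self) -> set[str]:
        return {
            c.concern_category for e in self.entries.values() for c in e.concerns
        }

    def concern_for(self, canonical_id: str, category: str) -> Optional[ConcernEntry]:
        entry = self.entries.get(canonical_id)
        if entry is None:
            return None
        for c in entry.concerns:
            if c.concern_category == category:
                return c
        return None

    def resolve_concern(
        self,
        parsed: ParsedIngredient,
        concern_category: str,
        whitelist: Iterable[str],
        product_id: str,
    ) -> Status:
        """Effective status of one parsed entry for a concern category.

        Potentially-offending downgrades to benign when a neutralizing
        modifier is present on the entry or the product id is whitelisted;
        offending is never neutralizable. Unknown ingredients are benign here
        (they are surfaced separately in reports).
        """
        if concern_category not in self.concern_categories():
            raise ValueError(f"unknown concern category {concern_category!r}")
        if parsed.canonical_id is None:
            return "benign"
        concern = self.concern_for(parsed.canonical_id, concern_category)
        if concern is None:
            return "benign"
        status = concern.status
        if status == "potentially-offending":
            has_neutralizer = any(
                m in concern.neutralizing_modifiers for m in parsed.modifiers
            )
            if has_neutralizer or product_id in set(whitelist):
                return "benign"
        return status

    # -- parsing ------------------------------------------------------------

    def _strip_modifiers(self, folded: str) -> tuple[list[str], str]:
        """Strip leading modifier tokens from folded text (longest form first)."""
        tags: list[str] = []
        remainder = folded
        surfaces = sorted(self.modifiers, key=len, reverse=True)
        changed = True
        while changed and remainder:
            changed = False
            for surface in surfaces:
                if remainder == surface:
                    continue  # don't consume the whole term
                if remainder.startswith(surface + " "):
                    tags.append(self.modifiers[surface])
                    remainder = remainder[len(surface) + 1 :]
                    changed = True
                    break
        return tags, remainder

    def _resolve_entry(self, raw: str) -> tuple[Optional[str], list[str]]:
        folded = fold(raw)
        if folded and folded in self._alias_index:
            return self._alias_index[folded], []  # full-phrase alias wins
        if not folded:
            return None, []
        tags, remainder = self._strip_modifiers(folded)
        if not remainder:
            return None, tags
        try:
            cid = self.normalize(remainder)
        except ValueError:
            cid = None
        return cid, tags

    def parse_statement(self, statement: str) -> list[ParsedIngredient]:
        """Parse an ingredient statement into an ordered entry list.

        Splits on commas/semicolons outside parentheses; parenthesized lists
        become sub_ingredients; leading modifier tokens are extracted as
        modifier tags. Unbalanced parentheses emit a warning and fall back to
        a flat split.
        """
        if not statement or not statement.strip():
            return []
        depth = 0
        for ch in statement:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
            if depth < 0:
                break
        if depth != 0:
            _warnings.warn(
                "unbalanced parentheses in ingredient statement; flat split applied",
                UnbalancedParenthesesWarning,
                stacklevel=2,
            )
            statement = statement.replace("(", " ").replace(")", " ")
        return self._parse_segment(statement, 0)

    def _parse_segment(self, text: str, offset: int) -> list[ParsedIngredient]:
        entries: list[ParsedIngredient] = []
        depth = 0
        start = 0
        spans: list[tuple[int, int]] = []
        for i, ch in enumerate(text):
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
            elif ch in ",;" and depth == 0:
                spans.append((start, i))
                start = i + 1
        spans.append((start, len(text)))
        for s, e in spans:
            chunk = text[s:e]
            if not chunk.strip():
                continue
            lead = s + (len(chunk) - len(chunk.lstrip()))
            trail = s + len(chunk.rstrip())
            raw = text[lead:trail]
            sub: list[ParsedIngredient] = []
            head = raw
            lp = raw.find("(")
            if lp != -1 and raw.rstrip().endswith(")"):
                inner_start = lead + lp + 1
                inner_end = lead + raw.rfind(")")
                head = raw[:lp].strip()
                sub = self._parse_segment(
                    text[inner_start:inner_end], offset + inner_start
                )
            cid, tags = self._resolve_entry(head) if head else (None, [])
            entries.append(
                ParsedIngredient(
                    raw_span=raw,
                    start=offset + lead,
                    end=offset + trail,
                    canonical_id=cid,
                    modifiers=tags,
                    sub_ingredients=sub,
                )
            )
        return entries

    # -- allergens ----------------------------------------------------------

    def detect_allergens(
        self, parsed: list[ParsedIngredient], registry: AllergenRegistry
    ) -> set[str]:
        """Union of allergen categories over all entries and sub-entries."""
        index = registry.trigger_index()
        found: set[str] = set()
        for entry in parsed:
            for item in entry.flatten():
                if item.canonical_id is not None and item.canonical_id in index:
                    found.add(index[item.canonical_id])
        return found
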