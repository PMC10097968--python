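"""Exception hierarchy shared across the package."""

from __future__ import annotations


class FoodTiersError(Exception):
    """Base class for all package errors."""


class ParseError(FoodTiersError):
    """Malformed input document (e.g. invalid JSON); carries the byte offset."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


class SchemaValidationError(FoodTiersError):
    """Structural/schema violations. ``violations`` lists every violated field path."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "schema validation failed:\n" + "\n".join(f"  - {v}" for v in self.violations)
        )


class ProductValidationError(FoodTiersError):
    """Semantic invariant breaches found while loading a product."""

    def __init__(self, findings):
        self.findings = list(findings)
        super().__init__(
            "product validation failed:\n"
            + "\n".join(f"  - [{f.rule}] {f.path}: {f.message}" for f in self.findings)
        )


class UnsupportedConversionError(FoodTiersError):
    """No conversion defined for the requested (unit, unit, nutrient) triple."""


class UnresolvableComponentError(FoodTiersError):
    """A component has no profile and no reference-registry entry."""

    def __init__(self, component_id: str, name: str):
        self.component_id = component_id
        self.name = name
        super().__init__(
            f"component {component_id!r} ({name!r}) has no nutrient profile, no "
            f"subcomponents, and no reference-registry entry"
        )


class LexiconError(FoodTiersError):
    """Inconsistent lexicon (duplicate aliases, unresolvable registry keys, ...)."""


class ConfigurationError(FoodTiersError):
    """Invalid criteria/matrix configuration. Lists every violation found."""

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__(
            "configuration error:\n" + "\n".join(f"  - {v}" for v in self.violations)
        )


class IncompleteEvaluationError(FoodTiersError):
    """Tier assignment requested with outcomes missing for configured criteria."""


class ProbeError(FoodTiersError):
    """Threshold probe found no pass/fail sign change on the given interval."""


class ReportError(FoodTiersError):
    """Report/overview rendering failed (incomplete inputs, mixed config versions)."""
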