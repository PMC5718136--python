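"""Exception hierarchy shared across sarakit modules."""

from __future__ import annotations


class SaraError(Exception):
    """Base class for all sarakit errors."""


class ParseError(SaraError):
    """A file could not be parsed (OBO, OWL, CSV, YAML)."""


class ValidationError(SaraError):
    """Input data violates a structural or range constraint.

    ``details`` carries the individual violations (one human-readable
    string each) so callers can report every problem at once.
    """

    def __init__(self, message: str, details: list[str] | None = None):
        self.details = list(details or [])
        if self.details:
            message = message + "\n  - " + "\n  - ".join(self.details)
        super().__init__(message)


class UnknownClassError(ValidationError):
    """A referenced ontology class identifier does not exist."""

    def __init__(self, missing, context: str = "ontology"):
        self.missing = sorted(missing)
        super().__init__(
            f"unknown class id(s) in {context}: {', '.join(self.missing)}"
        )


class DuplicateClassError(ValidationError):
    """An ontology class identifier is already present."""


class ConfigError(SaraError):
    """A configuration (scale definition, rule overrides) is invalid."""


class InfeasibleBandError(ConfigError):
    """A requested total-score band cannot be reached by an archetype."""
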