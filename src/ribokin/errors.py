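"""Exception hierarchy shared across the package."""


class RibokinError(Exception):
    """Base class for all package-specific errors."""


class DomainError(RibokinError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class ConfigurationError(RibokinError, ValueError):
    """A model was evaluated without the parameters its form requires."""


class IdentifiabilityError(RibokinError):
    """The data cannot constrain the requested parameters."""


class DiagnosticError(RibokinError):
    """A diagnostic step cannot proceed (e.g. too few surviving points)."""


class EquilibriumError(RibokinError):
    """The species-balance root finder failed to converge."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SchemaError(RibokinError, ValueError):
    """A data file does not match its expected column schema."""
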