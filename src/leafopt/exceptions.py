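"""Exception hierarchy for domain errors.

Every error a caller may want to catch selectively has its own class; all
inherit from :class:`LeafOptError` so a pipeline can trap the lot.
"""


class LeafOptError(Exception):
    """Base class for all leafopt domain errors."""


class PolarDayError(LeafOptError):
    """Sun does not rise or set: |tan(lat) * tan(declination)| >= 1."""


class DegenerateSiteError(LeafOptError):
    """A site has no growing season (no day above the temperature baseline)."""


class PhysicalDomainError(LeafOptError):
    """Inputs are outside the physical domain of a model (e.g. ca <= Gamma*)."""


class CollinearityError(LeafOptError):
    """A regression design matrix is rank deficient."""

    def __init__(self, column: str, message: str | None = None):
        self.column = column
        super().__init__(message or f"design is rank-deficient: column {column!r}")


class InsufficientDataError(LeafOptError):
    """Too few complete records for a fit."""


class SchemaError(LeafOptError):
    """An input table violates its documented schema."""

    def __init__(self, path: str, column: str, message: str | None = None):
        self.path = path
        self.column = column
        super().__init__(message or f"{path}: missing or invalid column {column!r}")


class ConfigurationError(LeafOptError):
    """Unknown configuration key or inconsistent run configuration."""
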