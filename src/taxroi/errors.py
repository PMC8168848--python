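"""Exception hierarchy."""


class TaxroiError(Exception):
    """Base class for all package errors."""


class SchemaError(TaxroiError):
    """A required column cannot be resolved in the input table."""


class ValidationError(TaxroiError):
    """A cell value is outside its allowed domain (carries the row index)."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"row {row}: {message}")
        self.row = row


class UnresolvedConflictError(TaxroiError):
    """Discordant multi-assessor records without a conflict-category label."""

    def __init__(self, species: list[str]):
        self.species = list(species)
        super().__init__(
            "discordant records without a conflict category for species: "
            + ", ".join(self.species)
        )


class CohortError(TaxroiError):
    """An assessment outside the ROI cohort was passed to the scorer."""


class ZeroCostError(TaxroiError):
    """A revision-needed species with no outstanding research steps."""


class GeometryError(TaxroiError):
    """Invalid, empty, or irreparable range geometry."""


class ConfigError(TaxroiError):
    """Invalid synthetic-data configuration."""
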