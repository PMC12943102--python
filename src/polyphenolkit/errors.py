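"""Exception hierarchy shared across the package."""


class PolyphenolkitError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PolyphenolkitError):
    """An input table is missing a mandatory column or has an unusable layout."""

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column


class StructureError(PolyphenolkitError):
    """A structure string could not be parsed into a molecule."""

    def __init__(self, structure: str, message: str | None = None):
        super().__init__(message or f"unparseable structure: {structure!r}")
        self.structure = structure


class FragmentTableError(PolyphenolkitError):
    """A fragment-score table contains an invalid substructure pattern."""


class ConfigError(PolyphenolkitError):
    """A run configuration violates its own invariants."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(str(e) for e in self.errors))


class EmptySummaryError(PolyphenolkitError, ValueError):
    """A distribution summary was requested for an empty sample."""
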