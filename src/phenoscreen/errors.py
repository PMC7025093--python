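"""Exception hierarchy."""


class PhenoscreenError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PhenoscreenError):
    """A table does not conform to the expected feature/metadata schema."""


class EmptyTableError(PhenoscreenError):
    """An input table contains no data rows."""


class ConfigurationError(PhenoscreenError):
    """A configuration value is invalid or inconsistent."""


class InsufficientDataError(PhenoscreenError):
    """Too few observations to perform the requested computation."""


class DataError(PhenoscreenError):
    """Input data violate a precondition of the requested computation."""
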