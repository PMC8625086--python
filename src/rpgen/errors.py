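"""Exception hierarchy for survey reading, harmonization and assembly."""


class RPGenError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RPGenError):
    """A schema map is incomplete or does not fit the input file."""


class RecodeError(RPGenError, ValueError):
    """A raw categorical code has no mapping to an internal value."""


class DomainError(RPGenError, ValueError):
    """A scalar argument lies outside its stated domain."""


class DataQualityError(RPGenError):
    """Too large a share of input rows failed validation to continue."""


class ConfigurationError(RPGenError):
    """A run configuration is missing, inconsistent, or empties the data."""


class MatchError(RPGenError, RuntimeError):
    """Household matching failed even after full pool relaxation."""
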