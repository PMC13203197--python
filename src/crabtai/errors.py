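"""Exception hierarchy for the crabtai pipeline.

Every error raised by the package derives from :class:`CrabTaiError`, so
callers can catch pipeline failures without masking programming errors.
"""


class CrabTaiError(Exception):
    """Base class for all crabtai errors."""


class FormatError(CrabTaiError):
    """A file does not follow the expected dialect (e.g. missing header rows)."""


class SchemaError(CrabTaiError):
    """A file parses but its structure disagrees with the expected schema."""


class ParseError(CrabTaiError):
    """A cell or field could not be converted to the expected type."""


class ValidationError(CrabTaiError):
    """Parsed data violates a documented invariant."""


class ConfigError(CrabTaiError):
    """A configuration value is out of its allowed range."""


class ParameterError(CrabTaiError):
    """A function argument is out of its allowed range."""


class FeatureError(CrabTaiError):
    """A kinematic feature is undefined for the given track (e.g. no valid frames)."""


class EstimationError(CrabTaiError):
    """A statistical estimate cannot be computed (e.g. rank-deficient design)."""


class DomainError(CrabTaiError):
    """A closed-form expression was evaluated outside its mathematical domain."""
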