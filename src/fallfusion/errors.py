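"""Exception hierarchy shared across the package."""


class FallFusionError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FallFusionError):
    """A file does not conform to the expected tabular layout."""


class DataError(FallFusionError):
    """Input data violate a contract (lengths, monotonicity, ranges)."""


class ConfigError(FallFusionError):
    """Invalid or unknown configuration value."""


class UsageError(FallFusionError):
    """The API was called in an unsupported way."""
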