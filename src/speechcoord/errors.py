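"""Exception types shared across the package."""


class SpeechCoordError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SpeechCoordError, ValueError):
    """A setting, selector, or parameter is invalid or unresolvable."""


class FormatError(SpeechCoordError, ValueError):
    """An input file or in-memory structure violates its format contract."""


class DegenerateDataError(SpeechCoordError, ValueError):
    """A statistical operation received data on which it is undefined
    (e.g., zero variance where a spread is required)."""
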