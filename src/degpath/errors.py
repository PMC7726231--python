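"""Exception hierarchy shared across the pipeline stages."""


class DegpathError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(DegpathError, ValueError):
    """A file could not be parsed; the message names the offending location."""


class ValidationError(DegpathError, ValueError):
    """An in-memory object violates one of its invariants."""


class ConfigurationError(DegpathError, ValueError):
    """A required input or option is missing or inconsistent."""


class StateError(DegpathError, RuntimeError):
    """An operation was applied to data in the wrong processing state."""
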