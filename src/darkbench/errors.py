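"""Exception hierarchy shared across the package."""


class DarkbenchError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DarkbenchError):
    """A text input did not follow its declared dialect."""


class StructureError(DarkbenchError):
    """A parsed object violates a structural invariant (e.g. orphan parent)."""


class ValidationError(DarkbenchError):
    """An argument is outside its documented domain."""


class DegenerateProfileError(DarkbenchError):
    """A filtering step removed every entry of a profile."""


class UndefinedMetricError(DarkbenchError):
    """A metric is undefined for the given input (e.g. constant vector)."""


class ConfigError(DarkbenchError):
    """A run configuration contains unknown or inconsistent keys."""
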