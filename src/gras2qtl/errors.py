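"""Exception hierarchy."""


class Gras2QtlError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(Gras2QtlError):
    """A configuration value violates its documented constraints."""


class NonEstimableError(Gras2QtlError):
    """A per-locus model cannot be initialized (degenerate or too-small data)."""


class DataFormatError(Gras2QtlError):
    """An input file or table violates the expected format."""
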