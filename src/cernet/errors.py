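"""Exception hierarchy shared across the pipeline."""


class CernetError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(CernetError, ValueError):
    """An invalid configuration field; the message names the field."""


class FormatError(CernetError, ValueError):
    """Malformed external input; the message locates the offending line/cell."""


class NormalizationError(CernetError, ValueError):
    """Count normalization cannot proceed (e.g. a zero-total sample)."""


class DomainError(CernetError, ValueError):
    """Arguments violate a statistical precondition; names the inequality."""


class SequenceError(CernetError, ValueError):
    """Invalid nucleotide sequence; the message gives the offending position."""


class MissingInputError(CernetError, FileNotFoundError):
    """A pipeline stage was invoked before its inputs exist."""
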