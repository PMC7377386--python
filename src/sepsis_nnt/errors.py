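"""Exception hierarchy shared across the package."""


class SepsisNNTError(Exception):
    """Base class for package errors."""


class ConfigurationError(SepsisNNTError, ValueError):
    """An invalid configuration value; the message names the field."""


class DataError(SepsisNNTError, ValueError):
    """Input data violating a structural invariant (e.g. reversed dates)."""


class DomainError(SepsisNNTError, ValueError):
    """A mathematical operation applied outside its domain (e.g. /0)."""
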