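"""Exception taxonomy shared across the package."""


class CardiosegError(Exception):
    """Base class for package errors."""


class ConfigError(CardiosegError, ValueError):
    """Invalid configuration value (bad fraction, degenerate grid, ...)."""


class StructuralError(CardiosegError, ValueError):
    """Shape or layout mismatch between related arrays."""


class LabelError(CardiosegError, ValueError):
    """A mask contains a label outside the declared label set."""


class RangeError(CardiosegError, ValueError):
    """Intensity values outside the declared range convention."""


class NumericError(CardiosegError, RuntimeError):
    """Non-finite value encountered during optimization."""
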