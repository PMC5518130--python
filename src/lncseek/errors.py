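"""Exception hierarchy shared across the package."""


class LncseekError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LncseekError, ValueError):
    """A file does not conform to its declared format (message names the line)."""


class BoundsError(LncseekError, IndexError):
    """A genomic lookup runs past the end of a chromosome."""


class InputError(LncseekError, ValueError):
    """An argument violates an operation's precondition."""


class ConfigurationError(LncseekError, ValueError):
    """A simulation or pipeline configuration is invalid."""
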