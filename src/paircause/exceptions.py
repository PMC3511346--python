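"""Error types shared across the package."""


class PaircauseError(Exception):
    """Base class for package-specific errors."""


class InputError(PaircauseError, ValueError):
    """Raised when an argument violates a precondition (lengths, ranges)."""


class DegenerateInputError(InputError):
    """Raised when a vector is constant or otherwise carries no information."""
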