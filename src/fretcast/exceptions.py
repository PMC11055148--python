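"""Exception hierarchy shared across the package."""


class FretcastError(Exception):
    """Base class for all package-specific errors."""


class InvalidSignalError(FretcastError, ValueError):
    """Signal contains non-finite values or is otherwise unusable."""


class TooShortError(FretcastError, ValueError):
    """Input sequence is too short for the requested operation."""


class HorizonError(FretcastError, ValueError):
    """No eligible archetype exists for the requested forecast horizon."""


class DegenerateWindowError(FretcastError, ValueError):
    """Window has zero variance (or zero range) where variation is required."""
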