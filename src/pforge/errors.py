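"""Exception hierarchy for pforge.

All pforge-specific failures derive from :class:`PforgeError` so callers can
catch the package's errors without masking programming bugs.
"""


class PforgeError(Exception):
    """Base class for all pforge errors."""


class InputError(PforgeError, ValueError):
    """Malformed user input (bad alphabet, bad coordinates, empty table...)."""


class ConfigError(PforgeError, ValueError):
    """Invalid configuration value (malformed motif pattern, bad gate box...)."""


class AlignmentError(PforgeError):
    """Sequences cannot be aligned within the allowed gap budget."""


class CrossoverError(PforgeError):
    """Crossover window inconsistent with the attachment sites it refers to."""


class RecombinationError(PforgeError):
    """Illegal recombination move (e.g. inversion between direct rix sites)."""


class StateSpaceOverflow(PforgeError):
    """Inversion-state closure exceeded the requested cap."""


class UndefinedFoldError(PforgeError, ZeroDivisionError):
    """A fold ratio is undefined because its denominator is zero."""
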