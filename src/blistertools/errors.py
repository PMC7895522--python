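"""Exception hierarchy.

All package errors derive from :class:`BlisterToolsError` so callers can trap
the whole family; the leaf classes distinguish contract violations (bad
arguments), structural defects in input files, and configuration problems
that make a criterion untestable (for example a clustering cutoff larger than
half the periodic box).
"""


class BlisterToolsError(Exception):
    """Base class for all blistertools errors."""


class ParseError(BlisterToolsError):
    """Malformed record in a text input; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class StructuralError(BlisterToolsError):
    """Internally inconsistent input (e.g. bead count changes between frames)."""


class ConfigurationError(BlisterToolsError):
    """Parameters incompatible with the data (windows, spacings, grids)."""


class AmbiguityError(ConfigurationError):
    """A distance cutoff at or beyond half the smallest box edge, where the
    minimum-image convention no longer identifies a unique nearest copy."""


class ContractError(BlisterToolsError):
    """Precondition violation on an operation's inputs."""


class DetectionError(BlisterToolsError):
    """An automatic feature detection (e.g. glycerol minima) failed; the
    caller should supply the feature manually."""


class FitError(BlisterToolsError):
    """A model fit could not be performed (too few points, no signal)."""
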