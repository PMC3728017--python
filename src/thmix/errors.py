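"""Exception types raised across the package."""


class ThmixError(Exception):
    """Base class for package-specific errors."""


class NoFixedPointError(ThmixError):
    """The root finder returned no fixed point (indicates a search-box bug)."""


class AmbiguousSteadyStateError(ThmixError):
    """A steady-state query hit a bistable parameter point."""

    def __init__(self, message, inputs=None):
        super().__init__(message)
        self.inputs = inputs


class SharpTransitionError(ThmixError):
    """A steady-state trajectory shows a persistent jump discontinuity."""


class EmptySortGateError(ThmixError):
    """Requested sort quadrant contains no cells."""


class DatasetParseError(ThmixError):
    """A dataset file is malformed; carries file/line context."""

    def __init__(self, message, path=None, line=None, column=None):
        loc = []
        if path is not None:
            loc.append(str(path))
        if line is not None:
            loc.append(f"line {line}")
        if column is not None:
            loc.append(f"column {column!r}")
        full = message if not loc else f"{message} ({', '.join(loc)})"
        super().__init__(full)
        self.path = path
        self.line = line
        self.column = column


class ConfigError(ThmixError):
    """Pipeline configuration failed schema validation."""
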