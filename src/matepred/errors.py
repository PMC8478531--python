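"""Exception hierarchy for matepred."""


class MatepredError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MatepredError, ValueError):
    """Model parameters violate their invariants."""


class GridError(MatepredError, ValueError):
    """Invalid spatial grid specification."""


class InvalidSpecError(MatepredError, ValueError):
    """Invalid initial-condition or run specification."""


class DimensionError(MatepredError, ValueError):
    """Mismatched array shapes."""


class NumericsError(MatepredError, ArithmeticError):
    """Non-finite fields or excessive imaginary residue in a transform."""


class BlowUpError(NumericsError):
    """Solution diverged during time integration.

    Attributes
    ----------
    t_reached : float
        Last time at which the state was still finite.
    """

    def __init__(self, msg: str, t_reached: float):
        super().__init__(msg)
        self.t_reached = t_reached


class InsufficientDataError(MatepredError, ValueError):
    """Trajectory too short for the requested diagnostic."""


class NoPeriodError(MatepredError, ValueError):
    """Signal does not contain enough maxima for period estimation."""


class ParseError(MatepredError, ValueError):
    """Malformed trajectory or config file.

    Attributes
    ----------
    line : int | None
        1-based line number where parsing failed, when known.
    """

    def __init__(self, msg: str, line: int | None = None):
        super().__init__(msg if line is None else f"line {line}: {msg}")
        self.line = line
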