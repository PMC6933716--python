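"""Exception hierarchy shared by all pipeline stages."""


class PanicleError(Exception):
    """Base class for all errors raised by paniclepheno."""


class ValidationError(PanicleError, ValueError):
    """An input violated a documented precondition."""


class FormatError(PanicleError, ValueError):
    """A file does not conform to its declared format."""


class PLYParseError(FormatError):
    """Malformed PLY content.

    Parameters
    ----------
    message : str
    offset : int
        Byte offset into the file at which parsing failed.
    """

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (byte offset {offset})")
        self.offset = offset


class IntegrityError(PanicleError, ValueError):
    """A table violated a key-uniqueness or range invariant."""


class AlignmentError(PanicleError, RuntimeError):
    """Reference geometry missing or degenerate; scaling/alignment impossible."""


class OutOfBoundsError(PanicleError, ValueError):
    """A point fell outside the shared bounding cube (failed alignment)."""


class UndefinedTraitError(PanicleError, ArithmeticError):
    """A derived trait (e.g. the R:G ratio with zero green sum) is undefined."""


class DegenerateTestError(PanicleError, ArithmeticError):
    """A statistical test could not be formed (e.g. zero variance everywhere)."""


class CapacityError(PanicleError, RuntimeError):
    """Synthetic placement could not be satisfied within bounded attempts."""
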