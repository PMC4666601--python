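"""Exception and warning types shared across the package."""


class DCSError(Exception):
    """Base class for errors raised by dcsflow."""


class DataError(DCSError):
    """A record or table violates the data contract (e.g. non-positive baseline)."""


class ParseError(DataError):
    """A curve, manifest or config file could not be parsed.

    Carries the offending line number where one is known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class DegenerateInputError(DataError):
    """The input is structurally valid but too thin to analyse (e.g. <10 usable lags)."""


class NumericalError(DCSError):
    """A non-finite intermediate appeared where the model guarantees finiteness."""


class NoSignalWarning(UserWarning):
    """The measured g2 never rises above the noise floor; the fit is not meaningful."""
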