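"""Exception types shared across the package."""


class BsadcError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BsadcError, ValueError):
    """An input violated a documented precondition."""


class DataError(BsadcError, ValueError):
    """A file or table could not be parsed into the expected shape."""


class FitError(BsadcError, RuntimeError):
    """A regression or least-squares fit was degenerate or did not converge."""


class NoPlateauError(BsadcError, RuntimeError):
    """A progress curve has not reached its product plateau."""
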