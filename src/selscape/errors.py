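"""Exception types shared across the package."""


class SelscapeError(Exception):
    """Base class for package-specific errors."""


class InvalidArgumentError(SelscapeError, ValueError):
    """An argument violates an operation's precondition."""


class GenerationError(SelscapeError, RuntimeError):
    """Synthetic-data generation could not satisfy its constraints."""


class EstimationDegenerateError(SelscapeError, RuntimeError):
    """Input is degenerate for estimation (e.g. invariant alignment)."""


class FormatError(SelscapeError, ValueError):
    """A file or table does not conform to the expected format."""
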