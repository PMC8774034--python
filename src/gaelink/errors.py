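"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
DivergenceError -> 4.
"""


class GaelinkError(Exception):
    """Base class for all package errors."""


class ConfigError(GaelinkError):
    """Malformed configuration or unusable parameter combination."""


class DataError(GaelinkError):
    """Malformed or inconsistent input data."""


class DegenerateProfileError(DataError):
    """All-zero association matrix: the Gaussian kernel bandwidth is zero."""


class DivergenceError(GaelinkError):
    """Training produced a non-finite loss.

    Attributes
    ----------
    epoch : int
        Zero-based epoch index at which the non-finite loss was observed.
    """

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite training loss at epoch {epoch}")
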