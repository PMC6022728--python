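"""Exception hierarchy for proxispec.

Every domain error raised by the library derives from :class:`ProxispecError`
so callers (and the CLI) can distinguish usage/domain problems from bugs.
"""


class ProxispecError(Exception):
    """Base class for all proxispec domain errors."""


class FormatError(ProxispecError):
    """A file is not in the expected format (bad magic, unknown version)."""


class CorruptFileError(ProxispecError):
    """A file matched the expected format but its payload is truncated/invalid."""


class OrderingError(ProxispecError):
    """Wavelengths are not strictly increasing."""


class EmptyFileError(ProxispecError):
    """No parseable data rows were found."""


class ParseError(ProxispecError):
    """A delimited table could not be parsed (ragged rows, bad cells)."""


class SchemaError(ProxispecError):
    """A sidecar table does not follow the required schema."""


class KeyCollisionError(ProxispecError):
    """Duplicate sample ids / filenames where uniqueness is required."""


class ShapeError(ProxispecError):
    """A layout matrix is not rectangular."""


class DuplicationError(ProxispecError):
    """A filename occurs in more than one layout cell."""


class IncompatibleGridsError(ProxispecError):
    """Spectra share no common wavelength; no interpolation is ever attempted."""


class EmptyRangeError(ProxispecError):
    """A trim/mask operation would leave no wavelengths."""


class InsufficientSamplesError(ProxispecError):
    """An operation needs more samples than the collection holds."""


class DegenerateDataError(ProxispecError):
    """Data carry no variance where variance is required (e.g. PCA input)."""


class UsageError(ProxispecError):
    """An argument combination violates an operation's contract."""


class UnknownNameError(ProxispecError, KeyError):
    """An attribute, sample or index name does not exist."""


class FormulaSyntaxError(ProxispecError):
    """A band-math expression failed to parse; carries the offending position."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class RegistryError(ProxispecError):
    """The vegetation-index registry file is malformed."""
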