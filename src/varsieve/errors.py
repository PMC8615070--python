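"""Exception hierarchy shared across the package.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and subclasses) to
exit code 3.
"""


class VarsieveError(Exception):
    """Base class for all package errors."""


class ConfigError(VarsieveError):
    """Invalid configuration: bad parameter values, missing paths, unknown keys."""


class DataError(VarsieveError):
    """Malformed or inconsistent input data."""


class ReferenceMismatchError(DataError):
    """A variant's stated reference allele disagrees with the sequence it is applied to."""

    def __init__(self, position: int, expected: str, found: str):
        self.position = position
        self.expected = expected
        self.found = found
        super().__init__(
            f"reference mismatch at CDS position {position}: "
            f"notation states {expected!r}, sequence has {found!r}"
        )


class UnsupportedNotationError(DataError):
    """HGVS notation outside the supported coding-variant grammar."""
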