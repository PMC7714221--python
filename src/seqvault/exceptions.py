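"""Exception hierarchy shared across all seqvault layers.

Error classes are deliberately distinct so that callers (and the HTTP
layer) can map each failure mode to a different status code without
string-matching messages.
"""


class SeqVaultError(Exception):
    """Base class for all seqvault errors."""


class NotFoundError(SeqVaultError, KeyError):
    """The requested sequence or identifier is not in the repository."""

    def __str__(self) -> str:  # KeyError quotes its args; keep plain text
        return Exception.__str__(self)


class AmbiguousIdentifierError(SeqVaultError):
    """A bare (namespace-less) alias resolved to more than one sequence."""

    def __init__(self, alias: str, namespaces: list[str]):
        self.alias = alias
        self.namespaces = list(namespaces)
        super().__init__(
            f"alias {alias!r} is ambiguous across namespaces: "
            + ", ".join(sorted(self.namespaces))
        )


class RangeError(SeqVaultError, ValueError):
    """A slice request violated 0 <= start <= end <= length."""


class ReadOnlyError(SeqVaultError):
    """A write was attempted on a read-only repository instance."""


class ReferentialError(SeqVaultError):
    """An alias referenced a sequence id not present in the store."""


class CurieParseError(SeqVaultError, ValueError):
    """A namespaced identifier string could not be parsed."""


class WriterLockError(SeqVaultError):
    """A second concurrent writer attempted to open the repository."""


class CrossDeviceError(SeqVaultError):
    """Snapshot destination is on a different filesystem than the source.

    Hard links cannot cross filesystems; the caller should choose a
    destination on the same device or fall back to a plain copy.
    """
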