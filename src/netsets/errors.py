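"""Exception hierarchy.

Errors split into two families: usage errors (bad command, missing
argument — things a script author fixes) and domain errors (unknown set,
kind mismatch — things the data dictates).  The CLI maps usage errors to
exit code 2 and domain errors to exit code 3.
"""


class NetSetsError(Exception):
    """Base class for all package errors."""


class UsageError(NetSetsError):
    """Malformed invocation: unknown command or missing required argument."""


class UnknownCommandError(UsageError):
    pass


class MissingArgumentError(UsageError):
    pass


class DomainError(NetSetsError):
    """Valid invocation that the current data cannot satisfy."""


class NameCollisionError(DomainError):
    pass


class UnknownSetError(DomainError):
    pass


class UnknownElementError(DomainError):
    pass


class MixedKindError(DomainError):
    pass


class TypedColumnError(DomainError):
    """A value does not conform to the column's declared type."""


class UnknownColumnError(DomainError):
    pass


class UnsupportedTypeError(DomainError):
    """Operation requires a different column value type."""


class ColumnCollisionError(DomainError):
    pass


class ExportError(DomainError):
    pass


class EmptyImportError(DomainError):
    pass


class SessionFormatError(DomainError):
    pass


class ParameterError(DomainError):
    pass
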