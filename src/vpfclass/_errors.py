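"""Exception hierarchy shared across the package.

``ValidationError`` covers everything a user can fix (bad files, inconsistent
tables, out-of-range parameters) and maps to exit code 2 in the CLI; anything
else is an internal error (exit 1).
"""


class VpfError(Exception):
    """Base class for all package errors."""


class ValidationError(VpfError):
    """Invalid user input: malformed file, inconsistent table, bad parameter."""


class ParseError(ValidationError):
    """A file could not be parsed; the message names the offending entry."""
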