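"""Exception hierarchy shared across the package.

Each top-level failure class maps to a distinct process exit code in the
command-line interface, so callers can distinguish bad inputs from internal
inconsistencies and from missing external tools.
"""


class FamclusterError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(FamclusterError):
    """Malformed or missing user input (files, formats, parameter values)."""

    exit_code = 2


class ParseError(InputError):
    """A file could not be parsed; message names the offending location."""


class ConsistencyError(FamclusterError):
    """Internally inconsistent objects passed between pipeline stages."""

    exit_code = 3


class ExternalToolError(FamclusterError):
    """An optional external program (aligner, tree builder) failed or is absent."""

    exit_code = 4
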