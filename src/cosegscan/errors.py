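"""Exception hierarchy.

Validation errors (bad inputs, malformed files, inconsistent arguments) and
computation errors (a stage failed mid-run) are distinguished so the CLI can
map them to distinct exit codes.
"""


class CosegscanError(Exception):
    """Base class for all package errors."""


class InputValidationError(CosegscanError):
    """Malformed or inconsistent input; CLI exit code 2."""


class ComputationError(CosegscanError):
    """A pipeline stage failed during computation; CLI exit code 3."""
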