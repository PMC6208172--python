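"""Exception hierarchy shared across the package.

Three families map onto the CLI exit codes: validation problems (bad
parameters, malformed specs) exit 1, I/O problems exit 2, contract
violations detected at run time exit 3.
"""


class CtnlmError(Exception):
    """Base class for all package errors."""

    exit_code = 3


class ValidationError(CtnlmError, ValueError):
    """A parameter or configuration value violates its documented domain."""

    exit_code = 1


class VolumeIOError(CtnlmError, OSError):
    """Reading or writing a volume failed or the file content is unusable."""

    exit_code = 2


class ContractError(CtnlmError, ValueError):
    """An operation precondition was violated by otherwise well-formed input."""

    exit_code = 3
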