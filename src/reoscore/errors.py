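"""Exception hierarchy.

``ValidationError`` marks malformed or inconsistent inputs (bad files,
violated invariants); ``ComputationError`` marks inputs that are well formed
but admit no result (e.g. a sample with no evaluable signature pair). The
CLI maps them to exit codes 1 and 2 respectively.
"""


class ReoscoreError(Exception):
    """Base class for all package errors."""


class ValidationError(ReoscoreError):
    """Input violates a format or type invariant."""


class ComputationError(ReoscoreError):
    """Well-formed input on which the requested computation is undefined."""
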