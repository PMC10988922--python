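"""Exception hierarchy.

Validation errors (bad inputs, violated preconditions) map to CLI exit code 2,
compute errors (a stage failed on valid-looking input) to exit code 3.
"""


class InsituAnnoError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(InsituAnnoError):
    """Invalid input, option, or violated precondition."""

    exit_code = 2


class ComputeError(InsituAnnoError):
    """A pipeline stage failed during computation."""

    exit_code = 3
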