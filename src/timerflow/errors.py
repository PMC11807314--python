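"""Exception hierarchy and shared constants.

Two error classes map onto the CLI exit-code convention: configuration
problems (bad flags, impossible parameter values) exit with code 1, data
problems (unreadable files, degenerate controls) exit with code 2.
"""

#: Minimum number of gated negative-control cells required to estimate
#: normalization statistics. Max and MAD are meaningless on tiny gates.
MIN_GATE_SIZE = 10


class TimerflowError(Exception):
    """Base class for all package errors."""

    exit_code = 2


class ConfigurationError(TimerflowError):
    """Invalid user-supplied configuration (flags, parameter values)."""

    exit_code = 1


class DataError(TimerflowError):
    """Problem with the input data (missing columns, degenerate control)."""

    exit_code = 2
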