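"""Exception hierarchy shared across the pipeline.

Each class maps to a distinct CLI exit code so that batch callers can
distinguish misconfiguration from bad input data from numerical failure.
"""


class NtcpValError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(NtcpValError):
    """Inconsistent or infeasible configuration (exit code 2)."""

    exit_code = 2


class DataError(NtcpValError):
    """Invalid input data: malformed DVH, unknown category, bad record (exit code 3)."""

    exit_code = 3


class InvalidDVHError(DataError):
    """A dose-volume histogram violating its invariants."""


class FittingError(NtcpValError):
    """Maximum-likelihood fitting failed: separation, constant outcome, no convergence (exit code 4)."""

    exit_code = 4
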