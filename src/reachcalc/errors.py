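"""Exception hierarchy.

Config/schema problems raise :class:`ConfigError` (CLI exit code 2);
arithmetic or consistency problems raise :class:`ModelError` (exit code 3).
"""


class ReachCalcError(Exception):
    """Base class for all package errors."""


class ConfigError(ReachCalcError):
    """Invalid configuration, period, or override path."""


class InvalidPeriodError(ConfigError):
    """Period end precedes start, or period is malformed."""


class InconsistentFlowsError(ReachCalcError):
    """Production − exports + imports came out negative."""


class ZeroUseError(ReachCalcError):
    """Per-consumer use is zero; reach is undefined."""


class DoubleCountingError(ReachCalcError):
    """Monthly reach values were summed into a period total.

    The same individual typically uses the product in several months, so a
    sum of monthly headcounts double-counts people. Aggregate the supply
    over the whole period instead and estimate reach once.
    """


class LedgerRowError(ReachCalcError):
    """A supply-ledger CSV row could not be parsed; carries row details."""

    def __init__(self, message: str, rows: list[str] | None = None):
        super().__init__(message)
        self.rows = rows or []
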