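"""Exception hierarchy for mtgrowth.

Input errors (bad arguments, malformed files) are distinguished from
analysis degeneracies (flat traces, crossings that never happen, too few
points in a fit window) so that callers — in particular the CLI — can map
them to different exit codes.
"""


class MTGrowthError(Exception):
    """Base class for all package errors."""


class InputError(MTGrowthError, ValueError):
    """Invalid argument, parameter, or malformed input file."""


class DegenerateTraceError(MTGrowthError):
    """A trace whose plateau is indistinguishable from its baseline."""


class UndefinedCrossingError(MTGrowthError):
    """The requested fractional level is never reached by the trace."""


class InsufficientWindowError(MTGrowthError):
    """Fewer than three samples fall inside the log-log fit window."""


class TraceRejected(MTGrowthError):
    """A trace failed pre-analysis screening.

    Attributes
    ----------
    reason : str
        One of ``"incomplete"`` (non-finite tail, e.g. a bubble ended the
        recording), ``"nonfinite"`` (non-finite values elsewhere), or
        ``"spike"`` (an isolated optical-density spike).
    run_id : str
        Identifier of the offending run, when known.
    """

    def __init__(self, reason: str, run_id: str = "", message: str = ""):
        self.reason = reason
        self.run_id = run_id
        super().__init__(message or f"trace rejected ({reason})"
                         + (f" [run {run_id}]" if run_id else ""))


class SParameterWarning(UserWarning):
    """Raised when a power budget implies negative absorbed power."""
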