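"""Package-wide exception types."""


class PhotophysError(Exception):
    """Base class for all photophys errors."""


class DegenerateDataError(PhotophysError):
    """Input carries no resolvable signal (e.g. a flat fluorescence trace)."""


class FitConvergenceError(PhotophysError):
    """A nonlinear fit failed to converge; diagnostics are in the message."""


class InfeasibleTargetError(PhotophysError):
    """A synthetic ground-truth request violates a physical constraint."""
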