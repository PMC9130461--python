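"""Exception hierarchy for pscfit."""


class PscfitError(Exception):
    """Base class for all pscfit errors."""


class KineticsError(PscfitError, ValueError):
    """Invalid kinetics parameters (invariant violation)."""


class DegenerateKineticsError(KineticsError):
    """Removable-singularity parameter combination (tau_rise == tau_decay)
    evaluated without opting into the analytic limiting rule."""


class PeakSolverError(PscfitError, RuntimeError):
    """Peak-time solver failure (no stationary point in the bracket, or a
    supplied peak time that is not a stationary point)."""


class FitError(PscfitError, RuntimeError):
    """Nonlinear least-squares fit failure."""


class TraceError(PscfitError, ValueError):
    """Invalid sampled trace (non-uniform grid, too short, bad units...)."""


class TraceFormatError(TraceError):
    """Malformed trace file (header, column or row format problems)."""


class AnalysisError(PscfitError, ValueError):
    """Trace-analysis rule cannot be applied (empty window, zero peak...)."""
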