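"""Uniformly sampled current/conductance traces and peak extraction."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional

import numpy as np

from .errors import AnalysisError, TraceError

__all__ = ["SampledTrace", "FitWindow", "PeakEstimate", "detect_peak"]

#: allowed jitter when checking sampling uniformity (ms)
UNIFORMITY_TOL = 1e-6


@dataclass(frozen=True)
class FitWindow:
    """Half-open-ish time window [start, end] in ms used to restrict a fit."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise TraceError(f"window start {self.start} must precede end {self.end}")


class PeakEstimate(NamedTuple):
    time: float       # ms
    amplitude: float  # signed, baseline-subtracted, trace units


@dataclass(frozen=True)
class SampledTrace:
    """A uniformly sampled (time, value) series.

    times : strictly increasing, uniform to within 1e-6 ms (>= 10 samples).
    values : current (pA) or conductance samples, same length as times.
    units_label : free-text unit tag, e.g. "pA".
    stim_time : optional stimulation time (ms) used by peak detection,
        baseline estimation and the ratio/QC rules.
    """

    times: np.ndarray
    values: np.ndarray
    units_label: str = "pA"
    stim_time: Optional[float] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise TraceError("times and values must be 1-D and of equal length")
        if len(t) < 10:
            raise TraceError(f"need at least 10 samples, got {len(t)}")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise TraceError("timestamps must be strictly increasing")
        if steps.max() - steps.min() > UNIFORMITY_TOL:
            raise TraceError(
                "non-uniform sampling: dt spread "
                f"{steps.max() - steps.min():.3g} ms exceeds {UNIFORMITY_TOL} ms"
            )

    @property
    def dt(self) -> float:
        """Sampling interval (ms)."""
        return float(np.mean(np.diff(self.times)))

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def with_values(self, values: np.ndarray, **kw) -> "SampledTrace":
        return replace(self, values=np.asarray(values, dtype=float), **kw)

    def baseline(self, pre_ms: float = 10.0) -> float:
        """Mean value over the ``pre_ms`` ms preceding stim_time (or over
        all pre-stimulus samples if fewer are available)."""
        if self.stim_time is None:
            raise TraceError("stim_time required for baseline estimation")
        mask = (self.times < self.stim_time) & (self.times >= self.stim_time - pre_ms)
        if not mask.any():
            mask = self.times < self.stim_time
        if not mask.any():
            return 0.0
        return float(self.values[mask].mean())

    def baseline_subtracted(self, pre_ms: float = 10.0) -> "SampledTrace":
        return self.with_values(self.values - self.baseline(pre_ms))

    def window_mask(self, w: FitWindow) -> np.ndarray:
        if w.start < self.times[0] - UNIFORMITY_TOL or w.end > self.times[-1] + UNIFORMITY_TOL:
            raise TraceError(
                f"window [{w.start}, {w.end}] exceeds the trace span "
                f"[{self.times[0]}, {self.times[-1]}]"
            )
        return (self.times >= w.start) & (self.times <= w.end)


def detect_peak(trace: SampledTrace, *, baseline_ms: float = 10.0) -> PeakEstimate:
    """Time and signed amplitude of the largest-magnitude post-stimulus
    excursion, after subtracting the pre-stimulus baseline."""
    if trace.stim_time is None:
        raise TraceError("stim_time required for peak detection")
    base = trace.baseline(baseline_ms)
    mask = trace.times >= trace.stim_time
    if not mask.any():
        raise AnalysisError("no samples at or after stim_time")
    vals = trace.values[mask] - base
    idx = int(np.argmax(np.abs(vals)))
    return PeakEstimate(float(trace.times[mask][idx]), float(vals[idx]))
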