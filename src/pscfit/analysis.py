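"""Paired-recording analysis rules: NMDA/AMPA ratio, QC, AMPA subtraction.

The ratio protocol pairs voltage-clamp recordings of the same cell at
-70 mV (AMPA-dominated; NMDA receptors are Mg-blocked) and +40 mV (the
block is relieved).  The AMPA component is the peak of the -70 mV trace,
the NMDA component is the mean current 50-60 ms after the stimulus at
+40 mV, where the fast AMPA current has decayed away.  Ratios are formed
per cell, then averaged within each (input region, cell type) group —
never as a ratio of group means.

The QC rule drops paired recordings whose apparent NMDA current peaks at
or before the AMPA current: NMDA receptors have slower kinetics, so such
traces indicate that no genuine NMDA component was isolated (seen in some
fast-spiking interneurons).
"""

from __future__ import annotations

from typing import Dict, Iterable, NamedTuple, Tuple

import numpy as np
import pandas as pd

from .errors import AnalysisError, TraceError
from .trace import SampledTrace, detect_peak

__all__ = [
    "QCDecision",
    "qc_exclude_trace",
    "nmda_ampa_ratio",
    "aggregate_ratios",
    "subtract_ampa_component",
    "NMDA_WINDOW_MS",
]

#: NMDA quantification window relative to the stimulus (ms)
NMDA_WINDOW_MS = (50.0, 60.0)


class QCDecision(NamedTuple):
    exclude: bool
    reason: str


def qc_exclude_trace(nmda_trace: SampledTrace,
                     ampa_trace: SampledTrace) -> QCDecision:
    """Exclude the pair iff the NMDA trace peaks at or before the AMPA one."""
    if nmda_trace.stim_time != ampa_trace.stim_time:
        raise TraceError("paired traces must share stim_time")
    t_nmda = detect_peak(nmda_trace).time
    t_ampa = detect_peak(ampa_trace).time
    if t_nmda <= t_ampa:
        return QCDecision(True,
                          f"NMDA peak at {t_nmda} ms is not after the AMPA peak "
                          f"at {t_ampa} ms (NMDA kinetics should be slower)")
    return QCDecision(False, "")


def nmda_ampa_ratio(minus70: SampledTrace, plus40: SampledTrace,
                    *, window_ms: Tuple[float, float] = NMDA_WINDOW_MS) -> float:
    """Per-cell NMDA/AMPA ratio.

    AMPA component: |peak| of the -70 mV trace.  NMDA component: |mean|
    of the +40 mV trace over stim_time + [50, 60] ms.  Both traces must be
    baseline-subtracted (their pre-stimulus baseline is removed here using
    the standard rule) and carry stim_time.
    """
    if minus70.stim_time is None or plus40.stim_time is None:
        raise TraceError("both traces need stim_time")
    ampa = abs(detect_peak(minus70).amplitude)
    if ampa == 0:
        raise AnalysisError("AMPA component is zero; ratio undefined")
    lo = plus40.stim_time + window_ms[0]
    hi = plus40.stim_time + window_ms[1]
    if plus40.times[-1] < hi - 1e-9:
        raise AnalysisError(
            f"+40 mV trace ends at {plus40.times[-1]} ms; it must cover the "
            f"NMDA window up to {hi} ms after the stimulus"
        )
    base = plus40.baseline()
    mask = (plus40.times >= lo) & (plus40.times <= hi)
    nmda = abs(float(np.mean(plus40.values[mask] - base)))
    return nmda / ampa


def aggregate_ratios(per_cell: Iterable[Tuple[str, float]]) -> pd.Series:
    """Group-average NMDA/AMPA ratios.

    ``per_cell`` yields (group label, per-cell ratio) records; the result
    is the arithmetic mean of the per-cell ratios within each group.  The
    per-cell ratio is computed first and averaged second (mean of ratios),
    which differs from the ratio of group-mean components.
    """
    df = pd.DataFrame(list(per_cell), columns=["group", "ratio"])
    if df.empty:
        raise AnalysisError("no per-cell ratio records supplied")
    if df["ratio"].isna().any():
        raise AnalysisError("NaN ratio in the per-cell records")
    return df.groupby("group")["ratio"].mean()


def subtract_ampa_component(raw_plus40: SampledTrace,
                            ampa_template: SampledTrace,
                            scale: float) -> SampledTrace:
    """Pointwise removal of a scaled AMPA template from a raw +40 mV trace.

    Used for the pharmacological separation workflow: the AMPA-only trace
    (recorded under NMDA blockade, or taken at -70 mV and rescaled by the
    driving-force ratio) is subtracted to isolate the NMDA component.
    The two traces must share the sampling grid exactly (within 1e-9 ms).
    """
    if len(raw_plus40.times) != len(ampa_template.times) or not np.allclose(
            raw_plus40.times, ampa_template.times, rtol=0, atol=1e-9):
        raise TraceError("sampling grids of raw trace and template differ")
    out = raw_plus40.with_values(raw_plus40.values - scale * ampa_template.values)
    return out


def driving_force_scale(v_target: float, v_template: float,
                        e_rev: float = 0.0) -> float:
    """Default AMPA-subtraction scale: linear driving-force ratio
    ``(v_target - e_rev) / (v_template - e_rev)``."""
    denom = v_template - e_rev
    if denom == 0:
        raise AnalysisError("template held at the reversal potential")
    return (v_target - e_rev) / denom
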