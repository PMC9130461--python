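"""Synthetic PSC traces with known ground truth.

The generator emulates the statistical structure of averaged voltage-clamp
PSC recordings: a conductance profile (bi- or tri-exponential) evaluated on
a uniform 10-20 kHz grid, converted to current at a holding potential
(Mg block applied for NMDA-type synapses), optionally low-pass filtered
(first-order, emulating acquisition filtering), with additive i.i.d.
Gaussian noise.  Currents are emitted in pA (the model works in uS/mV/nA;
1 nA = 1000 pA).  All randomness flows through the explicit seed, so a
spec reproduces its trace bit-for-bit.

``generate_paired_cell`` builds the -70/+40 mV pair of a virtual cell with
the NMDA conductance scaled so the noiseless pair returns a prescribed
NMDA/AMPA ratio through the standard analysis rules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .analysis import nmda_ampa_ratio
from .errors import KineticsError
from .fitting import TriExpPSCModel
from .kinetics import (
    BiExpKinetics,
    MgBlockParams,
    SynapseModel,
    TriExpKinetics,
)
from .peak import newton_peak_time
from .trace import SampledTrace

__all__ = [
    "GeneratorSpec",
    "generate_trace",
    "generate_paired_cell",
    "PairedRecording",
    "sample_physiological_kinetics",
    "recovery_suite",
    "PHYSIO_RANGES",
]

#: physiological sampling ranges for random tri-exponential kinetics (ms);
#: spans AMPA-like (few-ms decays) through NMDA-like (hundreds of ms) PSCs
PHYSIO_RANGES = {
    "tau_r": (0.2, 5.0),
    "tau_f": (2.0, 60.0),
    "tau_s": (60.0, 600.0),
    "slow_fraction": (0.1, 0.9),
}

NA_TO_PA = 1000.0


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic trace.

    model : the synapse (kinetics + reversal potential + optional Mg block).
    holding_mV : clamp potential.
    sampling_khz : 10-20 kHz emulates the acquisition hardware.
    duration : trace length (ms); the stimulus sits at model.kinetics.t0.
    noise_sd : additive Gaussian noise sd in pA.
    filter_khz : optional first-order low-pass corner.
    """

    model: SynapseModel
    holding_mV: float = -70.0
    sampling_khz: float = 10.0
    duration: float = 500.0
    noise_sd: float = 0.0
    seed: int = 0
    filter_khz: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sampling_khz <= 0:
            raise KineticsError("sampling_khz must be positive")
        if self.duration <= 0:
            raise KineticsError("duration must be positive")
        if self.noise_sd < 0:
            raise KineticsError("noise_sd must be nonnegative")


def _lowpass(values: np.ndarray, dt_ms: float, corner_khz: float) -> np.ndarray:
    """First-order (RC) low-pass, matched to the sampling interval."""
    alpha = 1.0 - np.exp(-2.0 * np.pi * corner_khz * dt_ms)
    out = np.empty_like(values)
    acc = values[0]
    for i, v in enumerate(values):
        acc += alpha * (v - acc)
        out[i] = acc
    return out


def generate_trace(spec: GeneratorSpec) -> Tuple[SampledTrace, Dict]:
    """Evaluate the model current on the grid, filter, add noise.

    Returns the trace (pA) plus a ground-truth record with the exact
    generating parameters.
    """
    dt = 1.0 / spec.sampling_khz  # ms
    times = np.arange(0.0, spec.duration, dt)
    current_na = spec.model.current(times, spec.holding_mV)
    values = np.asarray(current_na, dtype=float) * NA_TO_PA
    if spec.filter_khz is not None:
        values = _lowpass(values, dt, spec.filter_khz)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    trace = SampledTrace(times, values, units_label="pA",
                         stim_time=spec.model.kinetics.t0)
    truth = {
        "kinetics": vars(spec.model.kinetics) | {
            "kind": type(spec.model.kinetics).__name__},
        "e_rev": spec.model.e_rev,
        "mg": vars(spec.model.mg) if spec.model.mg else None,
        "holding_mV": spec.holding_mV,
        "sampling_khz": spec.sampling_khz,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "filter_khz": spec.filter_khz,
    }
    return trace, truth


@dataclass(frozen=True)
class PairedRecording:
    """A virtual cell's -70 mV / +40 mV pair with generation ground truth."""

    minus70: SampledTrace
    plus40: SampledTrace
    nmda_scale: float
    target_ratio: float
    truth: Dict


def generate_paired_cell(spec_ampa: GeneratorSpec, spec_nmda: GeneratorSpec,
                         target_ratio: float) -> PairedRecording:
    """Build a paired recording whose noiseless NMDA/AMPA ratio equals
    ``target_ratio`` through the standard analysis rules.

    Both holding potentials carry the sum of the AMPA and the (Mg-blocked)
    NMDA current; the NMDA peak conductance is rescaled by a numerically
    solved factor so that the ratio pipeline applied to the noiseless pair
    returns exactly the target.  Noise (per the two specs' noise_sd/seed)
    is added afterwards.
    """
    if target_ratio <= 0:
        raise KineticsError("target_ratio must be positive")
    if spec_ampa.sampling_khz != spec_nmda.sampling_khz or \
            spec_ampa.duration != spec_nmda.duration:
        raise KineticsError("paired specs must share sampling and duration")
    if not spec_nmda.model.is_nmda:
        raise KineticsError("spec_nmda.model must carry Mg-block parameters")

    quiet = {"noise_sd": 0.0}
    ampa70, _ = generate_trace(replace(spec_ampa, holding_mV=-70.0, **quiet))
    ampa40, _ = generate_trace(replace(spec_ampa, holding_mV=+40.0, **quiet))
    nmda70, _ = generate_trace(replace(spec_nmda, holding_mV=-70.0, **quiet))
    nmda40, _ = generate_trace(replace(spec_nmda, holding_mV=+40.0, **quiet))

    def ratio_minus_target(s: float) -> float:
        m70 = ampa70.with_values(ampa70.values + s * nmda70.values)
        p40 = ampa40.with_values(ampa40.values + s * nmda40.values)
        return nmda_ampa_ratio(m70, p40) - target_ratio

    # ratio grows monotonically with the NMDA scale; bracket then solve
    lo, hi = 1e-9, 1.0
    while ratio_minus_target(hi) < 0 and hi < 1e9:
        hi *= 4.0
    scale = brentq(ratio_minus_target, lo, hi, xtol=1e-12, rtol=1e-14)

    minus70 = ampa70.with_values(ampa70.values + scale * nmda70.values)
    plus40 = ampa40.with_values(ampa40.values + scale * nmda40.values)
    if spec_ampa.noise_sd > 0 or spec_nmda.noise_sd > 0:
        rng70 = np.random.default_rng(spec_ampa.seed)
        rng40 = np.random.default_rng(spec_nmda.seed)
        sd = max(spec_ampa.noise_sd, spec_nmda.noise_sd)
        minus70 = minus70.with_values(
            minus70.values + rng70.normal(0, sd, minus70.values.shape))
        plus40 = plus40.with_values(
            plus40.values + rng40.normal(0, sd, plus40.values.shape))
    truth = {
        "nmda_scale": scale,
        "target_ratio": target_ratio,
        "ampa_kinetics": vars(spec_ampa.model.kinetics),
        "nmda_kinetics": vars(spec_nmda.model.kinetics),
    }
    return PairedRecording(minus70, plus40, float(scale), float(target_ratio),
                           truth)


def sample_physiological_kinetics(rng: np.random.Generator,
                                  *, gbar: float = 1e-3,
                                  t0: float = 0.0) -> TriExpKinetics:
    """One random tri-exponential kinetics set from the documented
    physiological ranges (rejection keeps tau_r < tau_f)."""
    lo, hi = PHYSIO_RANGES["tau_r"]
    tau_r = rng.uniform(lo, hi)
    lo, hi = PHYSIO_RANGES["tau_f"]
    tau_f = rng.uniform(lo, hi)
    while tau_f <= tau_r:
        tau_f = rng.uniform(lo, hi)
    lo, hi = PHYSIO_RANGES["tau_s"]
    tau_s = rng.uniform(lo, hi)
    lo, hi = PHYSIO_RANGES["slow_fraction"]
    fs = rng.uniform(lo, hi)
    return TriExpKinetics(tau_r, tau_f, tau_s, 1.0 - fs, fs, gbar=gbar, t0=t0)


def recovery_suite(n: int, seed: int,
                   noise_sd_grid: Sequence[float] = (0.0, 0.01, 0.02, 0.05),
                   *, sampling_khz: float = 10.0,
                   stim_time: float = 20.0) -> pd.DataFrame:
    """Parameter-recovery study over random physiological kinetics.

    For each of ``n`` kinetics sets and each noise level (noise sd given as
    a fraction of the noiseless peak amplitude), generates an AMPA-type
    trace at -70 mV, fits the full tri-exponential model and tabulates the
    median relative error per parameter, the Newton iteration statistics
    and the fit-failure count.  Trace duration scales with tau_s
    (stim + 5 tau_s) so slow kinetics are fully sampled.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    kins = [sample_physiological_kinetics(rng, t0=stim_time) for _ in range(n)]
    rows = []
    for noise_frac in noise_sd_grid:
        recs = {p: [] for p in ("tau_r", "tau_f", "tau_s", "i_f", "i_s")}
        iters: List[int] = []
        failures = 0
        for i, kin in enumerate(kins):
            model = SynapseModel(kin, e_rev=0.0)
            spec0 = GeneratorSpec(model, holding_mV=-70.0,
                                  sampling_khz=sampling_khz,
                                  duration=stim_time + 5.0 * kin.tau_s,
                                  noise_sd=0.0, seed=0)
            clean, _ = generate_trace(spec0)
            peak_pA = float(np.abs(clean.values).max())
            sd = noise_frac * peak_pA
            spec = replace(spec0, noise_sd=sd,
                           seed=int(rng.integers(0, 2**31 - 1)))
            trace, _ = generate_trace(spec)
            try:
                res = TriExpPSCModel(trace).fit()
            except Exception:
                failures += 1
                continue
            truth = kin.normalized()
            got = res.kinetics
            for p in recs:
                tv = getattr(truth, p)
                recs[p].append(abs(getattr(got, p) - tv) / abs(tv))
            iters.append(res.peak.iterations)
        row = {"noise_frac": noise_frac, "n": n, "failures": failures,
               "newton_iter_max": max(iters) if iters else np.nan,
               "newton_iter_p99": float(np.percentile(iters, 99)) if iters else np.nan}
        for p, errs in recs.items():
            row[f"median_rel_err_{p}"] = float(np.median(errs)) if errs else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
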