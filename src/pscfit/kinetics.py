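"""Conductance kinetics of AMPA/NMDA postsynaptic currents.

Two conductance profiles are supported:

* the classical bi-exponential profile

  ``g(t) = gbar * K * (exp(-(t-t0)/tau_decay) - exp(-(t-t0)/tau_rise))``

  with a closed-form peak time and normalization factor, and

* a tri-exponential profile in which the decay phase keeps both the fast
  and the slow component of a double-exponential decay fit,

  ``g(t) = gbar * K * (I_f exp(-(t-t0)/tau_f) + I_s exp(-(t-t0)/tau_s)
                       - Ktilde exp(-(t-t0)/tau_r))``

  where ``Ktilde = I_f + I_s`` makes the profile start at exactly zero at
  the presynaptic spike time ``t0``.  The tri-exponential peak time has no
  closed form; it is computed numerically by :mod:`pscfit.peak`.

Units follow the NEURON mechanism conventions: time in ms, voltage in mV,
conductance in uS, current in nA (uS * mV = nA).  Conductances are
nonnegative; the sign of a current comes entirely from the driving force
``V - E_rev``, so a -70 mV recording of an excitatory synapse is negative
(inward).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .errors import DegenerateKineticsError, KineticsError, PeakSolverError

__all__ = [
    "BiExpKinetics",
    "TriExpKinetics",
    "MgBlockParams",
    "SynapseModel",
    "biexp_peak_time",
    "biexp_norm_factor",
    "biexp_conductance",
    "triexp_norm_factor",
    "triexp_conductance",
    "stationarity_residual",
    "weighted_tau",
    "mg_block",
    "synaptic_current",
]

#: relative tolerance on the stationarity balance used to accept an
#: externally supplied peak time
STATIONARITY_RTOL = 1e-8


@dataclass(frozen=True)
class BiExpKinetics:
    """Classical two-exponential conductance parameters.

    Parameters
    ----------
    tau_rise, tau_decay : float
        Rise and decay time constants (ms). ``tau_decay > tau_rise`` is
        required; the equal-tau alpha-function limit is only reachable
        through the explicit ``allow_limit`` flag of the evaluation
        functions.
    gbar : float
        Peak conductance (uS).
    t0 : float
        Presynaptic spike time (ms).
    """

    tau_rise: float
    tau_decay: float
    gbar: float = 1.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tau_rise > 0 and self.tau_decay > 0):
            raise KineticsError("time constants must be positive")
        if self.tau_decay < self.tau_rise:
            raise KineticsError(
                f"tau_decay ({self.tau_decay}) must be >= tau_rise ({self.tau_rise})"
            )
        if self.gbar < 0:
            raise KineticsError("gbar must be nonnegative")

    @property
    def is_degenerate(self) -> bool:
        """True when tau_rise == tau_decay (alpha-function limit)."""
        return self.tau_decay == self.tau_rise


@dataclass(frozen=True)
class TriExpKinetics:
    """Rise constant plus fast/slow decay constants with amplitude fractions.

    ``0 < tau_r < tau_f <= tau_s`` (ms); ``i_f, i_s >= 0`` with
    ``i_f + i_s > 0``.  The fractions are stored un-normalized; the derived
    quantity ``Ktilde = i_f + i_s`` is always recomputed, never stored.
    """

    tau_r: float
    tau_f: float
    tau_s: float
    i_f: float
    i_s: float
    gbar: float = 1.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.tau_r < self.tau_f <= self.tau_s):
            raise KineticsError(
                "need 0 < tau_r < tau_f <= tau_s, got "
                f"tau_r={self.tau_r}, tau_f={self.tau_f}, tau_s={self.tau_s}"
            )
        if self.i_f < 0 or self.i_s < 0:
            raise KineticsError("amplitude fractions must be nonnegative")
        if self.i_f + self.i_s <= 0:
            raise KineticsError("i_f + i_s must be positive")
        if self.gbar < 0:
            raise KineticsError("gbar must be nonnegative")

    @property
    def ktilde(self) -> float:
        """Sum of the amplitude fractions (subtracted with the rise
        exponential so the profile starts at zero)."""
        return self.i_f + self.i_s

    def normalized(self) -> "TriExpKinetics":
        """Same kinetics with fractions rescaled to sum to one."""
        k = self.ktilde
        return TriExpKinetics(
            self.tau_r, self.tau_f, self.tau_s,
            self.i_f / k, self.i_s / k, self.gbar, self.t0,
        )

    def reduces_to_biexp(self) -> Optional[BiExpKinetics]:
        """The equivalent bi-exponential kinetics when only one decay
        component is active (i_s == 0, i_f == 0, or tau_f == tau_s);
        None otherwise."""
        if self.i_s == 0:
            return BiExpKinetics(self.tau_r, self.tau_f, self.gbar, self.t0)
        if self.i_f == 0:
            return BiExpKinetics(self.tau_r, self.tau_s, self.gbar, self.t0)
        if self.tau_f == self.tau_s:
            return BiExpKinetics(self.tau_r, self.tau_f, self.gbar, self.t0)
        return None


@dataclass(frozen=True)
class MgBlockParams:
    """Voltage-dependent magnesium block of the NMDA receptor.

    ``block(V) = 1 / (1 + exp(-a V) * mg_conc / b)``

    Defaults are the classic Jahr-Stevens constants with a physiological
    1 mM extracellular Mg2+; both are user-overridable assumptions (see
    docs/methods.md).
    """

    a: float = 0.062   # 1/mV
    b: float = 3.57    # mM
    mg_conc: float = 1.0  # mM

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise KineticsError("Mg-block constants a, b must be positive")
        if self.mg_conc < 0:
            raise KineticsError("mg_conc must be nonnegative")


def biexp_peak_time(k: BiExpKinetics, *, allow_limit: bool = False) -> float:
    """Closed-form peak time of the bi-exponential conductance.

    ``t_peak = t0 + tau_d tau_r / (tau_d - tau_r) * ln(tau_d / tau_r)``;
    in the tau_rise -> tau_decay limit this tends to ``t0 + tau``, which is
    returned only when ``allow_limit`` is set.
    """
    if k.is_degenerate:
        if not allow_limit:
            raise DegenerateKineticsError(
                "tau_rise == tau_decay: pass allow_limit=True for the "
                "alpha-function limit"
            )
        return k.t0 + k.tau_rise
    td, tr = k.tau_decay, k.tau_rise
    return k.t0 + td * tr / (td - tr) * math.log(td / tr)


def biexp_norm_factor(k: BiExpKinetics, *, allow_limit: bool = False) -> float:
    """Normalization constant K making the profile reach gbar at its peak."""
    tp = biexp_peak_time(k, allow_limit=allow_limit) - k.t0
    if k.is_degenerate:
        # alpha function: g ~ (x/tau) exp(1 - x/tau), peak value exp(-1)*... = 1
        return math.e / k.tau_rise  # so that K * x * exp(-x/tau) peaks at 1
    return 1.0 / (math.exp(-tp / k.tau_decay) - math.exp(-tp / k.tau_rise))


def biexp_conductance(k: BiExpKinetics, t, *, allow_limit: bool = False):
    """Evaluate the bi-exponential conductance at time(s) ``t`` (uS).

    Returns 0 for ``t < t0`` (causality).  Vectorized over ``t``.
    """
    t = np.asarray(t, dtype=float)
    x = t - k.t0
    K = biexp_norm_factor(k, allow_limit=allow_limit)
    if k.is_degenerate:
        prof = K * x * np.exp(-x / k.tau_rise)
    else:
        prof = K * (np.exp(-x / k.tau_decay) - np.exp(-x / k.tau_rise))
    g = k.gbar * np.where(x >= 0, prof, 0.0)
    return g if g.ndim else float(g)


def stationarity_residual(k: TriExpKinetics, t: float) -> float:
    """Relative imbalance of the peak-time stationarity condition at ``t``.

    The peak satisfies
    ``I_f/tau_f e^{-x/tau_f} + I_s/tau_s e^{-x/tau_s}
      = Ktilde/tau_r e^{-x/tau_r}``
    (x = t - t0).  Returns |lhs - rhs| / max(lhs, rhs); zero at the exact
    stationary point.
    """
    x = t - k.t0
    lhs = (k.i_f / k.tau_f * math.exp(-x / k.tau_f)
           + k.i_s / k.tau_s * math.exp(-x / k.tau_s))
    rhs = k.ktilde / k.tau_r * math.exp(-x / k.tau_r)
    denom = max(lhs, rhs)
    if denom == 0:
        return math.inf
    return abs(lhs - rhs) / denom


def _triexp_profile(k: TriExpKinetics, x):
    """Un-normalized tri-exponential shape at x = t - t0 (may be array)."""
    return (k.i_f * np.exp(-x / k.tau_f)
            + k.i_s * np.exp(-x / k.tau_s)
            - k.ktilde * np.exp(-x / k.tau_r))


def triexp_norm_factor(k: TriExpKinetics, t_peak: float) -> float:
    """Normalization constant K for the tri-exponential profile.

    ``t_peak`` must be the stationary point produced by the peak solver for
    the same kinetics.
    """
    denom = float(_triexp_profile(k, t_peak - k.t0))
    if denom <= 0:
        raise PeakSolverError(
            f"invalid peak time {t_peak}: un-normalized profile is {denom} <= 0"
        )
    return 1.0 / denom


def triexp_conductance(k: TriExpKinetics, t, t_peak: float, *,
                       check_peak: bool = True):
    """Evaluate the tri-exponential conductance at time(s) ``t`` (uS).

    ``t_peak`` must come from :func:`pscfit.peak.newton_peak_time` (or the
    fallback) for this same kinetics; it is validated against the
    stationarity condition unless ``check_peak=False``.
    """
    if check_peak and stationarity_residual(k, t_peak) > STATIONARITY_RTOL:
        raise PeakSolverError(
            f"supplied t_peak={t_peak} is not a stationary point "
            f"(residual {stationarity_residual(k, t_peak):.3e})"
        )
    K = triexp_norm_factor(k, t_peak)
    t = np.asarray(t, dtype=float)
    x = t - k.t0
    g = k.gbar * K * np.where(x >= 0, _triexp_profile(k, np.maximum(x, 0.0)), 0.0)
    return g if g.ndim else float(g)


def weighted_tau(i_f: float, i_s: float, tau_f: float, tau_s: float) -> float:
    """Amplitude-weighted mean decay time constant.

    ``tau_w = i_f/(i_f+i_s) * tau_f + i_s/(i_f+i_s) * tau_s`` — the scalar
    often used to collapse a double-exponential decay to a single one.
    """
    total = i_f + i_s
    if total == 0:
        raise KineticsError("i_f + i_s must be nonzero for the weighted tau")
    return (i_f * tau_f + i_s * tau_s) / total


def mg_block(p: MgBlockParams, v):
    """Fraction of NMDA conductance left unblocked by Mg2+ at potential v.

    Sigmoidal in v, in (0, 1]; identically 1 when mg_conc = 0.
    Vectorized over ``v``.
    """
    v = np.asarray(v, dtype=float)
    out = 1.0 / (1.0 + np.exp(-p.a * v) * (p.mg_conc / p.b))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SynapseModel:
    """A receptor conductance plus its current mechanism.

    ``mg`` absent means AMPA-type (ohmic); present means NMDA-type (the
    driving force is scaled by the voltage-dependent Mg block).
    """

    kinetics: Union[BiExpKinetics, TriExpKinetics]
    e_rev: float = 0.0
    mg: Optional[MgBlockParams] = None

    @property
    def is_nmda(self) -> bool:
        return self.mg is not None

    def peak_time(self) -> float:
        """Conductance peak time (closed form or Newton-solved)."""
        if isinstance(self.kinetics, BiExpKinetics):
            return biexp_peak_time(self.kinetics)
        from .peak import newton_peak_time  # deferred: peak imports kinetics

        return newton_peak_time(self.kinetics).t_peak

    def conductance(self, t):
        """Conductance profile at time(s) t (uS)."""
        if isinstance(self.kinetics, BiExpKinetics):
            return biexp_conductance(self.kinetics, t)
        return triexp_conductance(self.kinetics, t, self.peak_time())

    def current(self, t, v):
        """Synaptic current (nA) at time(s) t and holding potential v (mV)."""
        return synaptic_current(self, self.conductance(t), v)

    def with_gbar(self, gbar: float) -> "SynapseModel":
        from dataclasses import replace

        return SynapseModel(replace(self.kinetics, gbar=gbar), self.e_rev, self.mg)


def synaptic_current(m: SynapseModel, g, v):
    """Current through the synapse: g*(V - E_rev), Mg-blocked for NMDA.

    g in uS, v in mV, result in nA.  Vectorized over g and/or v.
    """
    g = np.asarray(g, dtype=float)
    drive = np.asarray(v, dtype=float) - m.e_rev
    if m.is_nmda:
        i = g * mg_block(m.mg, v) * drive
    else:
        i = g * drive
    return i if np.ndim(i) else float(i)
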