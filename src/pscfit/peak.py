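"""Numerical peak time of the tri-exponential conductance.

The tri-exponential profile has no closed-form peak time.  Setting its
derivative to zero and rearranging (divide through by the fast-decay
exponential, take logs) yields a scalar root problem

``F(t) = (t - t0) - c * log(A(t)) = 0``

with ``c = tau_r tau_f / (tau_r - tau_f)`` and

``A(t) = (I_f/Ktilde)(tau_r/tau_f)
         + (I_s/Ktilde)(tau_r/tau_s) * exp((t-t0)(tau_s-tau_f)/(tau_f tau_s))``.

``A`` is a sum of positive terms, so the log is always defined for valid
kinetics; when ``I_s = 0`` or ``tau_f = tau_s`` the exponential term is
constant and F is affine, with root equal to the bi-exponential closed form.

``newton_peak_time`` runs plain Newton iteration on F from a closed-form
initial guess (the bi-exponential peak time computed with the weighted mean
decay constant), stopping on the step magnitude |d| <= tol.  Quadratic
convergence makes machine precision reachable in a handful of iterations.
A bracketed-bisection fallback on the sign of the conductance derivative
safeguards the rare non-convergent cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

from .errors import PeakSolverError
from .kinetics import (
    BiExpKinetics,
    TriExpKinetics,
    biexp_peak_time,
    stationarity_residual,
    weighted_tau,
)

__all__ = [
    "NewtonSettings",
    "NewtonResult",
    "peak_target_f",
    "peak_target_fprime",
    "default_initial_guess",
    "newton_peak_time",
    "fallback_peak_time",
]

#: relative stationarity residual below which a root is accepted
RESIDUAL_RTOL = 1e-8


@dataclass(frozen=True)
class NewtonSettings:
    """Solver settings.

    tol : step-size tolerance (ms) — convergence means |Newton step| <= tol.
    max_iter : iteration cap.
    initial_guess : explicit starting time (ms), or None for the default
        closed-form guess (bi-exp peak time with tau_decay = weighted tau).
    """

    tol: float = 1e-12
    max_iter: int = 50
    initial_guess: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class NewtonResult:
    """Solved peak time plus convergence diagnostics.

    ``converged`` refers to the Newton iteration itself: |final_step| <= tol
    within max_iter and the stationarity residual below threshold.  When the
    bisection fallback produced ``t_peak`` instead, ``method`` says so and
    ``converged`` is False; the residual still certifies the root.
    ``steps`` logs |d| per iteration for convergence-order diagnostics.
    """

    t_peak: float
    iterations: int
    final_step: float
    converged: bool
    stationarity_residual: float
    steps: Tuple[float, ...] = ()
    method: str = "newton"


def _coeffs(k: TriExpKinetics):
    """(c, a0, a1, r): F(t) = x - c*log(a0 + a1*exp(r*x)), x = t - t0."""
    kt = k.ktilde
    c = k.tau_r * k.tau_f / (k.tau_r - k.tau_f)
    a0 = (k.i_f / kt) * (k.tau_r / k.tau_f)
    a1 = (k.i_s / kt) * (k.tau_r / k.tau_s)
    r = (k.tau_s - k.tau_f) / (k.tau_f * k.tau_s)
    return c, a0, a1, r


def peak_target_f(k: TriExpKinetics, t: float) -> float:
    """Root target F(t); F(t_peak) = 0.  Units: ms."""
    c, a0, a1, r = _coeffs(k)
    x = t - k.t0
    arg = a0 + a1 * math.exp(r * x)
    if arg <= 0:
        raise PeakSolverError(f"log argument {arg} <= 0 at t={t}")
    return x - c * math.log(arg)


def peak_target_fprime(k: TriExpKinetics, t: float) -> float:
    """Analytic dF/dt (dimensionless).

    With A(x) = a0 + a1 exp(r x):  F'(t) = 1 - c * r * a1 exp(r x) / A(x).
    Constant 1 when the slow component is absent (F affine).
    """
    c, a0, a1, r = _coeffs(k)
    x = t - k.t0
    e = math.exp(r * x)
    arg = a0 + a1 * e
    if arg <= 0:
        raise PeakSolverError(f"log argument {arg} <= 0 at t={t}")
    return 1.0 - c * r * a1 * e / arg


def default_initial_guess(k: TriExpKinetics) -> float:
    """Closed-form starting point: bi-exponential peak time evaluated with
    the weighted mean decay constant in place of tau_decay."""
    tw = weighted_tau(k.i_f, k.i_s, k.tau_f, k.tau_s)
    return biexp_peak_time(BiExpKinetics(k.tau_r, tw, k.gbar, k.t0))


def _conductance_rate_sign(k: TriExpKinetics, x: float) -> float:
    """Sign of dg/dt at x = t - t0 (normalization-free)."""
    val = (k.ktilde / k.tau_r * math.exp(-x / k.tau_r)
           - k.i_f / k.tau_f * math.exp(-x / k.tau_f)
           - k.i_s / k.tau_s * math.exp(-x / k.tau_s))
    return val


def fallback_peak_time(k: TriExpKinetics, *, xtol: float = 1e-9) -> float:
    """Safeguarded peak time: bracket the sign change of dg/dt on
    (t0, t0 + 20 tau_s], then bisect to ``xtol`` ms.

    The rate is positive immediately after onset (tau_r < tau_f <= tau_s
    guarantees this) and negative past the peak, so a sign change exists for
    any valid kinetics; absence of one signals an error.
    """
    hi = 20.0 * k.tau_s
    lo = min(k.tau_r, hi) * 1e-6
    if _conductance_rate_sign(k, lo) <= 0:
        raise PeakSolverError("conductance not rising at onset: invalid kinetics")
    # geometric scan for the first sign change
    a, b = lo, lo
    found = False
    while b < hi:
        b = min(b * 2.0, hi)
        if _conductance_rate_sign(k, b) <= 0:
            found = True
            break
        a = b
    if not found:
        raise PeakSolverError(
            f"no stationary point of the conductance in (t0, t0 + {hi} ms]"
        )
    while b - a > xtol:
        m = 0.5 * (a + b)
        if _conductance_rate_sign(k, m) > 0:
            a = m
        else:
            b = m
    return k.t0 + 0.5 * (a + b)


def newton_peak_time(k: TriExpKinetics,
                     settings: Optional[NewtonSettings] = None) -> NewtonResult:
    """Tri-exponential conductance peak time by Newton's method on F.

    Iterates ``t <- t - F(t)/F'(t)`` until |step| <= tol or max_iter; the
    accepted root must also satisfy the stationarity condition to within
    a relative residual of 1e-8.  On non-convergence (or a domain error
    during iteration) the bisection fallback supplies the peak time and the
    result is flagged ``converged=False`` with ``method='bisection'``.
    """
    s = settings or NewtonSettings()
    t = s.initial_guess if s.initial_guess is not None else default_initial_guess(k)
    steps = []
    failed = False
    d = math.inf
    niter = 0
    try:
        while abs(d) > s.tol and niter < s.max_iter:
            fp = peak_target_fprime(k, t)
            if fp == 0 or not math.isfinite(fp):
                failed = True
                break
            d = peak_target_f(k, t) / fp
            t -= d
            niter += 1
            steps.append(abs(d))
            if not math.isfinite(t) or t <= k.t0:
                failed = True
                break
    except PeakSolverError:
        failed = True

    if not failed and abs(d) <= s.tol:
        res = stationarity_residual(k, t)
        if res <= RESIDUAL_RTOL:
            return NewtonResult(
                t_peak=t,
                iterations=niter,
                final_step=abs(d),
                converged=True,
                stationarity_residual=res,
                steps=tuple(steps),
                method="newton",
            )

    tp = fallback_peak_time(k)
    return NewtonResult(
        t_peak=tp,
        iterations=niter,
        final_step=abs(d) if math.isfinite(d) else math.inf,
        converged=False,
        stationarity_residual=stationarity_residual(k, tp),
        steps=tuple(steps),
        method="bisection",
    )
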