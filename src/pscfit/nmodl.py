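"""NMODL mechanism-text emitter for the dual AMPA/NMDA synapse.

Emits a NEURON point-process mechanism in which each receptor's
conductance is built from exponential states: one rise state plus one
decay state per decay component.  A tri-exponential receptor therefore
carries two decay states (the fast one and an extra slow one), a
bi-exponential receptor one.  The peak times (tp_ampa, tp_nmda) and
normalization factors (factor_ampa, factor_nmda) are baked in as
precomputed constants — they depend only on the kinetics, so they are
computed once (the tri-exponential peak by Newton's method) rather than
per timestep.  Emission is deterministic: identical inputs give
byte-identical text.
"""

from __future__ import annotations

from typing import Union

from .errors import PeakSolverError
from .kinetics import (
    BiExpKinetics,
    MgBlockParams,
    TriExpKinetics,
    biexp_norm_factor,
    biexp_peak_time,
    triexp_norm_factor,
)
from .peak import NewtonResult

__all__ = ["emit_nmodl"]

Kinetics = Union[BiExpKinetics, TriExpKinetics]


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def _receptor_blocks(tag: str, k: Kinetics, peak: float):
    """Per-receptor (params, states, derivs, gexpr, init, netrec) text."""
    if isinstance(k, TriExpKinetics):
        factor = triexp_norm_factor(k, peak)
        params = [
            f"tau_r_{tag} = {_fmt(k.tau_r)} (ms)",
            f"tau_f_{tag} = {_fmt(k.tau_f)} (ms)",
            f"tau_s_{tag} = {_fmt(k.tau_s)} (ms)",
            f"I_f_{tag} = {_fmt(k.i_f)}",
            f"I_s_{tag} = {_fmt(k.i_s)}",
            f"tp_{tag} = {_fmt(peak - k.t0)} (ms) : output of the Newton's method",
            f"factor_{tag} = {_fmt(factor)}",
        ]
        states = [f"A_{tag}", f"B_{tag}", f"C_{tag}"]
        derivs = [
            f"A_{tag}' = -A_{tag}/tau_r_{tag}",
            f"B_{tag}' = -B_{tag}/tau_f_{tag}",
            f"C_{tag}' = -C_{tag}/tau_s_{tag}",
        ]
        gexpr = f"g_{tag} = gmax_{tag}*factor_{tag}*(B_{tag} + C_{tag} - A_{tag})"
        netrec = [
            f"A_{tag} = A_{tag} + weight*(I_f_{tag} + I_s_{tag})",
            f"B_{tag} = B_{tag} + weight*I_f_{tag}",
            f"C_{tag} = C_{tag} + weight*I_s_{tag}",
        ]
    else:
        factor = biexp_norm_factor(k)
        peak = biexp_peak_time(k)
        params = [
            f"tau_rise_{tag} = {_fmt(k.tau_rise)} (ms)",
            f"tau_decay_{tag} = {_fmt(k.tau_decay)} (ms)",
            f"tp_{tag} = {_fmt(peak - k.t0)} (ms)",
            f"factor_{tag} = {_fmt(factor)}",
        ]
        states = [f"A_{tag}", f"B_{tag}"]
        derivs = [
            f"A_{tag}' = -A_{tag}/tau_rise_{tag}",
            f"B_{tag}' = -B_{tag}/tau_decay_{tag}",
        ]
        gexpr = f"g_{tag} = gmax_{tag}*factor_{tag}*(B_{tag} - A_{tag})"
        netrec = [
            f"A_{tag} = A_{tag} + weight",
            f"B_{tag} = B_{tag} + weight",
        ]
    return params, states, derivs, gexpr, netrec


def emit_nmodl(ampa: Kinetics, nmda: Kinetics, mg: MgBlockParams,
               e_rev: float, peak_times) -> str:
    """Render the mechanism source.

    ``peak_times`` maps 'ampa'/'nmda' to a NewtonResult (or plain float)
    for tri-exponential kinetics; bi-exponential peaks are recomputed from
    the closed form.  Missing or non-converged tri-exponential peaks raise.
    """

    def resolve_peak(tag: str, k: Kinetics) -> float:
        if isinstance(k, BiExpKinetics):
            return biexp_peak_time(k)
        p = (peak_times or {}).get(tag)
        if p is None:
            raise PeakSolverError(f"missing precomputed peak time for {tag}")
        if isinstance(p, NewtonResult):
            if not p.converged:
                raise PeakSolverError(f"peak time for {tag} did not converge")
            return p.t_peak
        return float(p)

    pa, sa, da, ga, na = _receptor_blocks("ampa", ampa, resolve_peak("ampa", ampa))
    pn, sn, dn, gn, nn = _receptor_blocks("nmda", nmda, resolve_peak("nmda", nmda))

    nl = "\n"
    param_lines = nl.join(f"    {p}" for p in pa + pn + [
        f"gmax_ampa = {_fmt(ampa.gbar)} (uS)",
        f"gmax_nmda = {_fmt(nmda.gbar)} (uS)",
        f"e_rev = {_fmt(e_rev)} (mV)",
        f"mg_a = {_fmt(mg.a)} (/mV)",
        f"mg_b = {_fmt(mg.b)} (mM)",
        f"mg = {_fmt(mg.mg_conc)} (mM)",
    ])
    state_lines = nl.join(f"    {s}" for s in sa + sn)
    deriv_lines = nl.join(f"    {d}" for d in da + dn)
    init_lines = nl.join(f"    {s} = 0" for s in sa + sn)
    netrec_lines = nl.join(f"    {x}" for x in na + nn)

    return f"""COMMENT
Dual AMPA/NMDA conductance-based synapse.
The decay phase keeps both the fast and the slow time constant of a
double-exponential fit; peak times and normalization factors are
precomputed constants (tri-exponential peaks via Newton's method).
Generated by pscfit; regeneration from the same parameters is
byte-identical.
ENDCOMMENT

NEURON {{
    POINT_PROCESS DoubleDecayGlut
    RANGE gmax_ampa, gmax_nmda, g_ampa, g_nmda, e_rev, i
    RANGE mg, mg_a, mg_b
    NONSPECIFIC_CURRENT i
}}

UNITS {{
    (nA) = (nanoamp)
    (mV) = (millivolt)
    (uS) = (microsiemens)
    (mM) = (milli/liter)
}}

PARAMETER {{
{param_lines}
}}

ASSIGNED {{
    v (mV)
    i (nA)
    g_ampa (uS)
    g_nmda (uS)
    mgblock
}}

STATE {{
{state_lines}
}}

INITIAL {{
{init_lines}
}}

BREAKPOINT {{
    SOLVE state METHOD cnexp
    {ga}
    {gn}
    mgblock = 1 / (1 + exp(-mg_a*v) * (mg / mg_b))
    i = g_ampa*(v - e_rev) + g_nmda*mgblock*(v - e_rev)
}}

DERIVATIVE state {{
{deriv_lines}
}}

NET_RECEIVE(weight) {{
{netrec_lines}
}}
"""
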