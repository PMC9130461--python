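# pscfit

Conductance-based models of AMPA- and NMDA-receptor postsynaptic currents
(PSCs) with a **tri-exponential** conductance profile — one rise constant and
*both* the fast and the slow decay constant of a double-exponential decay fit
— plus the trace-fitting and analysis machinery that goes with it.

## Who this is for

Electrophysiologists and modellers who fit voltage-clamp PSC recordings and
build conductance-based synapse models for simulators such as NEURON.  The
common practice of fitting two decay time constants and then collapsing them
into one amplitude-weighted mean (τ_w) discards information: the weighted
single exponential is generally no better than a plain mono-exponential fit.
Keeping both components describes the current profile substantially better,
at the cost of losing the closed-form peak time — which this package restores
numerically with a purpose-built Newton solver.

## The model

The classical bi-exponential conductance is

    g(t) = ḡ · K · (e^(−(t−t₀)/τ_decay) − e^(−(t−t₀)/τ_rise)),

with closed-form peak time t_peak = t₀ + (τ_d τ_r)/(τ_d − τ_r) · ln(τ_d/τ_r)
and normalization K chosen so g(t_peak) = ḡ.  The tri-exponential profile
keeps both decay components:

    g(t) = ḡ · K · (I_f e^(−(t−t₀)/τ_f) + I_s e^(−(t−t₀)/τ_s) − K̃ e^(−(t−t₀)/τ_r)),

where K̃ = I_f + I_s makes g(t₀) = 0.  Setting g′(t) = 0 and rearranging
yields a scalar root problem F(t_peak) = 0 which Newton's method
(t ← t − F/F′, analytic F′) solves to machine precision in a handful of
iterations from a closed-form starting guess (the bi-exponential peak time
evaluated with τ_w).  Currents follow I = g·(V − E_rev) for AMPA and
I = g·Mg(V)·(V − E_rev) for NMDA, with the sigmoidal magnesium block
Mg(V) = 1/(1 + e^(−aV)·[Mg²⁺]/b).

Trace analysis implements the standard paired-recording rules: the
NMDA/AMPA ratio (peak at −70 mV vs. mean current 50–60 ms post-stimulus at
+40 mV, computed per cell and then averaged per group), the peak-order QC
exclusion, and AMPA-template subtraction.

## Worked example

```python
import pscfit as pf

# NMDA-like kinetics: 2 ms rise, 30/200 ms fast/slow decay, 70/30 split
kin = pf.TriExpKinetics(tau_r=2.0, tau_f=30.0, tau_s=200.0,
                        i_f=0.7, i_s=0.3, gbar=1e-3, t0=20.0)
res = pf.newton_peak_time(kin)
print(f"peak time: {res.t_peak:.6f} ms after {res.iterations} Newton iterations")

# synthetic -70 mV recording at 10 kHz, then compare decay-fitting methods
spec = pf.GeneratorSpec(pf.SynapseModel(kin, e_rev=0.0), holding_mV=-70.0,
                        sampling_khz=10.0, duration=1100.0)
trace, _ = pf.generate_trace(spec)
print(pf.compare_methods(trace)[["rmse"]].round(4))

fit = pf.TriExpPSCModel(trace).fit()
print(fit.summary())
```

prints

```
peak time: 26.408144 ms after 3 Newton iterations
            rmse
method
mono      2.2773
weighted  3.6050
double    0.0808
Tri-exponential PSC fit (rise + fast/slow decay)
================================================
n samples   10800
tau_r       2 ms
tau_f       30 ms
tau_s       200 ms
I_f         0.7 (normalized)
I_s         0.3 (normalized)
peak ampl.  70 (trace units)
t_peak      26.4081 ms (newton, 3 iterations)
RMSE        1.86132e-15
```

The conductance peaks 6.408 ms after the synaptic onset (t₀ = 20 ms).  On
this NMDA-like trace the double-exponential decay fit beats the
mono-exponential by a factor ~28 in RMSE while the weighted-τ collapse is
*worse* than mono — the motivation for keeping both decay components.  The
full-profile fit recovers every generating parameter exactly at zero noise.

A CLI mirrors the library (`pscfit fit|compare|ratio|qc|simulate|peaktime|
emit-mod`); `pscfit emit-mod ampa.cfg nmda.cfg` renders a NEURON NMODL
mechanism with one extra conductance state per receptor for the slow decay
component and the Newton-solved peak times and normalization factors baked
in as constants.

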