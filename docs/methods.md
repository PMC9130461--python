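# Methods

## Conductance model

Synaptic conductances are modelled as differences of exponentials anchored
at the presynaptic spike time t₀.  The bi-exponential profile
(`BiExpKinetics`) uses one rise and one decay constant and has closed-form
peak time and normalization.  The tri-exponential profile
(`TriExpKinetics`) keeps both components of a double-exponential decay:

    g(t) = ḡ K (I_f e^(−x/τ_f) + I_s e^(−x/τ_s) − K̃ e^(−x/τ_r)),  x = t − t₀,

with K̃ = I_f + I_s so that g(t₀) = 0 exactly.  K̃ is always recomputed
from the stored fractions, never cached, so the zero-at-onset identity
cannot drift out of sync with the amplitudes.  The amplitude fractions are
stored un-normalized; `TriExpKinetics.normalized()` rescales them to sum
to one when a canonical form is needed (e.g. comparing fits).

Assumptions: deterministic conductance (no vesicle-release stochasticity,
no desensitization, no short-term plasticity), a single synchronous
activation at t₀, and causality (g ≡ 0 for t < t₀; the mathematical
profile is only used on t ≥ t₀).

Units follow NEURON mechanism conventions: ms, mV, µS, nA (µS·mV = nA).
Traces are handled in pA; the generator converts nA → pA.  Conductance is
nonnegative and the sign of a current comes entirely from the driving
force, so −70 mV recordings of excitatory PSCs are negative (inward).

Parameter invariants: 0 < τ_r < τ_f ≤ τ_s, I_f, I_s ≥ 0 with I_f + I_s > 0.
τ_f = τ_s is allowed (the peak-time target is regular there and the model
degenerates smoothly to the bi-exponential); the bi-exponential
τ_rise = τ_decay case is a removable singularity and is only evaluated via
the documented alpha-function limit behind an explicit `allow_limit` flag —
by default it is a validation error, since silently switching formulas
near the singular surface can mask a mis-specified fit.

## Peak time by Newton's method

Setting g′(t) = 0, dividing by the fast-decay exponential and taking logs
gives the root target

    F(t) = x − c·log(a₀ + a₁ e^(r x)),   c = τ_r τ_f/(τ_r − τ_f),
    a₀ = (I_f/K̃)(τ_r/τ_f),  a₁ = (I_s/K̃)(τ_r/τ_s),  r = (τ_s − τ_f)/(τ_f τ_s).

The log argument is a sum of positive terms, so F is defined for every
valid parameter set and every t.  F′ is derived analytically from this
expression (F′ = 1 − c r a₁ e^(r x)/(a₀ + a₁ e^(r x))) and validated
against central finite differences in the test suite rather than
transcribed from any secondary source.  When I_s = 0 or τ_f = τ_s the
exponential term is constant, F is affine, and the root coincides with the
bi-exponential closed form — the reduction identity checked to 10⁻¹⁰ ms.

Newton iteration: t ← t − F/F′, stopping on the step magnitude |d| ≤ tol
(not on |F|), defaults tol = 10⁻¹² ms and max_iter = 50.  The initial
guess is the bi-exponential closed-form peak time evaluated with the
amplitude-weighted mean decay constant τ_w — always defined, cheap, and
close enough to the root that convergence is quadratic from the first
step.  Across 1000 random physiological sets per seed the solver needs 3–5
iterations (≈40% take 3, ≈55% take 4); occasional extreme draws with
τ_f barely above τ_r can take 6–7.  A converged root must additionally
satisfy the stationarity balance
I_f/τ_f e^(−x/τ_f) + I_s/τ_s e^(−x/τ_s) = K̃/τ_r e^(−x/τ_r)
to a relative residual < 10⁻⁸, guarding against convergence to a point
where the iteration left the meaningful domain.

Safeguard: if Newton fails (non-finite iterate, t ≤ t₀, or no convergence
within the cap) a hand-rolled bracketed bisection on the sign of g′ over
(t₀, t₀ + 20 τ_s] refines the peak to 10⁻⁹ ms.  The rate is provably
positive at onset for valid kinetics, so a sign change always exists.  The
result is then flagged `converged=False, method="bisection"`; `converged`
refers strictly to the Newton iteration, while the stationarity residual
certifies the root either way.

## Trace fitting

All fits run on the magnitude of the baseline-subtracted current (inward
currents sign-flipped), with the baseline estimated as the mean over the
10 ms preceding the stimulus (configurable).  Decay fits use the window
from the detected peak to the last sample by default; window bounds are
user-overridable.  Decay fits carry no offset term by default (the traces
are assumed baseline-subtracted averaged sweeps); `fit_baseline=True`
adds one.

The optimizer is SciPy's trust-region-reflective nonlinear least squares
with positivity bounds, tolerances 10⁻¹³–10⁻¹⁴ and an evaluation budget of
5000.  The double-decay fit uses three seeded starts (fast-dominant,
slow-dominant, balanced) and keeps the best by cost; components are
relabelled post-fit so τ_f ≤ τ_s, ties broken by labelling the larger
amplitude fast, and fits with τ_f within 1% of τ_s are flagged degenerate.

The full-profile model fits c·(w e^(−x/τ_f) + (1−w) e^(−x/τ_s) − e^(−x/τ_r))
from the stimulus onward with t₀ fixed at the stimulus time.  Internally
the constants are parameterized as τ_r = q·τ_f (q ∈ (0,1)) and
τ_s = τ_f + d (d ≥ 0), so the ordering τ_r < τ_f ≤ τ_s holds for every
candidate the optimizer visits — without this, near-degenerate traces
(τ_r ≈ τ_f) let the optimizer wander into invalid orderings.  In that same
near-degenerate regime the cost valley is flat along the rise/fast-decay
direction and the step criterion may never fire within the budget although
the estimate has converged; budget-exhausted candidates are therefore
accepted but outranked by strictly converged ones.  Starting values come
from a double-decay pre-fit plus a rise-time heuristic (a third of the
stim-to-peak delay).  The fitted peak amplitude (`gbar` in trace units) is
c/K with K the normalization factor at the Newton-solved peak.

The "weighted" procedure reconstructs a single-exponential decay with τ_w
and total amplitude I_f + I_s from the double fit — the collapse this
package exists to argue against — and `compare_methods` reports the RMSE
of all three reconstructions on the shared window, marking failed methods
instead of aborting.

## Paired-recording analysis

NMDA/AMPA ratio: AMPA component = |peak| of the −70 mV trace; NMDA
component = |mean| of the +40 mV trace over stimulus + [50, 60] ms, where
the fast AMPA current has decayed.  Ratios are computed per cell, then
averaged per group (mean of ratios, never ratio of means — the two differ
whenever component magnitudes vary across cells, which the tests
demonstrate with a constructed discordant pair).  The window average
under-weights slow NMDA onset slightly relative to a peak measure; the
paired-trace generator calibrates against the same rule, so round trips
are exact by construction.

QC: a pair is excluded iff the NMDA trace's peak time is at or before the
AMPA trace's peak time, reflecting the slower kinetics genuine NMDA
currents must show; apparent NMDA responses that peak first (seen in some
fast-spiking interneurons, which may lack NMDA receptors) are artefacts of
imperfect separation.

AMPA subtraction removes a scaled template pointwise on a shared grid; the
default scale is the linear driving-force ratio
(V_target − E_rev)/(V_template − E_rev), exposed as a parameter since real
AMPA I–V curves are not perfectly linear.

## Magnesium block defaults

Mg(V) = 1/(1 + e^(−aV)·[Mg²⁺]/b) with defaults a = 0.062 mV⁻¹,
b = 3.57 mM — the classic Jahr–Stevens constants — and [Mg²⁺] = 1 mM
(standard ACSF).  These are assumptions, not fitted values: published
corrections to a and b exist and users with a preferred calibration should
override them (`MgBlockParams(a=..., b=..., mg_conc=...)`; the NMODL
emitter takes them as parameters).

## Synthetic data

`generate_trace` evaluates the model current exactly on a uniform 10–20 kHz
grid (matching typical acquisition rates), optionally applies a
first-order low-pass (emulating the ~kHz hardware filter), and adds
i.i.d. Gaussian noise seeded through the spec — at zero noise and no
filter the samples equal the analytic current to the last bit, which the
tests rely on.  What it does *not* emulate: trial-to-trial amplitude
variability, stimulus artefacts, access-resistance errors, 1/f or line
noise, and train stimulation; passing recovery tests therefore show
correctness of the fitting machinery on the assumed signal model, not
robustness to every artefact of real recordings, which are expected to be
pre-processed averaged sweeps.

Random kinetics are drawn from τ_r ∈ [0.2, 5], τ_f ∈ [2, 60],
τ_s ∈ [60, 600] ms, slow fraction ∈ [0.1, 0.9] (rejection keeps
τ_r < τ_f), spanning AMPA-like through NMDA-like PSCs in mammalian brain
slices.  The method-comparison study uses a narrower NMDA-like subset
(τ_r ∈ [2, 6], τ_f ∈ [25, 70] ms, τ_s ≥ 5 τ_f, slow fraction ∈ [0.3, 0.8]):
with rise constants approaching the fast decay constant the decay window
is contaminated by the rise remnant and no decay-only procedure fits well,
which is a property of the window, not of the decay model.  Recovery
studies use traces of duration stimulus + 5 τ_s so the slow component is
resolved, at 10 kHz; the acceptance-grade recovery study runs 12 zero-noise
sets and 100 sets at noise sd = 2% of peak.

## Known limitations

- No kinetic-scheme (Markov) receptor models, desensitization, or
  short-term plasticity; the NMODL emitter produces the conductance
  mechanism only and the text is not compiled or simulated here.
- t₀ is taken as the stimulus time in full-profile fits; synaptic latency
  is absorbed into the rise constant rather than fitted separately.
- Individual τ_r/τ_f estimates are poorly identified when τ_r ≈ τ_f
  (near-cancelling exponentials); τ_s and the overall profile remain
  well determined.
- The ratio rule's 50–60 ms window assumes the AMPA component is
  negligible there; for unusually slow AMPA kinetics the ratio is biased
  upward.
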