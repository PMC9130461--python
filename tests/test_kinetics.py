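"""Conductance profiles, normalization, Mg block, currents."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pscfit as pf
from pscfit.errors import DegenerateKineticsError, KineticsError, PeakSolverError


def tiny_biexp(tau_rise=1.0, tau_decay=2.0, **kw):
    return pf.BiExpKinetics(tau_rise, tau_decay, **kw)


class TestBiExp:
    def test_peak_time_closed_form_matches_grid_oracle(self):
        # brute-force maximization of the profile at 1e-5 ms resolution
        k = tiny_biexp()
        t = np.arange(1e-5, 20, 1e-5)
        prof = np.exp(-t / k.tau_decay) - np.exp(-t / k.tau_rise)
        t_grid = t[prof.argmax()]
        assert pf.biexp_peak_time(k) == pytest.approx(1.3863, abs=2e-4)
        assert abs(pf.biexp_peak_time(k) - t_grid) < 1e-5

    def test_norm_factor_value_and_peak_normalization(self):
        k = tiny_biexp()
        tp = pf.biexp_peak_time(k)
        assert pf.biexp_norm_factor(k) == pytest.approx(
            1.0 / (math.exp(-tp / 2) - math.exp(-tp / 1)))
        assert pf.biexp_norm_factor(k) == pytest.approx(4.0)
        assert pf.biexp_conductance(k, tp) == pytest.approx(k.gbar, rel=1e-12)

    @given(st.floats(0.1, 10), st.floats(1.05, 20))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_peak_after_onset_and_norm_factor_above_one(self, tr, ratio):
        k = pf.BiExpKinetics(tr, tr * ratio, gbar=2.0, t0=5.0)
        tp = pf.biexp_peak_time(k)
        assert tp > k.t0
        assert pf.biexp_norm_factor(k) > 1.0
        assert pf.biexp_conductance(k, tp) == pytest.approx(2.0, rel=1e-12)

    def test_zero_at_onset_before_onset_and_at_infinity(self):
        k = tiny_biexp(t0=3.0)
        assert pf.biexp_conductance(k, 3.0) == 0.0
        assert pf.biexp_conductance(k, 2.0) == 0.0
        assert pf.biexp_conductance(k, 1e5) == pytest.approx(0.0, abs=1e-300)

    def test_equal_taus_requires_opt_in_limit(self):
        k = pf.BiExpKinetics(2.0, 2.0)
        with pytest.raises(DegenerateKineticsError):
            pf.biexp_peak_time(k)
        # analytic alpha-function limit: peak at t0 + tau
        assert pf.biexp_peak_time(k, allow_limit=True) == pytest.approx(2.0)
        tp = pf.biexp_peak_time(k, allow_limit=True)
        assert pf.biexp_conductance(k, tp, allow_limit=True) == pytest.approx(
            k.gbar, rel=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(KineticsError):
            pf.BiExpKinetics(2.0, 1.0)
        with pytest.raises(KineticsError):
            pf.BiExpKinetics(-1.0, 2.0)
        with pytest.raises(KineticsError):
            pf.BiExpKinetics(1.0, 2.0, gbar=-1.0)


class TestTriExp:
    def test_zero_at_onset_and_peak_normalization(self, representative_kinetics):
        k = representative_kinetics
        res = pf.newton_peak_time(k)
        assert pf.triexp_conductance(k, k.t0, res.t_peak) == 0.0
        assert pf.triexp_conductance(k, res.t_peak, res.t_peak) == pytest.approx(
            k.gbar, rel=1e-12)
        assert pf.triexp_conductance(k, k.t0 - 1.0, res.t_peak) == 0.0

    def test_norm_factor_matches_grid_profile_maximum(self,
                                                      representative_kinetics):
        k = representative_kinetics
        res = pf.newton_peak_time(k)
        x = np.arange(1e-4, 5 * k.tau_s, 1e-3)
        prof = (k.i_f * np.exp(-x / k.tau_f) + k.i_s * np.exp(-x / k.tau_s)
                - k.ktilde * np.exp(-x / k.tau_r))
        assert pf.triexp_norm_factor(k, res.t_peak) == pytest.approx(
            1.0 / prof.max(), rel=1e-7)

    def test_single_component_reduces_to_biexp(self):
        k3 = pf.TriExpKinetics(1.0, 2.0, 2.0, 1.0, 0.0, gbar=1.5)
        k2 = pf.BiExpKinetics(1.0, 2.0, gbar=1.5)
        tp = pf.newton_peak_time(k3).t_peak
        assert tp == pytest.approx(pf.biexp_peak_time(k2), abs=1e-10)
        t = np.linspace(0, 30, 500)
        np.testing.assert_allclose(pf.triexp_conductance(k3, t, tp),
                                   pf.biexp_conductance(k2, t), rtol=1e-12,
                                   atol=1e-300)

    def test_supplied_nonstationary_peak_rejected(self, representative_kinetics):
        k = representative_kinetics
        with pytest.raises(PeakSolverError):
            pf.triexp_conductance(k, 10.0, 1.0)

    def test_nonnegative_on_support(self, random_kinetics_suite):
        for k in random_kinetics_suite[:50]:
            tp = pf.newton_peak_time(k).t_peak
            t = np.linspace(k.t0, k.t0 + 10 * k.tau_s, 2000)
            assert (pf.triexp_conductance(k, t, tp) >= -1e-300).all()

    def test_ktilde_is_recomputed_sum(self):
        k = pf.TriExpKinetics(1.0, 5.0, 50.0, 0.4, 1.2)
        assert k.ktilde == pytest.approx(1.6)


class TestWeightedTau:
    def test_equal_weights_give_arithmetic_mean(self):
        assert pf.weighted_tau(1.0, 1.0, 10.0, 50.0) == pytest.approx(30.0)

    def test_degenerate_weight_and_hand_arithmetic(self):
        assert pf.weighted_tau(1.0, 0.0, 10.0, 50.0) == pytest.approx(10.0)
        assert pf.weighted_tau(3.0, 1.0, 10.0, 50.0) == pytest.approx(20.0)

    def test_zero_total_amplitude_signals(self):
        with pytest.raises(KineticsError):
            pf.weighted_tau(0.0, 0.0, 10.0, 50.0)

    @given(st.floats(0.01, 10), st.floats(0.01, 10),
           st.floats(1, 50), st.floats(1, 50))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_bounded_by_the_two_constants(self, i_f, i_s, tau_f, tau_s):
        tw = pf.weighted_tau(i_f, i_s, tau_f, tau_s)
        assert min(tau_f, tau_s) - 1e-12 <= tw <= max(tau_f, tau_s) + 1e-12


class TestMgBlockAndCurrent:
    def test_no_magnesium_means_no_block(self):
        p = pf.MgBlockParams(mg_conc=0.0)
        v = np.linspace(-100, 60, 50)
        np.testing.assert_array_equal(pf.mg_block(p, v), np.ones_like(v))

    def test_limits_and_zero_voltage_value(self):
        p = pf.MgBlockParams(a=0.062, b=3.57, mg_conc=1.0)
        assert pf.mg_block(p, -1e4) == pytest.approx(0.0, abs=1e-12)
        assert pf.mg_block(p, 0.0) == pytest.approx(1.0 / (1.0 + 1.0 / 3.57))

    def test_bounded_and_monotone_in_voltage(self):
        p = pf.MgBlockParams(mg_conc=1.0)
        v = np.linspace(-120, 80, 400)
        b = pf.mg_block(p, v)
        assert ((b > 0) & (b <= 1)).all()
        assert (np.diff(b) >= 0).all()

    def test_current_sign_convention_and_reversal(self):
        ampa = pf.SynapseModel(pf.BiExpKinetics(1.0, 5.0), e_rev=0.0)
        assert pf.synaptic_current(ampa, 1.0, -70.0) == pytest.approx(-70.0)
        assert pf.synaptic_current(ampa, 1.0, 0.0) == 0.0

    def test_nmda_current_magnitude_below_ohmic(self):
        nmda = pf.SynapseModel(pf.BiExpKinetics(2.0, 80.0), e_rev=0.0,
                               mg=pf.MgBlockParams(mg_conc=1.0))
        ohmic = pf.SynapseModel(pf.BiExpKinetics(2.0, 80.0), e_rev=0.0)
        for v in (-70.0, -30.0, 40.0):
            assert abs(pf.synaptic_current(nmda, 0.5, v)) <= abs(
                pf.synaptic_current(ohmic, 0.5, v))
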