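import numpy as np
import pytest

from pscfit import (
    GeneratorSpec,
    SynapseModel,
    TriExpKinetics,
    generate_trace,
    sample_physiological_kinetics,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def representative_kinetics():
    """NMDA-like tri-exponential set used throughout the docs/tests."""
    return TriExpKinetics(tau_r=2.0, tau_f=30.0, tau_s=200.0,
                          i_f=0.7, i_s=0.3)


@pytest.fixture
def random_kinetics_suite(rng):
    """200 seeded physiological kinetics sets (rise 0.2-5 ms, fast decay
    2-60 ms, slow decay 60-600 ms, slow fraction 0.1-0.9)."""
    return [sample_physiological_kinetics(rng) for _ in range(200)]


@pytest.fixture
def nmda_like_trace():
    """Zero-noise synthetic NMDA-like PSC at -70 mV, 10 kHz."""
    kin = TriExpKinetics(2.0, 30.0, 200.0, 0.7, 0.3, gbar=1e-3, t0=20.0)
    spec = GeneratorSpec(SynapseModel(kin, e_rev=0.0), holding_mV=-70.0,
                         sampling_khz=10.0, duration=1100.0, noise_sd=0.0)
    trace, _ = generate_trace(spec)
    return trace, kin


def grid_argmax_peak(kin: TriExpKinetics, fine_step: float = 1e-4) -> float:
    """Independent peak-time oracle: dense-grid argmax of the un-normalized
    tri-exponential profile, coarse localization then a fine grid at
    ``fine_step`` ms resolution."""
    coarse = np.linspace(fine_step, 2.0 * kin.tau_s, 4000)

    def profile(x):
        return (kin.i_f * np.exp(-x / kin.tau_f)
                + kin.i_s * np.exp(-x / kin.tau_s)
                - kin.ktilde * np.exp(-x / kin.tau_r))

    i = int(np.argmax(profile(coarse)))
    lo = coarse[max(i - 2, 0)]
    hi = coarse[min(i + 2, len(coarse) - 1)]
    fine = np.arange(lo, hi, fine_step)
    return kin.t0 + float(fine[np.argmax(profile(fine))])
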