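"""Shared fixtures: analytic spectra, designed model pairs, random spectra."""

import numpy as np
import pytest

import fes


@pytest.fixture
def rng():
    return np.random.default_rng(20200809)


@pytest.fixture
def plan5():
    """Five log-equal sub-bands over [3, 300] Hz, the packaged analysis band."""
    return fes.make_band_plan(3.0, 300.0, 5)


@pytest.fixture
def power_law():
    """Factory for exact power-law spectra S(f) = level * f**(-gamma)."""

    def make(gamma, f_lo=0.1, f_hi=500.0, level=1.0, n=200, label="power-law"):
        f = np.geomspace(f_lo, f_hi, n)
        return fes.PowerSpectrum(
            frequencies=f, density=level * f ** (-gamma), label=label
        )

    return make


@pytest.fixture
def random_spectrum():
    """Factory for random positive spectra: log-density random walk on a log grid."""

    def make(rng, n=120, f_lo=1.0, f_hi=400.0):
        f = np.geomspace(f_lo, f_hi, n)
        log_s = np.cumsum(rng.normal(-0.05, 0.15, size=n)) - 3.0
        return fes.PowerSpectrum(frequencies=f, density=10.0 ** log_s)

    return make


@pytest.fixture
def designed_models():
    """Agent/reference models whose analytic ternary pattern is [+1,-1,0,+1,+1]."""
    return fes.designed_model_pair()
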