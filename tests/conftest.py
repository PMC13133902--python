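import numpy as np
import pytest

from darktrap import io
from darktrap.kinetics import KineticParams


@pytest.fixture(scope="session")
def diagram():
    """The packaged meta-HBDI level diagram."""
    return io.read_level_diagram()


@pytest.fixture(scope="session")
def reference_kinetics():
    """Sequential-model parameters at the experimentally fitted lifetimes."""
    return KineticParams(
        tau_fast=100e-15,
        tau_slow=94e-12,
        amp_s2=1.0,
        amp_s1=0.5,
        amp_s0=1.0,
        baseline=0.05,
        t0=0.0,
        irf_sigma=80e-15,
    )


def enumerate_sum_of_states(freqs_cm1, emax_cm1):
    """Brute-force count of harmonic states with sum(n_i nu_i) <= E.

    Independent oracle for the direct-count algorithm: plain recursive
    enumeration over occupation numbers.
    """
    freqs = list(freqs_cm1)
    count = 0

    def rec(i, remaining):
        nonlocal count
        if i == len(freqs):
            count += 1
            return
        f = freqs[i]
        n = 0
        while n * f <= remaining:
            rec(i + 1, remaining - n * f)
            n += 1

    rec(0, emax_cm1)
    return count


@pytest.fixture(scope="session")
def enum_oracle():
    return enumerate_sum_of_states


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
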